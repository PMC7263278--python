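"""Training of the oxidative-stress predictor.

The mutation rate Y (SNV count / 20,000) of each sample is modelled as a
linear combination of the log-transformed expressions of a small set of
enzyme-encoding genes:

    Y = X B + eps,

with model size controlled two ways: an L1 (Lasso) pre-screen over all
annotated enzyme genes, and a subset-size criterion RSS + lambda * m used
to compare candidate supports (the well-posed reading of a size-penalised
least-squares objective; for a fixed support the penalty is a constant, so
within-support fitting is plain OLS). The final support is refined by
backward elimination on coefficient p-values: genes with p > 0.05 are
removed and the model refitted until every retained gene is significant.

Training repeats over random 2/3 train - 1/3 test splits and keeps the
model with the best held-out Pearson correlation. The contribution of each
EC sub-subclass is summarised as the product of its selected genes'
p-values (computed in log space).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn import linear_model

from . import io as oio

logger = logging.getLogger("oxistress")


class EmptyModelError(RuntimeError):
    """No gene survived selection; there is no model to return."""


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the offending columns."""


# ---------------------------------------------------------------------------
# enzyme annotation


class EnzymeAnnotation:
    """Gene -> EC number mapping with sub-subclass extraction.

    A "subclass" here is the first three fields of an EC number (e.g.
    ``3.4.21`` of ``3.4.21.5``); a gene may carry several EC numbers and
    then belongs to every corresponding subclass.
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]]):
        self._map: dict[str, list[str]] = {}
        for gene, ecs in mapping.items():
            for ec in ecs:
                if not oio.EC_PATTERN.match(ec):
                    raise ValueError(f"malformed EC number {ec!r} for {gene!r}")
            self._map[str(gene)] = list(ecs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnzymeAnnotation":
        return cls(oio.read_ec_map(path))

    @staticmethod
    def subclass_key(ec: str) -> str:
        return ".".join(ec.split(".")[:3])

    @staticmethod
    def top_class(ec: str) -> str:
        return ec.split(".")[0]

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def genes(self) -> list[str]:
        return list(self._map)

    def ecs(self, gene: str) -> list[str]:
        return list(self._map.get(gene, []))

    def subclasses_of(self, gene: str) -> list[str]:
        seen: list[str] = []
        for ec in self._map.get(gene, []):
            key = self.subclass_key(ec)
            if key not in seen:
                seen.append(key)
        return seen

    def genes_in_classes(self, classes: Iterable[str]) -> list[str]:
        """Genes carrying at least one EC number in the given top classes."""
        wanted = {str(c) for c in classes}
        return [g for g, ecs in self._map.items()
                if any(self.top_class(ec) in wanted for ec in ecs)]


# ---------------------------------------------------------------------------
# expression transform


def transform_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) of a non-negative expression matrix (genes x samples)."""
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    return np.log2(expr + 1.0)


# ---------------------------------------------------------------------------
# ordinary least squares with coefficient t-tests


@dataclass
class OLSResult:
    coefficients: pd.Series   # per predictor
    intercept: float
    p_values: pd.Series       # two-sided t-tests, per predictor
    rss: float
    r2: float


def ols_fit(X: pd.DataFrame, y: pd.Series, intercept: bool = True) -> OLSResult:
    """Least-squares fit with per-coefficient two-sided t-test p-values.

    Requires n > m + 1 and a full-rank design; rank deficiency raises
    :class:`RankDeficiencyError` naming the offending columns.
    """
    n, m = X.shape
    if n <= m + (1 if intercept else 0):
        raise ValueError(f"need n > m + {int(intercept)} (got n={n}, m={m})")
    design = sm.add_constant(X, has_constant="add") if intercept else X
    arr = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # QR with column pivoting: trailing pivots are the dependent columns
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        bad = [design.columns[j] for j in piv[rank:]]
        raise RankDeficiencyError(f"rank-deficient design; offending columns: {bad}")
    fit = sm.OLS(np.asarray(y, dtype=float), arr).fit()
    names = list(design.columns)
    params = pd.Series(fit.params, index=names)
    pvals = pd.Series(fit.pvalues, index=names)
    if intercept:
        b0 = float(params.pop("const"))
        pvals = pvals.drop("const")
    else:
        b0 = 0.0
    return OLSResult(
        coefficients=params,
        intercept=b0,
        p_values=pvals,
        rss=float(fit.ssr),
        r2=float(fit.rsquared),
    )


# ---------------------------------------------------------------------------
# Lasso pre-screen


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def lasso_path(X: pd.DataFrame, y: pd.Series,
               lambdas: Sequence[float]) -> dict[float, pd.Series]:
    """Coordinate-descent Lasso solutions over a descending penalty grid.

    Columns of X are standardised internally (zero mean, unit sd). The
    objective is (1/2n)||y - Xb||^2 + lambda ||b||_1, so above
    max|X^T y| / n the solution is identically zero and, for an
    orthonormal design (X^T X = n I), each coefficient is the
    soft-thresholded OLS coefficient.
    """
    if len(lambdas) == 0:
        raise ValueError("empty lambda grid")
    Xs = _standardize(np.asarray(X, dtype=float))
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    out: dict[float, pd.Series] = {}
    for lam in sorted(lambdas, reverse=True):
        est = linear_model.Lasso(alpha=float(lam), fit_intercept=False,
                                 max_iter=50_000, tol=1e-10)
        est.fit(Xs, yc)
        out[float(lam)] = pd.Series(est.coef_, index=X.columns)
    return out


def lasso_screen(X: pd.DataFrame, y: pd.Series, alpha: float | None = None,
                 selection: str = "bic", seed: int = 0) -> list[str]:
    """Shortlist predictors with a Lasso fit; returns genes with nonzero
    coefficients.

    ``alpha`` fixes the penalty; otherwise it is chosen by BIC along the
    LARS path (default, sparse) or by 5-fold cross-validation
    (``selection="cv"``).
    """
    Xs = _standardize(np.asarray(X, dtype=float))
    yc = np.asarray(y, dtype=float)
    if alpha is not None:
        coef = lasso_path(X, y, [alpha])[float(alpha)]
    elif selection == "bic":
        est = linear_model.LassoLarsIC(criterion="bic", fit_intercept=True)
        est.fit(Xs, yc)
        coef = pd.Series(est.coef_, index=X.columns)
    elif selection == "cv":
        est = linear_model.LassoCV(cv=5, fit_intercept=True,
                                   random_state=seed, max_iter=50_000)
        est.fit(Xs, yc)
        coef = pd.Series(est.coef_, index=X.columns)
    else:
        raise ValueError(f"unknown selection mode {selection!r}")
    return [g for g in X.columns if coef[g] != 0.0]


# ---------------------------------------------------------------------------
# subset-size criterion


def subset_objective(rss: float, m: int, lam: float) -> float:
    """Size-penalised fit criterion RSS + lambda * m; lower is better."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if m < 0:
        raise ValueError("m must be non-negative")
    return float(rss) + float(lam) * int(m)


def best_subset(X: pd.DataFrame, y: pd.Series, lam: float,
                intercept: bool = True) -> tuple[tuple[str, ...], float]:
    """Exhaustively minimise subset_objective over all supports of X.

    Only feasible for small candidate sets (2^m fits); used as the
    reference the greedy pipeline is compared against.
    """
    cols = list(X.columns)
    if len(cols) > 16:
        raise ValueError("exhaustive search limited to 16 candidates")
    yv = np.asarray(y, dtype=float)
    best: tuple[tuple[str, ...], float] | None = None
    for r in range(len(cols) + 1):
        for combo in itertools.combinations(cols, r):
            if r == 0:
                resid = yv - (yv.mean() if intercept else 0.0)
                rss = float(resid @ resid)
            else:
                rss = ols_fit(X[list(combo)], y, intercept=intercept).rss
            obj = subset_objective(rss, r, lam)
            if best is None or obj < best[1] - 1e-12:
                best = (combo, obj)
    assert best is not None
    return best


def prune_by_subset_objective(
    X: pd.DataFrame, y: pd.Series, kept: Sequence[str], lam: float,
    intercept: bool = True,
) -> tuple[list[str], OLSResult | None]:
    """Greedy backward pruning of a support under RSS + lambda * m.

    Repeatedly removes the single gene whose removal most decreases the
    size-penalised objective, refitting by OLS, until no removal improves
    it (ties broken by gene symbol). Returns the pruned support and its
    fit; an emptied support returns ``([], None)``.
    """
    kept = list(kept)
    if not kept:
        return [], None
    fit = ols_fit(X[kept], y, intercept=intercept)
    current = subset_objective(fit.rss, len(kept), lam)
    while kept:
        best_gene, best_obj, best_fit = None, current, fit
        for g in sorted(kept):
            reduced = [h for h in kept if h != g]
            if reduced:
                trial = ols_fit(X[reduced], y, intercept=intercept)
                rss = trial.rss
            else:
                yv = np.asarray(y, dtype=float)
                resid = yv - (yv.mean() if intercept else 0.0)
                trial, rss = None, float(resid @ resid)
            obj = subset_objective(rss, len(reduced), lam)
            if obj < best_obj - 1e-12:
                best_gene, best_obj, best_fit = g, obj, trial
        if best_gene is None:
            return kept, fit
        kept = [h for h in kept if h != best_gene]
        current, fit = best_obj, best_fit
        if fit is None:
            return [], None
    return [], None


def bic_lambda(X: pd.DataFrame, y: pd.Series, intercept: bool = True) -> float:
    """Default subset-penalty weight, sigma_hat^2 * log(n) (BIC calibration).

    sigma_hat^2 is the residual variance of the full OLS fit when feasible,
    else the variance of y.
    """
    n, m = X.shape
    if n > m + 2:
        try:
            res = ols_fit(X, y, intercept=intercept)
            dof = n - m - (1 if intercept else 0)
            sigma2 = res.rss / dof
        except RankDeficiencyError:
            sigma2 = float(np.var(np.asarray(y, dtype=float), ddof=1))
    else:
        sigma2 = float(np.var(np.asarray(y, dtype=float), ddof=1))
    return sigma2 * math.log(n)


def ebic_lambda(X: pd.DataFrame, y: pd.Series, n_candidates: int,
                intercept: bool = True) -> float:
    """Extended-BIC penalty weight, sigma_hat^2 * (log n + 2 log P).

    The plain BIC weight is calibrated for a fixed small candidate pool;
    when P candidate predictors were screened to reach the current support
    the extra 2 log P term restores control over selection noise
    (Chen & Chen's extended information criterion, at gamma = 1).
    """
    n = X.shape[0]
    base = bic_lambda(X, y, intercept=intercept)
    sigma2 = base / math.log(n)
    return sigma2 * (math.log(n) + 2.0 * math.log(max(n_candidates, 1)))


# ---------------------------------------------------------------------------
# backward elimination on p-values


def backward_eliminate(X: pd.DataFrame, y: pd.Series, p_threshold: float = 0.05,
                       drop_all: bool = True,
                       intercept: bool = True) -> tuple[list[str], OLSResult | None]:
    """Iterated OLS refits removing insignificant genes.

    Each round drops every gene with p > ``p_threshold`` (or, with
    ``drop_all=False``, only the single worst gene, p-ties broken by gene
    symbol), until all retained genes are significant or none remain.
    """
    kept = list(X.columns)
    result: OLSResult | None = None
    while kept:
        result = ols_fit(X[kept], y, intercept=intercept)
        bad = result.p_values[result.p_values > p_threshold]
        if bad.empty:
            return kept, result
        if drop_all:
            drop = set(bad.index)
        else:
            worst_p = bad.max()
            ties = sorted(bad.index[bad == worst_p])
            drop = {ties[0]}
        kept = [g for g in kept if g not in drop]
        result = None
    return [], None


# ---------------------------------------------------------------------------
# the trained predictor


@dataclass
class TrainConfig:
    """Knobs of :func:`train_predictor`; defaults follow the pipeline's
    standard operating point."""

    lasso_alpha: float | None = None     # None -> BIC-selected along LARS path
    lasso_selection: str = "bic"         # "bic" | "cv" (when alpha is None)
    ec_classes: tuple[str, ...] = ("2", "3")
    p_threshold: float = 0.05
    split_fraction: float = 2 / 3
    n_restarts: int = 20
    subset_lambda: float | None = None   # None -> sigma^2 log n (BIC)
    drop_all: bool = True
    max_subclasses: int | None = None    # optionally cap subclass count
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise ValueError("split_fraction must be in (0, 1)")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class RegressionModel:
    """A trained oxidative-stress predictor.

    ``score = intercept + sum_g coefficients[g] * log2(expr[g] + 1)``.
    """

    genes: list[str]
    coefficients: dict[str, float]
    intercept: float
    p_values: dict[str, float]
    lam: float                    # subset-size penalty weight used for reporting
    lasso_alpha: float | None
    split_seed: int               # restart index of the winning split
    train_r2: float
    test_r2: float
    test_pearson_r: float
    subset_objective: float
    subclass_contributions: dict[str, float] = field(default_factory=dict)
    transform: str = "log2p1"

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "p_values": self.p_values,
            "lambda": self.lam,
            "lasso_alpha": self.lasso_alpha,
            "split_seed": self.split_seed,
            "train_r2": self.train_r2,
            "test_r2": self.test_r2,
            "test_pearson_r": self.test_pearson_r,
            "subset_objective": self.subset_objective,
            "subclass_contributions": self.subclass_contributions,
            "transform": self.transform,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegressionModel":
        return cls(
            genes=list(d["genes"]),
            coefficients=dict(d["coefficients"]),
            intercept=float(d["intercept"]),
            p_values=dict(d["p_values"]),
            lam=float(d["lambda"]),
            lasso_alpha=d.get("lasso_alpha"),
            split_seed=int(d["split_seed"]),
            train_r2=float(d["train_r2"]),
            test_r2=float(d["test_r2"]),
            test_pearson_r=float(d["test_pearson_r"]),
            subset_objective=float(d["subset_objective"]),
            subclass_contributions=dict(d.get("subclass_contributions", {})),
            transform=d.get("transform", "log2p1"),
        )

    def save(self, path: str | Path) -> None:
        oio.save_json(self.to_dict(), path)

    @classmethod
    def load(cls, path: str | Path) -> "RegressionModel":
        return cls.from_dict(oio.load_json(path))


def subclass_contribution(model: RegressionModel,
                          annot: EnzymeAnnotation) -> dict[str, float]:
    """Product of selected genes' p-values per EC sub-subclass.

    Computed in log space and returned on the natural scale; a gene with
    several EC numbers enters every corresponding subclass product.
    Subclasses with no selected gene are omitted.
    """
    logs: dict[str, float] = {}
    for gene in model.genes:
        p = model.p_values[gene]
        logp = math.log(p) if p > 0 else float("-inf")  # underflowed p
        for sub in annot.subclasses_of(gene):
            logs[sub] = logs.get(sub, 0.0) + logp
    return {sub: math.exp(v) if math.isfinite(v) else 0.0
            for sub, v in sorted(logs.items())}


def _as_response(rates: pd.DataFrame | pd.Series) -> pd.Series:
    if isinstance(rates, pd.Series):
        return rates.astype(float)
    if "rate" in rates.columns:
        return rates["rate"].astype(float)
    raise ValueError("rates must be a Series or a frame with a 'rate' column")


def train_predictor(
    expr: pd.DataFrame,
    rates: pd.DataFrame | pd.Series,
    annot: EnzymeAnnotation,
    config: TrainConfig | None = None,
) -> RegressionModel:
    """Full training pipeline for one cohort.

    Steps: (1) log2(x+1) transform; (2) Lasso pre-screen over all annotated
    enzyme genes on the training split; (3) restriction to the configured
    EC top classes (default transferases "2" and hydrolases "3"); (4)
    backward elimination of genes with p > p_threshold; (5) held-out
    evaluation on the remaining third of samples; (6) best model over
    ``n_restarts`` random splits by held-out Pearson r; (7) per-subclass
    contribution statistic.
    """
    config = config or TrainConfig()
    y_all = _as_response(rates)

    shared = expr.columns.intersection(y_all.index)
    missing_expr = y_all.index.difference(expr.columns)
    missing_rate = expr.columns.difference(y_all.index)
    if len(shared) < 30:
        raise ValueError(
            "need >= 30 shared samples between expression and rates; "
            f"got {len(shared)} (missing from expression: "
            f"{list(missing_expr[:5])}, missing rates: {list(missing_rate[:5])})"
        )
    enzyme_genes = [g for g in expr.index if g in annot]
    if not enzyme_genes:
        raise EmptyModelError("no expression rows carry an EC annotation")

    Xt = transform_expression(expr.loc[enzyme_genes, shared]).T  # samples x genes
    # zero-variance genes carry no information and break standardisation
    keep = Xt.columns[Xt.std(axis=0) > 0]
    Xt = Xt[keep]
    y = y_all.loc[shared]

    n = len(shared)
    n_train = int(round(config.split_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    best: RegressionModel | None = None
    for restart in range(config.n_restarts):
        perm = rng.permutation(n)
        train_idx = shared[perm[:n_train]]
        test_idx = shared[perm[n_train:]]
        X_train, y_train = Xt.loc[train_idx], y.loc[train_idx]

        screened = lasso_screen(X_train, y_train, alpha=config.lasso_alpha,
                                selection=config.lasso_selection,
                                seed=config.seed)
        in_class = set(annot.genes_in_classes(config.ec_classes))
        candidates = [g for g in screened if g in in_class]
        if not candidates:
            logger.debug("restart %d: no candidate survived screening", restart)
            continue

        kept, fit = backward_eliminate(X_train[candidates], y_train,
                                       p_threshold=config.p_threshold,
                                       drop_all=config.drop_all)
        if not kept or fit is None:
            logger.debug("restart %d: backward elimination emptied the model",
                         restart)
            continue

        # compare supports under the size-penalised objective RSS + lambda*m;
        # the default weight accounts for the size of the screened pool
        lam = config.subset_lambda
        if lam is None:
            lam = ebic_lambda(X_train[kept], y_train, Xt.shape[1])
        kept, fit = prune_by_subset_objective(X_train, y_train, kept, lam)
        if kept:  # pruning can shift p-values; re-assert the p contract
            kept, fit = backward_eliminate(X_train[kept], y_train,
                                           p_threshold=config.p_threshold,
                                           drop_all=config.drop_all)
        if not kept or fit is None:
            continue

        if config.max_subclasses is not None:
            kept, fit = _cap_subclasses(X_train, y_train, kept, fit, annot, config)
            if not kept or fit is None:
                continue

        X_test = Xt.loc[test_idx, kept]
        pred = fit.intercept + X_test.to_numpy() @ fit.coefficients.to_numpy()
        y_test = y.loc[test_idx].to_numpy()
        ss_res = float(np.sum((y_test - pred) ** 2))
        ss_tot = float(np.sum((y_test - y_test.mean()) ** 2))
        test_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
        if np.std(pred) > 0 and np.std(y_test) > 0:
            test_r = float(np.corrcoef(pred, y_test)[0, 1])
        else:
            test_r = float("nan")

        model = RegressionModel(
            genes=sorted(kept),
            coefficients={g: float(fit.coefficients[g]) for g in sorted(kept)},
            intercept=fit.intercept,
            p_values={g: float(fit.p_values[g]) for g in sorted(kept)},
            lam=float(lam),
            lasso_alpha=config.lasso_alpha,
            split_seed=restart,
            train_r2=fit.r2,
            test_r2=test_r2,
            test_pearson_r=test_r,
            subset_objective=subset_objective(fit.rss, len(kept), lam),
        )
        if best is None or (np.nan_to_num(test_r, nan=-2.0)
                            > np.nan_to_num(best.test_pearson_r, nan=-2.0)):
            best = model

    if best is None:
        raise EmptyModelError(
            "no gene survived selection in any restart (empty model)")
    best.subclass_contributions = subclass_contribution(best, annot)
    return best


def _cap_subclasses(X_train, y_train, kept, fit, annot, config):
    """Optionally keep only the top-k subclasses by contribution (smallest
    product of p-values), then refit."""
    model_stub = RegressionModel(
        genes=sorted(kept),
        coefficients={g: float(fit.coefficients[g]) for g in kept},
        intercept=fit.intercept,
        p_values={g: float(fit.p_values[g]) for g in kept},
        lam=0.0, lasso_alpha=None, split_seed=-1,
        train_r2=fit.r2, test_r2=float("nan"), test_pearson_r=float("nan"),
        subset_objective=float("nan"),
    )
    contrib = subclass_contribution(model_stub, annot)
    top = sorted(contrib, key=lambda s: (contrib[s], s))[: config.max_subclasses]
    top_set = set(top)
    kept2 = [g for g in kept
             if any(s in top_set for s in annot.subclasses_of(g))]
    if not kept2:
        return [], None
    return backward_eliminate(X_train[kept2], y_train,
                              p_threshold=config.p_threshold,
                              drop_all=config.drop_all)
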