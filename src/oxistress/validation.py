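"""Validation of a stress predictor and downstream enrichment analysis.

A predictor is validated by Pearson-correlating its scores with the
expression of gene panels of known anti-oxidative function (fatty-acid
synthesis, mucins, glutathione synthesis), by Welch t-test differential
expression between tumors and controls, and by hypergeometric
over-representation analysis (ORA) of score-co-expressed genes against
user-supplied gene sets with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .regression import transform_expression

logger = logging.getLogger("oxistress")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value.

    p comes from the t transform t = r sqrt((n-2)/(1-r^2)) on n-2 degrees
    of freedom; |r| = 1 gives p = 0. Zero variance in either input is an
    error, never a silent NaN.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(xv)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance input")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return r, p


@dataclass
class ValidationReport:
    """Per-panel correlation of gene expression with the stress score."""

    panel: str
    results: pd.DataFrame      # index gene; columns r, r2, p
    best_gene: str
    best_r: float
    skipped: list[str]         # panel genes absent from the matrix


def panel_validation(scores: pd.Series, expr: pd.DataFrame, panel: str,
                     genes: Sequence[str]) -> ValidationReport:
    """Correlate each panel gene's transformed expression with the score.

    The best gene is the argmax of r (ties broken lexicographically);
    absent genes are listed as skipped, and both r and r^2 are reported.
    """
    present = [g for g in genes if g in expr.index]
    skipped = [g for g in genes if g not in expr.index]
    if not present:
        raise ValueError(f"no panel genes present in expression: {list(genes)}")
    shared = scores.index.intersection(expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    s = scores.loc[shared].to_numpy()
    Xt = transform_expression(expr.loc[present, shared])
    rows = {}
    for g in present:
        r, p = pearson_r(Xt.loc[g].to_numpy(), s)
        rows[g] = {"r": r, "r2": r * r, "p": p}
    results = pd.DataFrame.from_dict(rows, orient="index")
    results.index.name = "gene"
    best_r = results["r"].max()
    best_gene = sorted(results.index[results["r"] == best_r])[0]
    return ValidationReport(panel=panel, results=results, best_gene=best_gene,
                            best_r=float(best_r), skipped=skipped)


def ttest_de(expr: pd.DataFrame, groups: pd.Series,
             alpha: float = 0.05) -> pd.DataFrame:
    """Welch two-sample t-test per gene between tumor and control samples.

    Computed on log2(x+1) expression; returns t, two-sided p and a
    significance flag at the 0.05 cut-off. Each group needs >= 2 samples.
    """
    groups = groups.loc[groups.index.intersection(expr.columns)]
    tumor = groups.index[groups == "tumor"]
    control = groups.index[groups == "control"]
    if len(tumor) < 2 or len(control) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (tumor={len(tumor)}, "
            f"control={len(control)})")
    Xt = transform_expression(expr)
    t, p = scipy.stats.ttest_ind(Xt[tumor], Xt[control], axis=1,
                                 equal_var=False)
    out = pd.DataFrame({"t": t, "p": p}, index=expr.index)
    out["significant"] = out["p"] < alpha
    out.index.name = "gene"
    return out


def coexpressed_genes(scores: pd.Series, expr: pd.DataFrame,
                      r_threshold: float) -> pd.DataFrame:
    """Genes whose transformed expression correlates with the score at
    |r| >= r_threshold, sorted by |r| descending (ties by symbol).

    Zero-variance genes are skipped: they have no defined correlation.
    """
    if not (0 <= r_threshold <= 1):
        raise ValueError("r_threshold must be in [0, 1]")
    shared = scores.index.intersection(expr.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    s = scores.loc[shared].to_numpy(dtype=float)
    if s.std() == 0:
        raise ValueError("score vector has zero variance")
    Xt = transform_expression(expr[shared]).to_numpy(dtype=float)
    Xc = Xt - Xt.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (sc @ sc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Xc @ sc / denom, np.nan)
    out = pd.DataFrame({"r": r}, index=expr.index)
    out = out.dropna()
    out = out[np.abs(out["r"]) >= r_threshold]
    out["abs_r"] = np.abs(out["r"])
    # deterministic order: |r| descending, then gene symbol
    order = np.lexsort((out.index.to_numpy(), -out["abs_r"].to_numpy()))
    out = out.iloc[order]
    out.index.name = "gene"
    return out[["r", "abs_r"]]


def ora(query: Iterable[str], gene_sets: Mapping[str, Sequence[str]],
        universe: Iterable[str], alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each gene set.

    For a universe of N genes, a set of K and a query of n with k genes in
    the set, the one-sided tail P(X >= k) is tested; p-values are
    Benjamini-Hochberg adjusted across sets and flagged at adjusted
    p < 0.05. Sets (and the query) are intersected with the universe.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    outside = query_set - universe_set
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query_set &= universe_set
        if not query_set:
            raise ValueError("query is disjoint from the universe")
    N, n = len(universe_set), len(query_set)
    rows = []
    for name in gene_sets:
        members = set(gene_sets[name]) & universe_set
        K = len(members)
        k = len(members & query_set)
        # survival function at k-1 gives P(X >= k)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "set_size": K, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["p_adj"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    return out
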