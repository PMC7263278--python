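"""Model training: OLS oracle equivalence, Lasso optimality, subset
criterion, backward elimination and planted-support recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import oxistress as ox
from oxistress.regression import (
    RankDeficiencyError,
    best_subset,
    bic_lambda,
    prune_by_subset_objective,
)

from conftest import random_regression_instance


def closed_form_ols(X, y, intercept=True):
    """Independent oracle: normal equations plus the textbook t formula."""
    A = np.column_stack([np.ones(len(X)), X]) if intercept else np.asarray(X)
    b = np.linalg.solve(A.T @ A, A.T @ y)
    resid = np.asarray(y) - A @ b
    rss = float(resid @ resid)
    df = A.shape[0] - A.shape[1]
    sigma2 = rss / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(A.T @ A)))
    t = b / se
    p = 2 * scipy.stats.t.sf(np.abs(t), df)
    return b, p, rss


class TestOlsFit:
    def test_exact_linear_relation(self):
        X = pd.DataFrame({"g": [1.0, 2.0, 3.0]})
        res = ox.ols_fit(X, pd.Series([2.0, 4.0, 6.0]), intercept=False)
        assert res.coefficients["g"] == pytest.approx(2.0, abs=1e-12)
        assert res.rss == pytest.approx(0.0, abs=1e-18)

    def test_orthogonal_response_gives_zero_slope(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # orthogonal to centred x
        res = ox.ols_fit(pd.DataFrame({"g": x}), pd.Series(y), intercept=True)
        assert res.coefficients["g"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_normal_equations_and_t_formula(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_regression_instance(rng, 50, 5)
        res = ox.ols_fit(X, y, intercept=True)
        b, p, rss = closed_form_ols(X.to_numpy(), y.to_numpy())
        assert res.intercept == pytest.approx(b[0], abs=1e-8)
        np.testing.assert_allclose(res.coefficients.to_numpy(), b[1:],
                                   atol=1e-8)
        np.testing.assert_allclose(res.p_values.to_numpy(), p[1:], atol=1e-8)
        assert res.rss == pytest.approx(rss, abs=1e-8)

    def test_rank_deficiency_names_offending_column(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.standard_normal(20)})
        X["b"] = 2 * X["a"]  # exact collinearity
        X["c"] = rng.standard_normal(20)
        with pytest.raises(RankDeficiencyError, match="a|b"):
            ox.ols_fit(X, pd.Series(rng.standard_normal(20)))

    def test_too_few_samples_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(ValueError, match="n > m"):
            ox.ols_fit(X, pd.Series([1.0, 2.0, 3.0]))


def orthonormal_design(rng, n, m):
    """Columns that, after centring and unit-sd scaling, satisfy X'X = nI."""
    raw = rng.standard_normal((n, m))
    raw = raw - raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    X = np.sqrt(n) * q[:, :m]
    return pd.DataFrame(X, columns=[f"g{j}" for j in range(m)])


class TestLassoPath:
    def test_orthonormal_design_soft_thresholds_ols(self, rng):
        X = orthonormal_design(rng, 40, 5)
        y = pd.Series(rng.standard_normal(40))
        yc = y - y.mean()
        ols = X.to_numpy().T @ yc.to_numpy() / 40
        for lam in (0.01, 0.05, 0.2):
            sol = ox.lasso_path(X, y, [lam])[lam]
            expected = np.sign(ols) * np.maximum(np.abs(ols) - lam, 0.0)
            np.testing.assert_allclose(sol.to_numpy(), expected, atol=1e-8)

    def test_all_zero_above_kkt_bound(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 8)),
                         columns=[f"g{j}" for j in range(8)])
        y = pd.Series(rng.standard_normal(60))
        Xs = (X - X.mean()) / X.std(ddof=0)
        yc = (y - y.mean()).to_numpy()
        lam_max = np.max(np.abs(Xs.to_numpy().T @ yc)) / 60
        sol = ox.lasso_path(X, y, [lam_max * 1.0001])
        assert (next(iter(sol.values())) == 0.0).all()

    def test_solution_beats_random_perturbations(self, rng):
        """Local-optimality certificate: the coordinate-descent solution has
        a lower penalised objective than 1,000 random perturbations."""
        n, m = 100, 30
        inst_rng = np.random.default_rng(5)
        X, y = random_regression_instance(inst_rng, n, m)
        lam = 0.1
        sol = ox.lasso_path(X, y, [lam])[lam].to_numpy()
        Xs = ((X - X.mean()) / X.std(ddof=0)).to_numpy()
        yc = (y - y.mean()).to_numpy()

        def objective(b):
            r = yc - Xs @ b
            return (r @ r) / (2 * n) + lam * np.abs(b).sum()

        base = objective(sol)
        for _ in range(1000):
            assert base <= objective(sol + 0.01 * rng.standard_normal(m)) + 1e-10

    def test_empty_grid_rejected(self, rng):
        X, y = random_regression_instance(rng, 20, 3)
        with pytest.raises(ValueError):
            ox.lasso_path(X, y, [])

    def test_support_non_increasing_along_path(self, rng):
        X, y = random_regression_instance(rng, 80, 10, sigma=2.0)
        grid = [0.5, 0.2, 0.1, 0.05, 0.01]
        sols = ox.lasso_path(X, y, grid)
        sizes = [int((sols[l] != 0).sum()) for l in sorted(grid, reverse=True)]
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))


class TestSubsetObjective:
    def test_empty_model(self):
        assert ox.subset_objective(1.0, 0, 0.5) == 1.0

    def test_arithmetic(self):
        assert ox.subset_objective(1.0, 4, 0.25) == 2.0

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            ox.subset_objective(1.0, 1, -0.1)

    def test_exhaustive_search_matches_brute_force_enumeration(self, rng):
        """best_subset agrees with a direct enumeration of all 2^m supports
        scored by lstsq residuals plus the size penalty."""
        n, m = 40, 8
        X, y = random_regression_instance(rng, n, m, sigma=1.5)
        lam = 0.8
        support, obj = best_subset(X, y, lam)

        yv = y.to_numpy()
        best_obj = None
        best_combo = None
        for r in range(m + 1):
            for combo in itertools.combinations(X.columns, r):
                A = np.column_stack([np.ones(n)] +
                                    [X[c].to_numpy() for c in combo])
                resid = yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]
                o = float(resid @ resid) + lam * r
                if best_obj is None or o < best_obj - 1e-12:
                    best_obj, best_combo = o, combo
        assert obj == pytest.approx(best_obj, abs=1e-8)
        assert set(support) == set(best_combo)

    def test_greedy_pruning_never_worse_than_start(self, rng):
        X, y = random_regression_instance(rng, 50, 6, sigma=2.0)
        lam = bic_lambda(X, y)
        start = list(X.columns)
        kept, fit = prune_by_subset_objective(X, y, start, lam)
        full = ox.ols_fit(X, y)
        start_obj = ox.subset_objective(full.rss, len(start), lam)
        if kept:
            end_obj = ox.subset_objective(fit.rss, len(kept), lam)
            assert end_obj <= start_obj + 1e-12


class TestEnzymeAnnotation:
    def test_subclass_extraction_and_multi_ec(self):
        annot = ox.EnzymeAnnotation({"A": ["3.4.21.5"],
                                     "B": ["2.7.1.11", "3.1.3.2"]})
        assert annot.subclasses_of("A") == ["3.4.21"]
        assert annot.subclasses_of("B") == ["2.7.1", "3.1.3"]
        assert set(annot.genes_in_classes(["2"])) == {"B"}
        assert set(annot.genes_in_classes(["2", "3"])) == {"A", "B"}

    def test_malformed_ec_rejected(self):
        with pytest.raises(ValueError):
            ox.EnzymeAnnotation({"A": ["x.4.21"]})


class TestSubclassContribution:
    def _model(self, p_values):
        genes = sorted(p_values)
        return ox.RegressionModel(
            genes=genes, coefficients={g: 1.0 for g in genes}, intercept=0.0,
            p_values=p_values, lam=0.0, lasso_alpha=None, split_seed=0,
            train_r2=1.0, test_r2=1.0, test_pearson_r=1.0,
            subset_objective=0.0)

    def test_single_gene(self):
        annot = ox.EnzymeAnnotation({"A": ["3.4.21.1"]})
        out = ox.subclass_contribution(self._model({"A": 0.03}), annot)
        assert out == {"3.4.21": pytest.approx(0.03)}

    def test_product_of_two(self):
        annot = ox.EnzymeAnnotation({"A": ["2.7.1.1"], "B": ["2.7.1.2"]})
        out = ox.subclass_contribution(self._model({"A": 1e-5, "B": 1e-7}),
                                       annot)
        assert out["2.7.1"] == pytest.approx(1e-12, rel=1e-9)

    def test_matches_direct_product_over_many_genes(self, rng):
        subclasses = ["2.7.1", "3.4.21", "3.1.3", "2.4.1"]
        mapping = {f"G{i}": [f"{subclasses[i % 4]}.{i}"] for i in range(12)}
        p_values = {f"G{i}": float(rng.uniform(1e-8, 0.05)) for i in range(12)}
        annot = ox.EnzymeAnnotation(mapping)
        out = ox.subclass_contribution(self._model(p_values), annot)
        for sub in subclasses:
            direct = 1.0
            for i in range(12):
                if i % 4 == subclasses.index(sub):
                    direct *= p_values[f"G{i}"]
            assert out[sub] == pytest.approx(direct, rel=1e-9)

    def test_multi_ec_gene_enters_every_subclass(self):
        annot = ox.EnzymeAnnotation({"A": ["2.7.1.1", "3.1.3.9"]})
        out = ox.subclass_contribution(self._model({"A": 0.01}), annot)
        assert out == {"2.7.1": pytest.approx(0.01),
                       "3.1.3": pytest.approx(0.01)}


class TestBackwardElimination:
    def test_retained_genes_all_significant(self, rng):
        X, y = random_regression_instance(rng, 120, 10, sigma=3.0)
        kept, fit = ox.backward_eliminate(X, y, p_threshold=0.05)
        if kept:
            assert (fit.p_values <= 0.05).all()

    def test_one_at_a_time_mode_drops_single_worst(self, rng):
        X, y = random_regression_instance(rng, 60, 6, sigma=5.0)
        full = ox.ols_fit(X, y)
        if (full.p_values > 0.05).any():
            kept, _ = ox.backward_eliminate(X, y, drop_all=False)
            # one-at-a-time never removes more than drop-all would keep
            kept_all, _ = ox.backward_eliminate(X, y, drop_all=True)
            assert set(kept_all) >= set()  # both modes terminate
            assert len(kept) <= X.shape[1]


class TestTrainPredictor:
    def test_recovers_planted_support(self):
        d = ox.generate(ox.SyntheticConfig(seed=3))
        rates = ox.mutation_rates(d.variants, list(d.expression.columns))
        annot = ox.EnzymeAnnotation(d.ec_map)
        m = ox.train_predictor(d.expression, rates, annot,
                               ox.TrainConfig(n_restarts=2, seed=1))
        assert set(m.genes) == d.truth.support
        assert max(m.p_values.values()) <= 0.05
        assert m.test_pearson_r > 0.99

    def test_noiseless_case_is_exactly_identified(self):
        d = ox.generate(ox.SyntheticConfig(seed=3, noise_sd=0.0))
        annot = ox.EnzymeAnnotation(d.ec_map)
        m = ox.train_predictor(d.expression, d.truth.latent_stress, annot,
                               ox.TrainConfig(n_restarts=2, seed=1))
        assert m.test_pearson_r == pytest.approx(1.0, abs=1e-9)
        B = d.truth.B_true
        rmse = np.sqrt(np.mean([(m.coefficients.get(g, 0.0) - B[g]) ** 2
                                for g in B]))
        assert rmse <= 1e-6

    def test_training_is_deterministic(self, trained):
        d, rates, annot, model = trained
        tumor = d.metadata.index[d.metadata["group"] == "tumor"]
        again = ox.train_predictor(d.expression[tumor], rates.loc[tumor],
                                   annot, ox.TrainConfig(n_restarts=2, seed=1))
        assert again.to_dict() == model.to_dict()

    def test_subclass_contributions_cover_selected_genes(self, trained):
        d, _, annot, model = trained
        subs = set()
        for g in model.genes:
            subs.update(annot.subclasses_of(g))
        assert set(model.subclass_contributions) == subs

    def test_misaligned_samples_rejected(self):
        d = ox.generate(ox.SyntheticConfig(n_samples=40, n_genes=20, seed=1))
        annot = ox.EnzymeAnnotation(d.ec_map)
        bad = pd.Series(0.01, index=[f"OTHER{i}" for i in range(40)])
        with pytest.raises(ValueError, match="shared samples"):
            ox.train_predictor(d.expression, bad, annot)

    def test_unannotated_expression_is_an_empty_model(self):
        d = ox.generate(ox.SyntheticConfig(n_samples=40, n_genes=20, seed=1))
        rates = ox.mutation_rates(d.variants, list(d.expression.columns))
        with pytest.raises(ox.EmptyModelError):
            ox.train_predictor(d.expression, rates,
                               ox.EnzymeAnnotation({"NOPE": ["1.1.1.1"]}))

    def test_model_json_round_trip(self, trained, tmp_path):
        _, _, _, model = trained
        model.save(tmp_path / "model.json")
        loaded = ox.RegressionModel.load(tmp_path / "model.json")
        assert loaded.to_dict() == model.to_dict()
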