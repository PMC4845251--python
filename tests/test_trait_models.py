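import itertools

import numpy as np
import pandas as pd
import pytest

from swardlab.trait_models import (
    RankDeficientError,
    assemble_matrix,
    best_subset_by_loocv,
    importance_table,
    lmg_importance,
    loocv_mse,
    ols_r2,
    pmvd_importance,
)


def literal_loocv(X, y, cols):
    """Refit-n-times oracle for the closed-form LOO identity."""
    from sklearn.linear_model import LinearRegression

    n = len(y)
    cols = list(cols)
    errs = []
    for i in range(n):
        mask = np.arange(n) != i
        lm = LinearRegression().fit(X[mask][:, cols], y[mask])
        errs.append((y[i] - lm.predict(X[i : i + 1, cols])[0]) ** 2)
    return float(np.mean(errs))


def lmg_permutation_oracle(X, y, subset):
    """Average sequential R^2 increments over explicitly enumerated orderings."""
    k = len(subset)
    shares = np.zeros(k)
    index = {j: i for i, j in enumerate(subset)}
    for perm in itertools.permutations(subset):
        prefix = []
        prev = 0.0
        for j in perm:
            prefix.append(j)
            r2 = ols_r2(X, y, tuple(prefix))
            shares[index[j]] += r2 - prev
            prev = r2
    import math

    return shares / math.factorial(k)


class TestLoocv:
    def test_matches_literal_refit_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = rng.integers(10, 31)
            p = rng.integers(1, 5)
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            cols = tuple(range(p))
            assert loocv_mse(X, y, cols) == pytest.approx(
                literal_loocv(X, y, cols), abs=1e-10, rel=1e-10
            )

    def test_rank_deficient_subset_raises(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 2))
        X = np.column_stack([X[:, 0], X[:, 0]])  # duplicated column
        y = rng.normal(size=15)
        with pytest.raises(RankDeficientError):
            loocv_mse(X, y, (0, 1))


class TestBestSubset:
    def test_exact_linear_dependence_selects_true_predictor(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(size=25)
        x2 = rng.normal(size=25)
        X = np.column_stack([x1, x2])
        y = 2.0 * x1
        rep = best_subset_by_loocv(X, y, max_size=2)
        assert rep.selected == ("x1",)
        assert rep.cv_mse == pytest.approx(0.0, abs=1e-20)
        assert rep.r2 == pytest.approx(1.0)

    def test_pure_noise_flagged_low_r2(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        rep = best_subset_by_loocv(X, y, max_size=2)
        assert rep.low_r2
        # CV error cannot beat the irreducible noise by much
        assert rep.cv_mse >= 0.5 * np.var(y)

    def test_insufficient_rows_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 5))
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="too small"):
            best_subset_by_loocv(X, y, max_size=5)

    def test_winner_matches_exhaustive_enumeration(self):
        """Fixed n=20, 4-predictor instance vs. a hand-rolled search."""
        rng = np.random.default_rng(99)
        X = rng.normal(size=(20, 4))
        y = 1.5 * X[:, 1] - 0.8 * X[:, 3] + rng.normal(scale=0.4, size=20)
        rep = best_subset_by_loocv(X, y, max_size=3)

        best = None
        for k in range(1, 4):
            for cols in itertools.combinations(range(4), k):
                mse = literal_loocv(X, y, cols)
                if best is None or mse < best[0] - 1e-12:
                    best = (mse, cols)
        expected = {f"x{j + 1}" for j in best[1]}
        assert set(rep.selected) == expected
        assert rep.cv_mse == pytest.approx(best[0], rel=1e-9)

    def test_dataframe_columns_named_in_report(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=["WUE", "L.area", "N"])
        y = 2 * X["WUE"].to_numpy() + rng.normal(scale=0.2, size=30)
        rep = best_subset_by_loocv(X, y, max_size=2)
        assert rep.selected[0] == "WUE"


class TestLmg:
    def test_single_predictor_share_is_r2(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 1))
        y = X[:, 0] + rng.normal(scale=0.5, size=30)
        res = lmg_importance(X, y, (0,))
        assert res["raw"][0] == pytest.approx(ols_r2(X, y, (0,)))
        assert res["normalized"][0] == pytest.approx(1.0)

    def test_orthogonal_predictors_get_marginal_r2(self):
        n = 64
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)  # exactly orthogonal, zero mean
        X = np.column_stack([x1, x2])
        y = 3 * x1 + 1 * x2
        res = lmg_importance(X, y, (0, 1))
        assert res["raw"][0] == pytest.approx(ols_r2(X, y, (0,)), abs=1e-10)
        assert res["raw"][1] == pytest.approx(ols_r2(X, y, (1,)), abs=1e-10)

    def test_duplicate_predictors_share_equally(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        X = np.column_stack([x, x.copy()])
        y = x + rng.normal(scale=0.3, size=40)
        res = lmg_importance(X, y, (0, 1))
        assert res["raw"][0] == pytest.approx(res["raw"][1], rel=1e-9)

    def test_shares_sum_to_full_r2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=40)
        res = lmg_importance(X, y, tuple(range(5)))
        assert res["raw"].sum() == pytest.approx(ols_r2(X, y, tuple(range(5))),
                                                 abs=1e-9)
        assert (res["raw"] >= -1e-12).all()
        assert res["normalized"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_permutation_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for k in (2, 3, 4, 5):
            X = rng.normal(size=(35, k))
            y = X @ rng.normal(size=k) + rng.normal(size=35)
            res = lmg_importance(X, y, tuple(range(k)))
            oracle = lmg_permutation_oracle(X, y, tuple(range(k)))
            np.testing.assert_allclose(res["raw"], oracle, atol=1e-10)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=30)
        a = lmg_importance(X, y, (0, 1, 2))
        b = lmg_importance(X[:, ::-1], y, (0, 1, 2))
        np.testing.assert_allclose(a["raw"], b["raw"][::-1], atol=1e-10)

    def test_large_subset_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 9))
        with pytest.raises(ValueError, match="8"):
            lmg_importance(X, X[:, 0], tuple(range(9)))


class TestPmvd:
    def test_single_predictor(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 1))
        y = X[:, 0] + rng.normal(scale=0.5, size=30)
        res = pmvd_importance(X, y, (0,))
        assert res["normalized"][0] == 1.0

    def test_orthogonal_predictors_match_lmg(self):
        n = 64
        t = np.arange(n)
        X = np.column_stack([np.cos(2 * np.pi * t / n), np.sin(2 * np.pi * t / n)])
        y = 3 * X[:, 0] + X[:, 1]
        lmg = lmg_importance(X, y, (0, 1))
        pmvd = pmvd_importance(X, y, (0, 1))
        np.testing.assert_allclose(pmvd["raw"], lmg["raw"], atol=1e-8)

    def test_irrelevant_predictor_share_vanishes(self):
        """A regressor with zero partial contribution: PMVD ~ 0, LMG > 0."""
        rng = np.random.default_rng(12)
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        X = np.column_stack([x1, x2])
        y = x1.copy()  # exact fit through x1 alone
        pmvd = pmvd_importance(X, y, (0, 1))
        lmg = lmg_importance(X, y, (0, 1))
        assert pmvd["raw"][1] == pytest.approx(0.0, abs=1e-6)
        assert lmg["raw"][1] > 1e-4

    def test_shares_sum_to_full_r2(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=40)
        res = pmvd_importance(X, y, tuple(range(4)))
        assert res["raw"].sum() == pytest.approx(ols_r2(X, y, tuple(range(4))),
                                                 abs=1e-9)


@pytest.fixture(scope="module")
def analysis_tables(noisy_dataset):
    """Period metrics, CWM table and partition table for the noisy dataset."""
    from swardlab.community_traits import build_cwm_table
    from swardlab.diversity_effects import partition_per_period
    from swardlab.resource_metrics import build_period_metrics, species_period_table

    ds = noisy_dataset
    sp = species_period_table(ds.design, ds.biomass, ds.traits)
    pm = build_period_metrics(ds.design, ds.biomass, ds.traits, ds.weights,
                              ds.moisture, species_table=sp)
    cw = build_cwm_table(ds.design, sp, pm)
    eff, _ = partition_per_period(ds.biomass, ds.design, ds.pool)
    return pm, cw, eff


class TestAssembleAndReport:
    def test_matrix_shape_and_standardization(self, noisy_dataset, analysis_tables):
        ds = noisy_dataset
        pm, cw, eff = analysis_tables
        matrix = assemble_matrix(cw, eff, pm, ds.design, scope="whole")
        n_mixtures = len(ds.design.compositions(min_richness=2))
        assert matrix.X.shape == (n_mixtures, 10)
        np.testing.assert_allclose(matrix.X.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(matrix.X.std(ddof=0), 1.0, rtol=1e-9)

    def test_whole_scope_averages_periods_brute_force(self, noisy_dataset,
                                                      analysis_tables):
        ds = noisy_dataset
        pm, cw, eff = analysis_tables
        matrix = assemble_matrix(cw, eff, pm, ds.design, scope="whole")

        comp = "dg-tr"
        pots = [p.pot_id for p in ds.design.pots_for_composition(("dg", "tr"))]
        vals = cw[(cw["pot_id"].isin(pots)) & (cw["trait"] == "WUE")]["value"]
        brute = vals.mean()
        col = matrix.standardization.loc["WUE"]
        assert matrix.X.loc[comp, "WUE"] * col["sd"] + col["mean"] == pytest.approx(
            brute, rel=1e-9
        )

    def test_constant_column_rejected(self, noisy_dataset, analysis_tables):
        ds = noisy_dataset
        pm, cw, eff = analysis_tables
        cw = cw.copy()
        cw.loc[cw["trait"] == "WUE", "value"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            assemble_matrix(cw, eff, pm, ds.design, scope="whole")

    def test_importance_table_blocks(self):
        rng = np.random.default_rng(21)
        reports = []
        for resp in ("biomass", "net_effect", "complementarity"):
            X = pd.DataFrame(rng.normal(size=(30, 6)),
                             columns=[f"t{j}" for j in range(6)])
            y = X.iloc[:, 0] * 2 + X.iloc[:, 1] + rng.normal(scale=0.5, size=30)
            reports.append(best_subset_by_loocv(X, y.to_numpy(), max_size=5,
                                                response=resp))
        table = importance_table(reports)
        assert set(table["response"]) == {"biomass", "net_effect", "complementarity"}
        for _, block in table.groupby("response"):
            assert block["pct_r2"].sum() == pytest.approx(100.0, abs=0.1)

    def test_unknown_scope_rejected(self, noisy_dataset, analysis_tables):
        ds = noisy_dataset
        pm, cw, eff = analysis_tables
        with pytest.raises(ValueError, match="scope"):
            assemble_matrix(cw, eff, pm, ds.design, scope="summer")
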