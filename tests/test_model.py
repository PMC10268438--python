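"""Design construction, OLS/Huber fitting and substitution estimation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tuscoda.model import (
    build_design,
    estimate_substitution,
    fit,
    substitution_table,
)
from tuscoda.reallocation import Reallocation, reallocate
from tuscoda.synthetic import SimulationConfig, simulate_cohort
from tuscoda.timeuse import PARTS


@pytest.fixture(scope="module")
def cohort_truth():
    return simulate_cohort(SimulationConfig(seed=42))


@pytest.fixture(scope="module")
def fitted(cohort_truth):
    cohort, _ = cohort_truth
    X, y, labels = build_design(cohort)
    return fit(X, y, labels, method="robust")


class TestBuildDesign:
    def test_shape_and_columns(self, cohort_truth):
        cohort, _ = cohort_truth
        X, y, labels = build_design(cohort)
        # intercept + 3 d_ilr + 3 b_ilr + baseline marker + sex + age
        # + 4 education + zbmi + d_zbmi + 4 pubertal + 2 wear = 22
        assert X.shape == (296, 22)
        assert len(labels) == 22 and y.shape == (296,)
        assert labels[0] == "intercept"
        assert labels[1:4] == ["d_ilr1", "d_ilr2", "d_ilr3"]

    def test_identical_waves_have_zero_ilr_change(self, cohort_truth):
        cohort, _ = cohort_truth
        frozen = cohort.copy()
        for p in PARTS:
            frozen[f"{p}_fu_h"] = frozen[f"{p}_base_h"]
        X, _, labels = build_design(frozen)
        d_cols = [labels.index(f"d_ilr{i+1}") for i in range(3)]
        assert np.abs(X[:, d_cols]).max() < 1e-12

    def test_incomplete_rows_dropped(self, cohort_truth, caplog):
        cohort, _ = cohort_truth
        damaged = cohort.copy()
        damaged.loc[3, "zbmi"] = np.nan
        X, _, _ = build_design(damaged)
        assert X.shape[0] == 295

    def test_unknown_category_rejected(self, cohort_truth):
        cohort, _ = cohort_truth
        bad = cohort.copy()
        bad.loc[0, "maternal_education"] = "phd"
        with pytest.raises(ValueError, match="maternal_education"):
            build_design(bad)

    def test_missing_column_named_in_error(self, cohort_truth):
        cohort, _ = cohort_truth
        with pytest.raises(ValueError, match="zbmi"):
            build_design(cohort.drop(columns=["zbmi"]))


class TestFit:
    @pytest.mark.parametrize("method", ["ols", "robust"])
    def test_noise_free_exact_recovery(self, method):
        cohort, truth = simulate_cohort(SimulationConfig(seed=1, noise_sd=0.0))
        X, y, labels = build_design(cohort)
        fitted = fit(X, y, labels, method=method)
        assert np.abs(fitted.beta - truth.beta.to_numpy()).max() < 1e-8

    def test_unbiased_under_gaussian_noise(self):
        reps = 80
        est = {"ols": [], "robust": []}
        truth_vec = None
        for rep in range(reps):
            cohort, truth = simulate_cohort(SimulationConfig(seed=3000 + rep))
            truth_vec = truth.beta[["d_ilr1", "d_ilr2", "d_ilr3"]].to_numpy()
            X, y, labels = build_design(cohort)
            for method in est:
                f = fit(X, y, labels, method=method)
                est[method].append([f.coef(f"d_ilr{i+1}") for i in range(3)])
        for method, values in est.items():
            values = np.asarray(values)
            mc_se = values.std(axis=0, ddof=1) / np.sqrt(reps)
            bias = values.mean(axis=0) - truth_vec
            assert np.all(np.abs(bias) < 4 * mc_se), (method, bias, mc_se)

    def test_robust_beats_ols_under_contamination(self):
        sq_err = {"ols": [], "robust": []}
        for rep in range(60):
            cohort, truth = simulate_cohort(
                SimulationConfig(seed=5000 + rep, contamination_frac=0.10)
            )
            X, y, labels = build_design(cohort)
            bt = truth.beta[["d_ilr1", "d_ilr2", "d_ilr3"]].to_numpy()
            for method in sq_err:
                f = fit(X, y, labels, method=method)
                b = np.array([f.coef(f"d_ilr{i+1}") for i in range(3)])
                sq_err[method].append(float(((b - bt) ** 2).sum()))
        rmse = {m: np.sqrt(np.mean(v)) for m, v in sq_err.items()}
        assert rmse["robust"] < rmse["ols"]

    def test_agrees_with_statsmodels_rlm(self, cohort_truth):
        sm = pytest.importorskip("statsmodels.api")
        cohort, _ = cohort_truth
        X, y, labels = build_design(cohort)
        mine = fit(X, y, labels, method="robust")
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad")
        scale = np.max(np.abs(ref.params))
        assert np.max(np.abs(mine.beta - ref.params)) / scale < 1e-4
        np.testing.assert_allclose(np.sqrt(np.diag(mine.cov)), ref.bse, rtol=1e-3)

    def test_rank_deficiency_rejected(self, cohort_truth):
        cohort, _ = cohort_truth
        X, y, labels = build_design(cohort)
        X2 = np.hstack([X, X[:, [1]]])
        with pytest.raises(ValueError, match="rank"):
            fit(X2, y, labels + ["dup"])

    def test_more_columns_than_rows_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 6))
        with pytest.raises(ValueError):
            fit(X, rng.normal(size=5), [f"c{i}" for i in range(6)])


class TestEstimateSubstitution:
    def test_shrinks_to_zero_with_duration(self, fitted, cohort_truth):
        _, truth = cohort_truth
        deltas = [
            abs(
                estimate_substitution(
                    fitted, truth.base, Reallocation("sb", "sleep", m)
                ).delta_hat
            )
            for m in (10.0, 1.0, 0.01, 1e-4)
        ]
        assert deltas == sorted(deltas, reverse=True)
        assert deltas[-1] < 1e-4

    def test_path_reversal_identity(self, fitted, cohort_truth):
        _, truth = cohort_truth
        for a, b in itertools.permutations(PARTS, 2):
            fwd = estimate_substitution(fitted, truth.base, Reallocation(a, b, 30.0))
            moved = reallocate(truth.base, Reallocation(a, b, 30.0))
            rev = estimate_substitution(fitted, moved, Reallocation(b, a, 30.0))
            assert fwd.delta_hat == pytest.approx(-rev.delta_hat, abs=1e-10)

    def test_nonlinear_in_duration(self, fitted, cohort_truth):
        _, truth = cohort_truth
        d10 = estimate_substitution(fitted, truth.base, Reallocation("sb", "sleep", 10.0))
        d60 = estimate_substitution(fitted, truth.base, Reallocation("sb", "sleep", 60.0))
        assert d60.delta_hat != pytest.approx(6.0 * d10.delta_hat, rel=1e-6)

    def test_ci_width_nondecreasing_in_duration(self, fitted, cohort_truth):
        _, truth = cohort_truth
        for a, b in itertools.permutations(PARTS, 2):
            widths = []
            for m in (10.0, 30.0, 60.0):
                if truth.base.part_min(a) <= m:
                    continue
                est = estimate_substitution(fitted, truth.base, Reallocation(a, b, m))
                widths.append(est.ci_high - est.ci_low)
            assert widths == sorted(widths)

    def test_infeasible_reallocation_rejected(self, fitted, cohort_truth):
        _, truth = cohort_truth
        with pytest.raises(ValueError):
            estimate_substitution(fitted, truth.base, Reallocation("mvpa", "sb", 70.0))


class TestSubstitutionTable:
    def test_full_grid(self, fitted, cohort_truth):
        _, truth = cohort_truth
        tab = substitution_table(fitted, truth.base)
        assert len(tab) == 36
        assert set(tab["duration_min"]) == {10.0, 30.0, 60.0}

    def test_significance_flag_matches_ci(self, fitted, cohort_truth):
        _, truth = cohort_truth
        tab = substitution_table(fitted, truth.base)
        excludes_zero = ~((tab["ci_low"] <= 0.0) & (tab["ci_high"] >= 0.0))
        assert (tab["significant"] == excludes_zero).all()

    def test_reverse_direction_flips_sign_qualitatively(self, fitted, cohort_truth):
        _, truth = cohort_truth
        tab = substitution_table(fitted, truth.base).set_index(
            ["duration_min", "from", "to"]
        )
        for (m, a, b), row in tab.iterrows():
            if row["significant"] and row["delta"] > 0:
                assert tab.loc[(m, b, a), "delta"] < 0
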