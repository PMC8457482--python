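import numpy as np
import pandas as pd
import pytest

from bearconflict.io import read_use_availability_csv
from bearconflict.rspf import (DesignMatrix, RSPFFit, SeparationError, aic_of,
                               build_design, count_df, eval_w, fit_rspf,
                               neg_log_likelihood)
from conftest import make_use_availability
from oracles import grid_search_mle, naive_use_avail_loglik


def toy_design(seed, n_used=40, n_avail=120, beta=(0.5, 1.2)):
    """One-covariate instance drawn from a known logistic w(x)."""
    rng = np.random.default_rng(seed)
    xs, labels = [], []
    while sum(labels) < n_used or (len(labels) - sum(labels)) < n_avail:
        x = rng.standard_normal()
        if sum(labels) < n_used and rng.random() < eval_w(np.array(beta),
                                                          np.array([1.0, x])):
            xs.append(x)
            labels.append(1)
        elif (len(labels) - sum(labels)) < n_avail:
            xs.append(rng.standard_normal())
            labels.append(0)
    X = np.column_stack([np.ones(len(xs)), xs])
    return DesignMatrix(X, np.array(labels), ["intercept", "x"])


class TestEvalW:
    def test_zero_coefficients_give_one_half(self):
        assert eval_w(np.zeros(3), np.array([1.0, 4.2, -7.0])) == 0.5

    def test_unit_logit_closed_form(self):
        w = eval_w(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert w == pytest.approx(np.e / (1 + np.e), abs=1e-12)

    def test_extreme_negative_logit_is_stable(self):
        w = eval_w(np.array([-800.0]), np.array([1.0]))
        assert 0.0 <= w < 1e-300 or w == 0.0  # no overflow, no NaN
        assert np.isfinite(w)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            eval_w(np.zeros(2), np.zeros(3))

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            eval_w(np.array([np.inf]), np.array([1.0]))

    def test_monotone_in_positively_weighted_covariate(self):
        beta = np.array([0.3, 2.0])
        xs = np.linspace(-3, 3, 20)
        w = eval_w(beta, np.column_stack([np.ones(20), xs]))
        assert np.all(np.diff(w) > 0)


class TestNegLogLikelihood:
    def test_zero_beta_is_exactly_zero(self):
        rng = np.random.default_rng(0)
        used = np.column_stack([np.ones(10), rng.standard_normal(10)])
        avail = np.column_stack([np.ones(30), rng.standard_normal(30)])
        assert neg_log_likelihood(np.zeros(2), used, avail) == 0.0

    def test_identical_used_and_available_point_cancels(self):
        x = np.array([[1.0, 2.5]])
        for beta in ([0.0, 0.0], [1.0, -3.0], [-2.0, 0.7]):
            assert neg_log_likelihood(np.array(beta), x, x) == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_two_loop_summation(self):
        rng = np.random.default_rng(3)
        used = np.column_stack([np.ones(10), rng.standard_normal((10, 2))])
        avail = np.column_stack([np.ones(30), rng.standard_normal((30, 2))])
        beta = rng.standard_normal(3)
        mine = -neg_log_likelihood(beta, used, avail)
        assert mine == pytest.approx(naive_use_avail_loglik(beta, used, avail),
                                     abs=1e-12)

    def test_invariant_to_duplicating_the_availability_sample(self):
        rng = np.random.default_rng(4)
        used = np.column_stack([np.ones(8), rng.standard_normal(8)])
        avail = np.column_stack([np.ones(20), rng.standard_normal(20)])
        beta = np.array([0.4, -1.1])
        once = neg_log_likelihood(beta, used, avail)
        thrice = neg_log_likelihood(beta, used, np.vstack([avail] * 3))
        # identical up to float summation order of the availability mean
        assert once == pytest.approx(thrice, abs=1e-12)

    def test_empty_stratum_rejected(self):
        x = np.array([[1.0, 0.0]])
        with pytest.raises(ValueError, match="nonempty"):
            neg_log_likelihood(np.zeros(2), x[:0], x)


class TestFit:
    def test_matches_dense_grid_search_on_toy_instance(self):
        data = toy_design(seed=5)
        fit = fit_rspf(data, B=0)
        (g0, g1), (s0, s1), _ = grid_search_mle(
            data.used_rows(), data.avail_rows(), (-3.0, 3.0), (-3.0, 3.0))
        assert abs(fit.beta[0] - g0) <= s0
        assert abs(fit.beta[1] - g1) <= s1

    def test_null_data_keeps_slopes_within_two_se(self):
        # used and available drawn from the same distribution: every slope
        # should be a null result in at least 90% of replicates
        ok = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(1200), rng.standard_normal((1200, 2))])
            labels = np.concatenate([np.ones(300, dtype=int), np.zeros(900, dtype=int)])
            data = DesignMatrix(X, labels, ["intercept", "a", "b"])
            # flat null likelihood can drift to the separating ridge; keep the
            # boundary fit (huge estimate, huge bootstrap SE) rather than error
            fit = fit_rspf(data, B=100, seed=seed, on_separation="flag")
            ok += bool(np.all(np.abs(fit.beta[1:]) < 2 * fit.se[1:]))
        assert ok >= 45

    def test_bootstrap_outputs_are_well_formed(self, design):
        fit = fit_rspf(design, B=60, seed=2)
        assert fit.se is not None and np.all(fit.se >= 0)
        assert np.all((0 <= fit.p) & (fit.p <= 1))
        assert fit.B == 60 and fit.m == 0
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)

    def test_bootstrap_is_deterministic_under_fixed_seed(self, design):
        a = fit_rspf(design, B=30, seed=9)
        b = fit_rspf(design, B=30, seed=9)
        np.testing.assert_array_equal(a.se, b.se)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_separation_raises_and_names_the_column(self):
        rng = np.random.default_rng(6)
        # covariate "sep" is strictly positive for used, negative for available
        n = 60
        x = rng.standard_normal(n)
        sep = np.concatenate([rng.uniform(1, 2, 20), rng.uniform(-2, -1, 40)])
        X = np.column_stack([np.ones(n), x, sep])
        labels = np.concatenate([np.ones(20, dtype=int), np.zeros(40, dtype=int)])
        data = DesignMatrix(X, labels, ["intercept", "x", "sep"])
        with pytest.raises(SeparationError, match="sep"):
            fit_rspf(data, B=0)
        fit = fit_rspf(data, B=0, on_separation="flag")
        assert "sep" in fit.boundary_columns

    def test_matching_designs_are_not_supported(self, design):
        with pytest.raises(NotImplementedError):
            fit_rspf(design, B=0, m=1)

    def test_reference_class_is_modal_available_class(self, use_avail_points):
        design = build_design(use_avail_points, ["c0"], cover="cover")
        avail = use_avail_points[use_avail_points["label"] == 0]
        modal = avail["cover"].value_counts().idxmax()
        assert design.reference_class == modal
        assert f"cover={modal}" not in design.column_names


class TestRecoveryAndCoverage:
    def test_slope_recovery_and_bootstrap_ci_coverage(self, std_spec, std_truth):
        """Simulated studies recover every continuous slope within 2 bootstrap
        SEs in >= 90% of replicates, and normal bootstrap 95% CIs cover the
        truth at 95 +/- 5 points pooled over slopes."""
        from bearconflict.simulate import (LandscapeSpec, full_synthetic_study)
        n_reps = 200
        slopes = ["c0", "c1", "c2"]
        truth_vec = np.array([std_truth.betas[s] for s in slopes])
        within_2se = 0
        covered = total = 0
        for rep in range(n_reps):
            spec = LandscapeSpec(std_spec.n_rows, std_spec.n_cols, 50.0,
                                 10_000 + rep,
                                 covariate_defs=std_spec.covariate_defs,
                                 n_cover_classes=std_spec.n_cover_classes)
            study = full_synthetic_study(spec, std_truth)
            pts = make_use_availability(study, 700, seed=20_000 + rep)
            design = build_design(pts, slopes, cover="cover")
            fit = fit_rspf(design, B=200, seed=30_000 + rep)
            est = fit.beta[1:4]
            se = fit.se[1:4]
            if rep < 50:
                within_2se += bool(np.all(np.abs(est - truth_vec) <= 2 * se))
            lo, hi = est - 1.96 * se, est + 1.96 * se
            covered += int(np.sum((lo <= truth_vec) & (truth_vec <= hi)))
            total += len(slopes)
        assert within_2se >= 45
        assert 0.90 <= covered / total <= 1.0


class TestCountDfAndAIC:
    def test_parameter_counts_for_cover_models(self):
        assert count_df(["a", "b", "c", "d", "e", "f", "cover"], 8) == 14
        assert count_df(["a", "b", "c", "d", "e", "f", "g", "cover"], 8) == 15
        assert count_df([], 8) == 1

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            count_df(["mystery"], 8, known_terms={"a", "cover"})

    def test_aic_arithmetic(self):
        fit = RSPFFit(beta=np.zeros(1), se=None, p=None, loglik=0.0, k=1,
                      n_used=1, n_avail=1, column_names=["intercept"])
        assert aic_of(fit) == 2.0
        fit14 = RSPFFit(beta=np.zeros(14), se=None, p=None, loglik=-5141.7,
                        k=14, n_used=1, n_avail=1,
                        column_names=[f"c{i}" for i in range(14)])
        assert aic_of(fit14) == pytest.approx(10311.4)

    def test_unconverged_fit_has_no_aic(self):
        fit = RSPFFit(beta=np.zeros(1), se=None, p=None, loglik=0.0, k=1,
                      n_used=1, n_avail=1, column_names=["intercept"],
                      converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            aic_of(fit)


class TestUseAvailabilityTable:
    def test_binary_conflict_column_round_trip(self, tmp_path, use_avail_points):
        # synthetic table in the published supplementary layout: a binary
        # "Conflict" column plus covariates, coordinates withheld
        table = use_avail_points[["label", "c0", "c1", "c2", "cover"]].rename(
            columns={"label": "Conflict"})
        path = tmp_path / "synthetic_use_availability.csv"
        table.to_csv(path, index=False)
        pts = read_use_availability_csv(path)
        assert list(pts["label"]) == list(use_avail_points["label"])
        design = build_design(pts, ["c0", "c1", "c2"], cover="cover")
        fit = fit_rspf(design, B=0)
        assert fit.converged and np.isfinite(fit.aic)

    def test_nonbinary_label_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"Conflict": [0, 2], "x1": [1.0, 2.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="binary"):
            read_use_availability_csv(path)
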