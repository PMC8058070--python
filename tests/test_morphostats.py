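"""Reliability, accuracy, variance-component and agreement statistics."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.special import gammaln

from densemorph import (
    RepeatedIndications,
    VarianceComponents,
    agreement_stats,
    bland_altman,
    euclidean_accuracy,
    interlandmark_distances,
    multivariate_icc,
    principal_variation_axes,
    reliability_report,
    rms_to_centroid,
    variance_components,
)
from densemorph.errors import MissingLandmarkError, UnbalancedDesignError
from densemorph.landmark_transfer import TransferRecord


class TestRmsToCentroid:
    def test_identical_points_give_zero(self):
        assert rms_to_centroid(np.ones((3, 3))) == 0.0

    def test_two_points_give_half_distance(self):
        pts = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert np.isclose(rms_to_centroid(pts), 1.5)

    def test_matches_termwise_oracle(self, rng):
        pts = rng.normal(size=(7, 3))
        centroid = pts.mean(axis=0)
        expected = np.sqrt(np.mean([np.dot(p - centroid, p - centroid) for p in pts]))
        assert abs(rms_to_centroid(pts) - expected) < 1e-12

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            rms_to_centroid(np.zeros((1, 3)))


def _simulate_indications(L=26, O=3, R=3, sigma=0.5, bias_sd=0.0, seed=0, label="unaltered"):
    g = np.random.default_rng(seed)
    truth = g.normal(scale=30, size=(L, 1, 1, 3))
    bias = g.normal(scale=bias_sd, size=(1, O, 1, 3)) if bias_sd else 0.0
    coords = truth + bias + g.normal(scale=sigma, size=(L, O, R, 3))
    return RepeatedIndications(
        landmarks=tuple(f"lm{i}" for i in range(L)), coords=coords, sample_label=label
    )


class TestReliabilityReport:
    def test_identical_indications_give_zero_everywhere(self):
        ind = _simulate_indications(sigma=1e-30)
        df = reliability_report([ind])
        assert np.allclose(df.to_numpy(), 0.0, atol=1e-12)

    def test_row_structure(self):
        inds = [_simulate_indications(O=7, seed=s) for s in range(2)]
        auto = [np.random.default_rng(s).normal(size=(26, 3, 3)) for s in range(2)]
        df = reliability_report(inds, automatic=auto)
        assert list(df.index) == ["automated", "inter_observer"] + [
            f"intra_observer_{k}" for k in range(1, 8)
        ]
        assert list(df.columns) == ["mean", "ci_low", "ci_high", "std", "min", "max"]

    def test_intra_rms_matches_gaussian_closed_form(self):
        """Unprojected Gaussian noise: E[RMS^2] = 3 sigma^2 (r-1)/r and the
        mean RMS equals sigma * E[chi_{3(r-1)}] / sqrt(r)."""
        sigma, R = 0.5, 3
        rms_vals = []
        for seed in range(200):
            ind = _simulate_indications(L=26, O=2, R=R, sigma=sigma, seed=seed)
            df = reliability_report([ind])
            rms_vals.append(df.loc["intra_observer_1", "mean"])
        k = 3 * (R - 1)
        expected_mean_rms = sigma * np.sqrt(2 / R) * np.exp(
            gammaln((k + 1) / 2) - gammaln(k / 2)
        )
        assert abs(np.mean(rms_vals) - expected_mean_rms) < 0.05 * expected_mean_rms
        assert abs(np.mean(rms_vals) - sigma * np.sqrt(3 * (R - 1) / R)) < 0.1

    def test_observer_bias_raises_inter_over_intra(self):
        inds = [_simulate_indications(O=4, sigma=0.4, bias_sd=0.8, seed=s) for s in range(3)]
        df = reliability_report(inds)
        intra_mean = df.loc[[f"intra_observer_{k}" for k in range(1, 5)], "mean"].mean()
        assert df.loc["inter_observer", "mean"] > intra_mean

    def test_incomplete_design_names_missing_cell(self):
        coords = np.random.default_rng(0).normal(size=(2, 2, 2, 3))
        coords[1, 0, 1] = np.nan
        with pytest.raises(UnbalancedDesignError, match="lm1.*observer 0.*repetition 1"):
            RepeatedIndications(landmarks=("lm0", "lm1"), coords=coords)


class TestPrincipalAxes:
    def test_collinear_deviations(self, rng):
        direction = np.array([1.0, 2.0, -1.0]) / np.sqrt(6)
        devs = rng.normal(size=(50, 1)) * direction
        res = principal_variation_axes(devs)
        assert abs(abs(res.axes[0] @ direction) - 1) < 1e-9
        assert np.allclose(res.variances[1:], 0.0, atol=1e-12)

    def test_isotropic_cloud_has_equal_variances(self, rng):
        devs = rng.normal(size=(20000, 3))
        res = principal_variation_axes(devs)
        assert res.variances[0] / res.variances[2] < 1.1

    def test_variance_sum_equals_mean_squared_norm(self, rng):
        devs = rng.normal(size=(40, 3)) * 2.0
        res = principal_variation_axes(devs)
        assert np.isclose(res.variances.sum(), (devs**2).sum(axis=1).mean())

    def test_degenerate_input_flagged(self):
        res = principal_variation_axes(np.zeros((5, 3)))
        assert res.degenerate
        np.testing.assert_allclose(res.axes @ res.axes.T, np.eye(3), atol=1e-12)


class TestEuclideanAccuracy:
    @staticmethod
    def _records(rng, n_targets=4, landmarks=("a", "b"), cal_equals_ml=False):
        recs = []
        for t in range(n_targets):
            for lm in landmarks:
                ml = rng.normal(size=3)
                cal = ml if cal_equals_ml else ml + rng.normal(scale=0.5, size=3)
                recs.append(
                    TransferRecord(
                        target_id=f"t{t}", landmark=lm, ml=ml, cal=cal, training_ids=()
                    )
                )
        return recs

    def test_perfect_agreement_gives_zeros(self, rng):
        df = euclidean_accuracy(self._records(rng, cal_equals_ml=True))
        assert np.allclose(df.to_numpy(), 0.0)

    def test_single_record_row(self, rng):
        recs = self._records(rng, n_targets=1)
        df = euclidean_accuracy(recs)
        row = df.loc["a"]
        assert row["mean"] == row["min"] == row["max"]
        assert row["std"] == 0.0

    def test_matches_brute_force(self, rng):
        recs = self._records(rng, n_targets=6, landmarks=("a", "b", "c"))
        df = euclidean_accuracy(recs, landmark_order=("a", "b", "c"))
        for lm in ("a", "b", "c"):
            dists = [
                np.linalg.norm(r.ml - r.cal) for r in recs if r.landmark == lm
            ]
            assert np.isclose(df.loc[lm, "mean"], np.mean(dists))
            assert np.isclose(df.loc[lm, "std"], np.std(dists, ddof=1))
            assert np.isclose(df.loc[lm, "min"], np.min(dists))
            assert np.isclose(df.loc[lm, "max"], np.max(dists))
        np.testing.assert_allclose(
            df.loc["average"], df.loc[["a", "b", "c"]].mean(axis=0)
        )

    def test_missing_landmark_rejected(self, rng):
        recs = self._records(rng, n_targets=2)[:-1]  # drop one landmark of t1
        with pytest.raises(MissingLandmarkError, match="t1"):
            euclidean_accuracy(recs)


class TestBlandAltman:
    def test_equal_series_degenerate_at_zero(self):
        res = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert res.mean_difference == res.loa_low == res.loa_high == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 2, 3])
        res = bland_altman(a, a + 2.0)
        assert np.isclose(res.mean_difference, -2.0)
        assert np.isclose(res.loa_low, -2.0) and np.isclose(res.loa_high, -2.0)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 40))
    def test_matches_direct_formula(self, seed, n):
        g = np.random.default_rng(seed)
        a, b = g.normal(size=n), g.normal(size=n)
        res = bland_altman(a, b)
        d = a - b
        assert np.isclose(res.mean_difference, d.mean())
        assert np.isclose(res.loa_low, d.mean() - 1.96 * d.std(ddof=1))
        assert np.isclose(res.loa_high, d.mean() + 1.96 * d.std(ddof=1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2], [1.0])


def simulate_balanced(s2_jaw, s2_obs, s2_err, a, b, m, rng):
    jaw = rng.normal(scale=np.sqrt(s2_jaw), size=(a, 1, 1))
    obs = rng.normal(scale=np.sqrt(s2_obs), size=(1, b, 1))
    method = np.arange(m).reshape(1, 1, m) * 0.3  # fixed effect
    err = rng.normal(scale=np.sqrt(s2_err), size=(a, b, m))
    return 100.0 + jaw + obs + method + err


def reml_oracle(y):
    """Direct numerical REML for the balanced crossed design (independent of
    the ANOVA estimator): maximizes the restricted likelihood of
    V = s2j ZJ ZJ' + s2o ZO ZO' + s2e I with fixed method effects."""
    a, b, m = y.shape
    n = a * b * m
    yv = y.reshape(-1)
    idx = np.indices((a, b, m)).reshape(3, -1)
    ZJ = np.eye(a)[idx[0]]
    ZO = np.eye(b)[idx[1]]
    X = np.column_stack([np.ones(n), *(1.0 * (idx[2] == k) for k in range(1, m))])
    GJ = ZJ @ ZJ.T
    GO = ZO @ ZO.T

    def neg_restricted_loglik(log_params):
        s2j, s2o, s2e = np.exp(log_params)
        V = s2j * GJ + s2o * GO + s2e * np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdetV = 2 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, yv)
        Vi_X = np.linalg.solve(V, X)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        resid = yv - X @ beta
        quad = resid @ np.linalg.solve(V, resid)
        return 0.5 * (logdetV + np.linalg.slogdet(XtViX)[1] + quad)

    start = np.log([max(np.var(yv) / 3, 1e-3)] * 3)
    res = minimize(
        neg_restricted_loglik,
        start,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000, "maxfev": 6000},
    )
    return np.exp(res.x)


class TestVarianceComponents:
    def test_constant_values_give_zero_components(self):
        vc = variance_components(np.full((5, 4, 2), 7.0))
        assert vc.sigma2_jaw == vc.sigma2_observer == vc.sigma2_error == 0.0

    def test_parameter_recovery(self):
        truth = (144.0, 0.8, 0.3)
        est = np.zeros((200, 3))
        for seed in range(200):
            y = simulate_balanced(*truth, 30, 7, 2, np.random.default_rng(seed))
            vc = variance_components(y)
            est[seed] = (vc.sigma2_jaw, vc.sigma2_observer, vc.sigma2_error)
        mean = est.mean(axis=0)
        assert abs(mean[0] - truth[0]) / truth[0] < 0.05
        assert abs(mean[1] - truth[1]) / truth[1] < 0.25
        assert abs(mean[2] - truth[2]) / truth[2] < 0.25

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_direct_reml_on_balanced_data(self, seed):
        y = simulate_balanced(8.0, 3.0, 1.0, 6, 4, 2, np.random.default_rng(seed))
        vc = variance_components(y)
        if vc.truncated:
            pytest.skip("draw hit the parameter-space boundary")
        s2j, s2o, s2e = reml_oracle(y)
        np.testing.assert_allclose(vc.sigma2_jaw, s2j, rtol=1e-5)
        np.testing.assert_allclose(vc.sigma2_observer, s2o, rtol=1e-5)
        np.testing.assert_allclose(vc.sigma2_error, s2e, rtol=1e-5)

    def test_negative_estimates_truncated_and_flagged(self):
        # tiny jaw variance, huge noise: jaw estimate often negative
        for seed in range(20):
            y = simulate_balanced(0.0, 0.0, 5.0, 4, 3, 2, np.random.default_rng(seed))
            vc = variance_components(y)
            assert vc.sigma2_jaw >= 0 and vc.sigma2_observer >= 0
            if vc.truncated:
                return
        pytest.fail("no truncation observed in 20 null draws")

    def test_unbalanced_input_rejected(self):
        y = np.full((4, 3, 2), 1.0)
        y[0, 0, 0] = np.nan
        with pytest.raises(UnbalancedDesignError):
            variance_components(y)


class TestAgreementStats:
    @pytest.mark.parametrize(
        "jaw, obs, err, sem, rc, icc",
        [
            (144.28, 0.8278, 0.284, 0.533, 1.476, 0.998),
            (168.35, 0.6861, 0.4401, 0.663, 1.838, 0.997),
        ],
    )
    def test_worked_examples(self, jaw, obs, err, sem, rc, icc):
        ag = agreement_stats(VarianceComponents(jaw, obs, err))
        assert round(ag.sem, 3) == sem
        assert round(ag.rc, 3) == rc
        assert round(ag.icc, 3) == icc

    def test_noiseless_limit(self):
        ag = agreement_stats(VarianceComponents(10.0, 1.0, 0.0))
        assert ag.sem == 0.0 and ag.rc == 0.0 and ag.icc == 1.0

    def test_rc_is_exact_multiple_of_sem(self):
        ag = agreement_stats(VarianceComponents(5.0, 0.2, 0.7))
        assert ag.rc == 2.77 * ag.sem

    def test_observer_inclusion_option_lowers_icc(self):
        vc = VarianceComponents(144.28, 0.8278, 0.284)
        assert agreement_stats(vc, include_observer=True).icc < agreement_stats(vc).icc

    def test_all_zero_components_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(VarianceComponents(0.0, 0.0, 0.0))


class TestInterlandmarkDistances:
    def test_26_landmarks_give_325_distances(self, rng):
        assert len(interlandmark_distances(rng.normal(size=(26, 3)))) == 325

    def test_unit_triangle(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        np.testing.assert_allclose(interlandmark_distances(pts), [1.0, 1, 1])

    def test_matches_double_loop_oracle_and_rigid_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.normal(size=(26, 3)) * 25
        d = interlandmark_distances(pts)
        oracle = [
            np.linalg.norm(pts[i] - pts[j])
            for i in range(26)
            for j in range(i + 1, 26)
        ]
        np.testing.assert_allclose(d, oracle, atol=1e-12)
        R = Rotation.random(random_state=1).as_matrix()
        np.testing.assert_allclose(
            interlandmark_distances(pts @ R.T + 5.0), d, atol=1e-9
        )


class TestMultivariateICC:
    def test_perfect_agreement_gives_one(self, rng):
        X = rng.normal(size=(10, 325))
        assert np.isclose(multivariate_icc(X, X), 1.0)

    def test_dimension_one_matches_univariate_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        subj = rng.normal(scale=3, size=20)
        x = subj + rng.normal(scale=1, size=20)
        y = subj + 0.5 + rng.normal(scale=1, size=20)
        ours = multivariate_icc(x[:, None], y[:, None])
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(20), 2),
                "rater": np.repeat(["m1", "m2"], 20),
                "score": np.concatenate([x, y]),
            }
        )
        icc2 = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(A,1)", "ICC"]
        assert np.isclose(ours, icc2, atol=1e-9)

    def test_null_simulation_stays_low(self):
        vals = []
        for seed in range(200):
            g = np.random.default_rng(seed)
            vals.append(multivariate_icc(g.normal(size=(30, 325)), g.normal(size=(30, 325))))
        assert np.mean(vals) <= 0.1

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            multivariate_icc(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))
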