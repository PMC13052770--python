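import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motisyn.errors import ConfigError, DegenerateInputError
from motisyn.msd_models import (
    MODELS,
    MSDCurve,
    TrackClassification,
    aicc,
    classify_track,
    compute_msd,
    derive_motility,
    eval_model,
    fit_model,
    fit_power_law,
    truncate_for_fit,
)

from .conftest import make_track


def brute_force_msd(positions, frame_interval):
    """Independent oracle: explicit double loop over overlapping pairs."""
    n = len(positions)
    lags, msd, n_pairs = [], [], []
    for k in range(1, n):
        sq = []
        for i in range(n - k):
            dx = positions[i + k][0] - positions[i][0]
            dy = positions[i + k][1] - positions[i][1]
            sq.append(dx * dx + dy * dy)
        lags.append(k * frame_interval)
        msd.append(np.mean(np.array(sq)))
        n_pairs.append(n - k)
    return np.array(lags), np.array(msd), np.array(n_pairs)


def curve_from_model(name, params, lags, track_id="synthetic"):
    values = eval_model(name, params, lags)
    n_pairs = np.arange(len(lags), 0, -1) + 3
    return MSDCurve(track_id=track_id, lags=lags, msd=values, n_pairs=n_pairs)


class TestComputeMsd:
    def test_worked_example(self):
        track = make_track([(0, 0), (1, 0), (2, 0), (3, 0)])
        curve = compute_msd(track)
        np.testing.assert_allclose(curve.lags, [1, 2, 3])
        np.testing.assert_allclose(curve.msd, [1, 4, 9])
        np.testing.assert_array_equal(curve.n_pairs, [3, 2, 1])

    def test_stationary(self):
        track = make_track([(5, 5)] * 6)
        assert np.all(compute_msd(track).msd == 0)

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 51))
            pos = np.cumsum(rng.normal(0, 1, size=(n, 2)), axis=0)
            track = make_track(pos, frame_interval=2.0)
            curve = compute_msd(track)
            lags, msd, n_pairs = brute_force_msd(pos, 2.0)
            np.testing.assert_array_equal(curve.msd, msd)
            np.testing.assert_array_equal(curve.lags, lags)
            np.testing.assert_array_equal(curve.n_pairs, n_pairs)

    def test_max_lag_fraction(self):
        track = make_track([(float(i), 0.0) for i in range(11)])
        curve = compute_msd(track, max_lag_fraction=0.4)
        assert len(curve.lags) == 4

    def test_too_short(self):
        with pytest.raises(DegenerateInputError):
            compute_msd(make_track([(0, 0), (1, 0)]))

    def test_rejects_gaps(self):
        track = make_track([(0, 0), (1, 0), (2, 0)], times=[0.0, 1.0, 3.0])
        with pytest.raises(DegenerateInputError, match="gap"):
            compute_msd(track)


class TestTruncate:
    def test_forty_percent_of_19(self):
        curve = curve_from_model("brownian", [1.0], np.arange(1.0, 20.0))
        assert truncate_for_fit(curve, 0.4).fitted_window == 7

    def test_forty_percent_of_100(self):
        curve = curve_from_model("brownian", [1.0], np.arange(1.0, 101.0))
        assert truncate_for_fit(curve, 0.4).fitted_window == 40

    def test_clamped_to_minimum(self):
        curve = curve_from_model("brownian", [1.0], np.arange(1.0, 6.0))
        assert truncate_for_fit(curve, 0.4).fitted_window == 4

    def test_too_short(self):
        curve = curve_from_model("brownian", [1.0], np.arange(1.0, 4.0))
        with pytest.raises(DegenerateInputError):
            truncate_for_fit(curve)


class TestEvalModel:
    def test_brownian_closed_form(self):
        assert eval_model("brownian", [1.0], [2.0])[0] == pytest.approx(8.0)

    def test_constrained_plateau(self):
        val = eval_model("constrained", {"Dc": 1.0, "R": 10.0}, [1e6])[0]
        assert val == pytest.approx(100.0, rel=1e-6)

    def test_constrained_initial_slope(self):
        # tau -> 0: MSD ~ 4 Dc tau
        tau = 1e-6
        val = eval_model("constrained", {"Dc": 2.0, "R": 10.0}, [tau])[0]
        assert val == pytest.approx(8.0 * tau, rel=1e-4)

    def test_prw_ballistic_limit(self):
        val = eval_model("prw", {"v": 2.0, "tau_p": 5.0}, [0.01])[0]
        assert val == pytest.approx(4.0e-4, rel=1e-3)

    def test_prw_diffusive_slope(self):
        # slope for tau >= 100 tau_p within 1% of 2 v^2 tau_p
        v, tp = 3.0, 2.0
        taus = np.array([200 * tp, 200 * tp + 1.0])
        vals = eval_model("prw", {"v": v, "tau_p": tp}, taus)
        slope = (vals[1] - vals[0]) / (taus[1] - taus[0])
        assert slope == pytest.approx(2 * v**2 * tp, rel=1e-2)

    def test_prw_small_ratio_relative_error(self):
        v, tp = 5.0, 10.0
        for tau in (tp / 100, tp / 1e4, tp / 1e6):
            val = eval_model("prw", {"v": v, "tau_p": tp}, [tau])[0]
            assert val == pytest.approx(v**2 * tau**2, rel=1e-2)

    def test_stability_extreme_arguments(self):
        taus = np.array([1e-6, 1e-3, 1.0, 1e3, 1e6])
        for name, params in (
            ("constrained", {"Dc": 1.0, "R": 1.0}),
            ("prw", {"v": 1.0, "tau_p": 1.0}),
        ):
            vals = eval_model(name, params, taus)
            assert np.all(np.isfinite(vals))
            assert np.all(vals >= 0)

    def test_powerlaw(self):
        assert eval_model("powerlaw", {"A": 3.0, "alpha": 2.0}, [2.0])[0] == 12.0

    def test_rejects_nonpositive_params(self):
        with pytest.raises(ConfigError):
            eval_model("brownian", [0.0], [1.0])
        with pytest.raises(ConfigError):
            eval_model("prw", [1.0, -1.0], [1.0])


class TestAicc:
    def test_hand_arithmetic_k1(self):
        assert aicc(10.0, 10, 1) == pytest.approx(2.5)

    def test_hand_arithmetic_k2(self):
        assert aicc(10.0, 10, 2) == pytest.approx(4 + 12 / 7)

    def test_denominator_guard(self):
        with pytest.raises(DegenerateInputError):
            aicc(10.0, 3, 2)

    def test_zero_rss_sentinel(self):
        assert aicc(0.0, 10, 2) == -math.inf

    @given(
        rss=st.floats(1e-6, 1e6),
        n=st.integers(6, 200),
        k=st.integers(1, 3),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_k_and_rss(self, rss, n, k):
        assert aicc(rss, n, k + 1) > aicc(rss, n, k)
        assert aicc(rss * 1.5, n, k) > aicc(rss, n, k)


class TestFitModel:
    def test_brownian_self_recovery(self):
        lags = np.arange(1.0, 21.0)
        curve = truncate_for_fit(curve_from_model("brownian", [1.0], lags))
        fit = fit_model(curve, "brownian")
        assert fit.converged
        assert fit.params["D"] == pytest.approx(1.0, rel=1e-6)
        assert fit.exact_fit
        assert fit.aicc == -math.inf

    def test_prw_self_recovery(self):
        lags = 2.0 * np.arange(1.0, 50.0)
        curve = truncate_for_fit(curve_from_model("prw", [5.0, 10.0], lags))
        fit = fit_model(curve, "prw")
        assert fit.params["v"] == pytest.approx(5.0, rel=1e-4)
        assert fit.params["tau_p"] == pytest.approx(10.0, rel=1e-4)

    def test_constrained_self_recovery(self):
        lags = 2.0 * np.arange(1.0, 50.0)
        curve = truncate_for_fit(curve_from_model("constrained", [1.0, 15.0], lags))
        fit = fit_model(curve, "constrained")
        assert fit.params["Dc"] == pytest.approx(1.0, rel=1e-4)
        assert fit.params["R"] == pytest.approx(15.0, rel=1e-4)

    def test_powerlaw_on_brownian_curve(self):
        lags = np.arange(1.0, 30.0)
        curve = truncate_for_fit(curve_from_model("brownian", [1.0], lags))
        fit = fit_power_law(curve)
        assert fit.params["alpha"] == pytest.approx(1.0, rel=1e-6)
        assert fit.params["A"] == pytest.approx(4.0, rel=1e-6)

    def test_powerlaw_on_ballistic_curve(self):
        lags = np.arange(1.0, 30.0)
        curve = MSDCurve(
            track_id="ballistic",
            lags=lags,
            msd=4.0 * lags**2,
            n_pairs=np.full(len(lags), 5),
            fitted_window=11,
        )
        fit = fit_power_law(curve)
        assert fit.params["alpha"] == pytest.approx(2.0, rel=1e-5)

    def test_powerlaw_on_saturating_window(self):
        # constrained curve sampled into saturation yields alpha < 1
        lags = 2.0 * np.arange(1.0, 40.0)
        curve = curve_from_model("constrained", [1.0, 5.0], lags)
        curve = truncate_for_fit(curve, 1.0)
        fit = fit_power_law(curve)
        assert fit.params["alpha"] < 1.0

    def test_window_too_small_for_model(self):
        curve = curve_from_model("brownian", [1.0], np.arange(1.0, 6.0))
        curve = truncate_for_fit(curve)
        curve.fitted_window = 3
        with pytest.raises(DegenerateInputError):
            fit_model(curve, "prw")


class TestClassify:
    def test_brownian_curve(self):
        lags = 2.0 * np.arange(1.0, 40.0)
        cls = classify_track(curve_from_model("brownian", [1.0], lags))
        assert cls.best_model == "brownian"
        assert cls.delta_aicc["brownian"] == 0.0
        assert all(v >= 0 for v in cls.delta_aicc.values())

    def test_constrained_curve(self):
        lags = 2.0 * np.arange(1.0, 40.0)
        cls = classify_track(curve_from_model("constrained", [1.0, 10.0], lags))
        assert cls.best_model == "constrained"

    def test_ballistic_track_is_prw(self):
        track = make_track([(2.0 * i, 0.0) for i in range(30)], frame_interval=1.0)
        curve = truncate_for_fit(compute_msd(track))
        cls = classify_track(curve)
        assert cls.best_model == "prw"
        assert cls.persistence_speed is not None

    def test_prw_fields_absent_otherwise(self):
        lags = 2.0 * np.arange(1.0, 40.0)
        cls = classify_track(curve_from_model("brownian", [2.0], lags))
        assert cls.persistence_speed is None
        assert cls.persistence_time is None


class TestDeriveMotility:
    def _cls(self, best, params, rmc=None):
        return TrackClassification(
            track_id="t",
            best_model=best,
            delta_aicc={},
            params_best=params,
            rmc=rmc,
        )

    def test_brownian_identity(self):
        rec = derive_motility(self._cls("brownian", {"D": 1.5}, rmc=1.5))
        assert rec.rmc == pytest.approx(1.5)
        assert rec.effective_coefficient == pytest.approx(1.5)

    def test_prw_effective(self):
        rec = derive_motility(self._cls("prw", {"v": 2.0, "tau_p": 3.0}, rmc=1.0))
        assert rec.effective_coefficient == pytest.approx(6.0)

    def test_constrained_identity(self):
        rec = derive_motility(self._cls("constrained", {"Dc": 0.8, "R": 9.0}, rmc=1.0))
        assert rec.effective_coefficient == pytest.approx(0.8)

    def test_missing_fit_flagged(self):
        rec = derive_motility(self._cls("unclassified", {}))
        assert rec.rmc is None
        assert "missing_brownian_fit" in rec.flags
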