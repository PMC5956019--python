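"""Curve fitting: saturation K_d, competition IC50, one-phase decay, r^2.

The recovery/coverage studies reuse the simulators so noiseless round trips
are exact and noisy ones are checked at the study's stated sample sizes.
"""

import numpy as np
import pytest

import mstkit as mk
from mstkit.errors import DataError, DomainError, FlatCurveError, NotDecayingError


def saturation_series(kd=7.65, top_final=50.0, tracer=0.25, seed=None, exclude_top=False):
    noise = (
        mk.TraceNoiseModel(noise_cv=0.0, bleach_rate=0.0)
        if seed is None
        else mk.TraceNoiseModel(rng_seed=seed)
    )
    design = mk.TitrationDesign.from_top_final(top_final, tracer_final=tracer)
    traces = mk.simulate_saturation_run(design, kd=kd, noise=noise)
    pts = mk.traces_to_points(traces, exclude_top_point=exclude_top)
    return mk.TitrationSeries(mk.Mode.SATURATION, pts, tracer_total=tracer)


def flat_series(mode, n=16):
    pts = [
        mk.FnormPoint(titrant_conc=float(2**i) / 100, fnorm=1000.0, cold_mean=1000.0)
        for i in range(n)
    ]
    return mk.TitrationSeries(mode, pts, tracer_total=0.25, antibody_sites=10.0)


class TestFitSaturation:
    def test_noiseless_recovery_is_exact(self):
        fit = mk.fit_saturation(saturation_series(kd=7.65))
        assert fit.estimate == pytest.approx(7.65, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)
        assert fit.fnorm_unbound == pytest.approx(1000.0, abs=1e-4)
        assert fit.fnorm_bound == pytest.approx(950.0, abs=1e-4)

    def test_flat_series_raises_flat_curve_error(self):
        with pytest.raises(FlatCurveError):
            mk.fit_saturation(flat_series(mk.Mode.SATURATION))

    def test_point_order_invariance(self):
        series = saturation_series(kd=4.58, seed=3)
        rev = mk.TitrationSeries(
            mk.Mode.SATURATION, tuple(reversed(series.points)), tracer_total=0.25
        )
        assert mk.fit_saturation(series).estimate == pytest.approx(
            mk.fit_saturation(rev).estimate, rel=1e-9
        )

    def test_affine_fnorm_rescaling_preserves_estimate(self):
        series = saturation_series(kd=4.58, seed=3)
        scaled_pts = [
            mk.FnormPoint(p.titrant_conc, 3.0 * p.fnorm + 100.0, p.cold_mean, p.qc_flags)
            for p in series.points
        ]
        scaled = mk.TitrationSeries(mk.Mode.SATURATION, scaled_pts, tracer_total=0.25)
        f0, f1 = mk.fit_saturation(series), mk.fit_saturation(scaled)
        assert f1.estimate == pytest.approx(f0.estimate, rel=1e-6)
        assert f1.fnorm_unbound == pytest.approx(3.0 * f0.fnorm_unbound + 100.0, rel=1e-6)

    @pytest.mark.parametrize("kd_true", [0.5, 5.0, 50.0, 500.0])
    def test_recovery_and_ci_coverage_across_decades(self, kd_true):
        """16-point 1:1 titration at default noise: median |relative error|
        below 15% and 95% CI coverage within [88%, 99%] (200 seeds)."""
        top = 6.5 * kd_true  # same top/Kd ratio as the serum design
        errs, cover, n = [], 0, 200
        for s in range(n):
            fit = mk.fit_saturation(
                saturation_series(kd=kd_true, top_final=top, seed=s)
            )
            errs.append(abs(fit.estimate - kd_true) / kd_true)
            cover += fit.ci95[0] <= kd_true <= fit.ci95[1]
        assert np.median(errs) < 0.15
        assert 0.88 <= cover / n <= 0.99


class TestFitCompetition:
    def test_noiseless_logistic_data_recovered_exactly(self):
        ell = np.geomspace(0.1, 4000.0, 16)
        ic50, b, u = 12.0, 950.0, 1000.0
        y = b + (u - b) * ell / (ell + ic50)
        pts = [mk.FnormPoint(c, v, 1000.0) for c, v in zip(ell, y)]
        series = mk.TitrationSeries(mk.Mode.COMPETITION, pts, tracer_total=0.25, antibody_sites=10.0)
        fit = mk.fit_competition(series)
        assert fit.estimate == pytest.approx(ic50, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("ki_true", [1.60, 2.27])
    def test_noiseless_ternary_round_trip_recovers_ki(self, ki_true, standard_competition_design, noiseless):
        """Full generator -> fitter -> converter loop on the heroin
        competition design recovers K_i within 2% without noise."""
        traces = mk.simulate_competition_run(
            standard_competition_design, kd_tracer=7.65, ki=ki_true, noise=noiseless
        )
        pts = mk.traces_to_points(traces)
        series = mk.TitrationSeries(
            mk.Mode.COMPETITION, pts, tracer_total=0.25, antibody_sites=10.0, tracer_kd=7.65
        )
        fit = mk.fit_competition(series)
        l0 = max(p.titrant_conc for p in pts)
        ki = mk.ki_from_ic50(7.65, 10.0, 0.25, l0, fit.estimate)
        assert ki == pytest.approx(ki_true, rel=0.02)

    def test_flat_series_raises_flat_curve_error(self):
        with pytest.raises(FlatCurveError):
            mk.fit_competition(flat_series(mk.Mode.COMPETITION))

    def test_upper_plateau_only_warns_extrapolated(self):
        # all sampled concentrations far below the IC50: only the bound
        # plateau with the first hint of displacement is seen
        ell = np.geomspace(0.1, 100.0, 12)
        ic50 = 1e4
        y = 950.0 + 50.0 * ell / (ell + ic50)
        pts = [mk.FnormPoint(c, v, 1000.0) for c, v in zip(ell, y)]
        series = mk.TitrationSeries(mk.Mode.COMPETITION, pts, tracer_total=0.25, antibody_sites=10.0)
        fit = mk.fit_competition(series)
        assert "EXTRAPOLATED_IC50" in fit.warnings


class TestFitOnePhaseDecay:
    def test_exact_model_data(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
        y = 100.0 * np.exp(-np.log(2.0) * t)
        fit = mk.fit_one_phase_decay(t, y)
        assert fit.t_half == pytest.approx(1.0, rel=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_half_life(self):
        fit = mk.fit_one_phase_decay([0.0, 1.0], [100.0, 50.0])
        assert fit.k == pytest.approx(np.log(2.0), abs=1e-9)

    def test_increasing_series_rejected(self):
        with pytest.raises(NotDecayingError):
            mk.fit_one_phase_decay([0.0, 1.0, 2.0, 3.0], [10.0, 20.0, 40.0, 80.0])

    def test_ci_range_brackets_half_life_on_noisy_data(self):
        rng = np.random.default_rng(0)
        t = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0])
        y = 100.0 * np.exp(-np.log(2.0) / 0.42 * t) * (1 + 0.05 * rng.standard_normal(t.shape))
        fit = mk.fit_one_phase_decay(t, y)
        lo, hi = fit.t_half_ci99
        assert lo < fit.t_half < hi

    def test_rate_bias_small_at_default_noise(self):
        """Simulator round trip: mean fitted k within 2% of truth (500 seeds)."""
        k_true = np.log(2.0) / 0.42
        ks = []
        for s in range(500):
            course = mk.simulate_degradation_course(
                mk.Condition.PRE_IMMUNE, 4000.0, 0.0, 1.0, k_true,
                [0, 0.25, 0.5, 1, 2, 3], seed=s,
            )
            pct = mk.percent_heroin(course.concentrations, course.heroin_initial)
            ks.append(mk.fit_one_phase_decay(course.times, pct).k)
        assert abs(np.mean(ks) - k_true) / k_true < 0.02


class TestGoodnessOfFit:
    def test_perfect_and_null_predictions(self):
        obs = [1.0, 2.0, 3.0]
        assert mk.goodness_of_fit(obs, obs) == 1.0
        assert mk.goodness_of_fit(obs, [2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert mk.goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            mk.goodness_of_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            mk.goodness_of_fit([1.0, 2.0], [1.0, 2.0, 3.0])
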