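import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ripvent as rv
from conftest import make_belts, sinusoid_belts
from ripvent.config import CalibrationConfig, OCFConfig
from ripvent.correction import _k_of_t, fit_ocf_params


class TestPowerlossObjective:
    def test_identical_signals_give_one_for_every_k(self):
        d = np.cos(np.linspace(0, 20, 500))
        for k in (0.0, 0.3, 0.5, 0.9, 1.0):
            assert rv.powerloss_objective(k, d, d) == pytest.approx(1.0)

    def test_perfect_cancellation(self):
        d = np.cos(np.linspace(0, 20, 500))
        assert rv.powerloss_objective(0.5, d, -d) == pytest.approx(0.0, abs=1e-12)

    def test_proportional_antiphase_closed_form(self):
        # dab = -2 dth, k = 0.2: |1 - k(1+c)| / (1 - k + k c) = 0.4 / 1.2
        d = np.cos(np.linspace(0, 20, 500))
        got = rv.powerloss_objective(0.2, d, -2 * d)
        assert got == pytest.approx(abs(1 - 3 * 0.2) / 1.2, abs=1e-12)

    def test_domain_and_degenerate_errors(self):
        d = np.cos(np.linspace(0, 20, 500))
        with pytest.raises(ValueError):
            rv.powerloss_objective(1.2, d, d)
        with pytest.raises(ValueError):
            rv.powerloss_objective(0.5, np.zeros(10), np.zeros(10))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0), st.integers(0, 2 ** 31 - 1),
           st.floats(0.1, 100.0))
    def test_bounded_and_scale_invariant(self, k, seed, scale):
        rng = np.random.default_rng(seed)
        dth = rng.normal(size=64)
        dab = rng.normal(size=64)
        v = rv.powerloss_objective(k, dth, dab)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert rv.powerloss_objective(k, scale * dth, scale * dab) == \
            pytest.approx(v, abs=1e-9)


class TestFitPowerlossK:
    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0, 4.0])
    def test_antiphase_proportional_recovers_closed_form(self, c):
        belts = sinusoid_belts(duration=120.0, ab_gain=-c)
        k, obj, fallback = rv.fit_powerloss_k(belts, (0.0, 120.0))
        assert not fallback
        assert k == pytest.approx(1.0 / (1.0 + c), abs=0.01)
        assert obj < 0.05

    def test_identical_belts_fall_back(self):
        belts = sinusoid_belts(duration=120.0)
        k, _, fallback = rv.fit_powerloss_k(belts, (0.0, 120.0))
        assert fallback
        assert k == CalibrationConfig().fallback_k

    def test_too_short_interval_errors(self):
        belts = sinusoid_belts(duration=60.0)
        with pytest.raises(ValueError):
            rv.fit_powerloss_k(belts, (10.0, 10.05))


class TestMovements:
    def _steady(self, duration=600.0, step_at=None, step_size=0.0):
        t = np.arange(0.0, duration, 0.04)
        x = np.sin(2 * np.pi * 0.25 * t)
        base = np.where(t >= step_at, step_size, 0.0) if step_at else 0.0
        return make_belts(x + base, x + base)

    def test_stationary_signal_has_no_movements(self):
        belts = self._steady()
        breaths = rv.detect_breaths_rip(belts)
        assert rv.detect_movements(belts, breaths) == []

    def test_20x_step_detected_once(self):
        # median tidal volume of a unit sinusoid is 2 (peak-to-peak)
        belts = self._steady(step_at=300.0, step_size=40.0)
        breaths = rv.detect_breaths_rip(belts)
        moves = rv.detect_movements(belts, breaths)
        assert len(moves) == 1
        assert abs(moves[0] - 300.0) < 10.0

    def test_10x_step_is_subthreshold(self):
        belts = self._steady(step_at=300.0, step_size=20.0)
        breaths = rv.detect_breaths_rip(belts)
        assert rv.detect_movements(belts, breaths) == []

    def test_fewer_than_20_breaths_gives_single_period(self):
        belts = self._steady(duration=60.0)
        breaths = rv.detect_breaths_rip(belts)
        assert len(breaths) < 20
        periods = rv.segment_calibration_periods(belts, breaths)
        assert len(periods) == 1


class TestCalibrationPeriods:
    def test_periods_are_contiguous_and_cover_recording(self):
        belts = sinusoid_belts(duration=300.0)
        breaths = rv.detect_breaths_rip(belts)
        periods = rv.segment_calibration_periods(
            belts, breaths, movements=[100.0, 200.0])
        assert len(periods) == 3
        assert periods[0].start_s == 0.0
        assert periods[-1].end_s == pytest.approx(300.0)
        for a, b in zip(periods[:-1], periods[1:]):
            assert a.end_s == b.start_s

    def test_fallback_periods_inherit_previous_k(self):
        t = np.arange(0.0, 400.0, 0.04)
        x = np.sin(2 * np.pi * 0.25 * t)
        ab = np.where(t < 200.0, -2.0 * x, x)   # paradox first, in-phase after
        belts = make_belts(x, ab)
        breaths = rv.detect_breaths_rip(belts)
        periods = rv.segment_calibration_periods(
            belts, breaths, movements=[200.0])
        assert not periods[0].fallback
        assert periods[0].k == pytest.approx(1.0 / 3.0, abs=0.02)
        assert periods[1].fallback
        assert periods[1].k == periods[0].k


class TestCalibrateFlow:
    def test_k_half_identity(self):
        belts = sinusoid_belts(duration=60.0)
        periods = [rv.CalibrationPeriod(0.0, 60.0, 0.5, 0.0, False)]
        fs = rv.calibrate_flow(belts, periods)
        t = fs.volume.times()
        ref = np.sin(2 * np.pi * 0.25 * t)
        assert np.abs(fs.volume.samples - ref)[50:-50].max() < 0.02
        w = 2 * np.pi * 0.25
        assert np.abs(fs.flow.samples - w * np.cos(w * t))[50:-50].max() < 0.05

    def test_isovolume_cancellation(self):
        belts = sinusoid_belts(duration=60.0, ab_gain=-2.0)
        periods = [rv.CalibrationPeriod(0.0, 60.0, 1.0 / 3.0, 0.0, False)]
        fs = rv.calibrate_flow(belts, periods)
        assert np.abs(fs.volume.samples[50:-50]).max() < 0.02

    def test_crossfade_keeps_flow_bounded(self):
        belts = sinusoid_belts(duration=120.0)
        periods = [rv.CalibrationPeriod(0.0, 60.0, 0.3, 0.0, False),
                   rv.CalibrationPeriod(60.0, 120.0, 0.7, 0.0, False)]
        fs = rv.calibrate_flow(belts, periods)
        within = np.abs(fs.flow.samples[100:1300]).max()
        near_boundary = np.abs(fs.flow.samples[1400:1600]).max()
        assert near_boundary < 3.0 * within
        k = _k_of_t(periods, belts.times(), 2.0)
        assert np.all(np.abs(np.diff(k)) < 0.02)   # no k jump larger than one
                                                   # crossfade increment


class TestOCF:
    def test_printed_defaults(self):
        # direct evaluation of the squared-logistic form at the published
        # x0 = 0.034, k = 31.0, y_min = 0.22
        assert rv.ocf(1.0) == pytest.approx(1.0, abs=1e-3)
        assert rv.ocf(0.0) == pytest.approx(1.0, abs=1e-3)
        L = 1.0 / (1.0 + np.exp(31.0 * 0.034))
        assert rv.ocf(-1.0) == pytest.approx(0.78 * L ** 2 + 0.22, abs=1e-9)
        assert rv.ocf(-1.0) == pytest.approx(0.272, abs=0.001)

    @pytest.mark.parametrize("form", [1, 2])
    def test_monotone_and_bounded(self, form):
        params = OCFConfig(exponent_form=form)
        r = np.linspace(-1.0, 1.0, 2001)
        g = rv.ocf(r, params)
        assert np.all(np.diff(g) >= -1e-12)
        assert g[-1] >= 0.999
        assert np.all(g >= params.y_min * 0.9)
        assert np.all(g <= 1.001)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            rv.ocf(1.5)

    def test_apply_identity_when_all_in_phase(self):
        belts = sinusoid_belts(duration=60.0)
        breaths = rv.detect_breaths_rip(belts)
        fs = rv.benchmark_2to1(belts)
        out = rv.apply_ocf(fs, breaths)
        assert np.allclose(out.flow.samples, fs.flow.samples)
        assert np.all(out.breath_gains > 0.999)

    def test_apply_is_local_to_the_paradoxical_breath(self):
        belts = sinusoid_belts(duration=60.0)
        breaths = rv.detect_breaths_rip(belts)
        breaths[5].paradox_r = -1.0
        fs = rv.benchmark_2to1(belts)
        out = rv.apply_ocf(fs, breaths)
        gain = rv.ocf(-1.0)
        b = breaths[5]
        i0 = fs.flow.index_at(b.onset_s) + 1
        i1 = fs.flow.index_at(b.end_s) - 1
        ratio = out.flow.samples[i0:i1] / np.where(
            fs.flow.samples[i0:i1] == 0, 1, fs.flow.samples[i0:i1])
        assert np.allclose(ratio[np.abs(fs.flow.samples[i0:i1]) > 1e-6], gain)
        j0 = fs.flow.index_at(breaths[2].onset_s) + 1
        j1 = fs.flow.index_at(breaths[2].end_s) - 1
        assert np.allclose(out.flow.samples[j0:j1], fs.flow.samples[j0:j1])


class TestFitOCFParams:
    def test_recovers_generating_curve(self):
        rng = np.random.default_rng(0)
        r = np.clip(rng.uniform(-1.0, 1.0, 3000), -1, 1)
        ratio = rv.ocf(r)
        fit = fit_ocf_params(r, ratio)
        grid = np.linspace(-1, 1, 201)
        assert np.abs(rv.ocf(grid, fit) - rv.ocf(grid)).max() < 0.02

    def test_flat_ratio_fits_constant_one(self):
        rng = np.random.default_rng(1)
        r = rng.uniform(-1.0, 1.0, 2000)
        fit = fit_ocf_params(r, np.ones_like(r))
        grid = np.linspace(-1, 1, 201)
        assert np.abs(rv.ocf(grid, fit) - 1.0).max() < 0.02

    def test_noisy_deciles_stay_close(self):
        # r distribution as in real nights: a paradoxical cluster near -1
        # and a synchronous cluster near +1, so the deciles cover the knee
        rng = np.random.default_rng(2)
        r = np.concatenate([np.clip(rng.normal(-0.95, 0.08, 1500), -1, 1),
                            np.clip(rng.normal(0.9, 0.15, 3500), -1, 1)])
        ratio = rv.ocf(r) + rng.normal(0.0, 0.05, r.size)
        fit = fit_ocf_params(r, ratio)
        grid = np.linspace(-1, 1, 201)
        assert np.abs(rv.ocf(grid, fit) - rv.ocf(grid)).max() < 0.1

    def test_degenerate_r_errors(self):
        with pytest.raises(ValueError):
            fit_ocf_params(np.full(100, 0.3), np.ones(100))


class TestPowerLaw:
    def test_fixed_points_and_printed_values(self):
        assert rv.apply_power_law(100.0) == pytest.approx(100.0, abs=1e-12)
        assert rv.apply_power_law(0.0) == 0.0
        assert rv.apply_power_law(50.0) == pytest.approx(100 * 0.5 ** 1.17,
                                                         abs=1e-9)
        assert rv.apply_power_law(150.0) == pytest.approx(100 * 1.5 ** 1.17,
                                                          abs=1e-9)

    def test_strictly_increasing(self):
        v = np.linspace(0.0, 300.0, 1000)
        out = rv.apply_power_law(v)
        assert np.all(np.diff(out) > 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            rv.apply_power_law(-1.0)


class TestBenchmark:
    def test_in_phase_identity(self):
        belts = sinusoid_belts(duration=60.0)
        fs = rv.benchmark_2to1(belts)
        t = fs.volume.times()
        assert np.abs(fs.volume.samples - np.sin(2 * np.pi * 0.25 * t))[50:-50].max() < 0.02

    def test_antiphase_residual_not_cancelled(self):
        # thorax = sin, abdomen = -2 sin: 2:1 mixing leaves -sin
        belts = sinusoid_belts(duration=60.0, ab_gain=-2.0)
        fs = rv.benchmark_2to1(belts)
        t = fs.volume.times()
        assert np.abs(fs.volume.samples + np.sin(2 * np.pi * 0.25 * t))[50:-50].max() < 0.02
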