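import numpy as np
import pytest

from ripvent.concordance import BreathPair, bland_altman, binned_agreement, \
    bootstrap_delta_icc, icc_2_1, pair_breaths, stratified_errors
from ripvent.config import StatsConfig

from test_events import series_from_pct


class TestPairing:
    def test_identical_grids_fully_matched(self):
        a = series_from_pct([100.0] * 50)
        pairs, dropped = pair_breaths(a, a)
        assert len(pairs) == 50
        assert dropped == 0

    def test_missing_reference_breath_drops_one(self):
        test = series_from_pct([100.0] * 50)
        ref_pct = [100.0] * 49
        ref = series_from_pct(ref_pct)
        # reference stops 4 s early: its last breath has no partner
        pairs, dropped = pair_breaths(test, ref)
        assert len(pairs) == 49
        assert dropped == 1

    def test_small_time_shift_still_matches(self):
        test = series_from_pct([100.0] * 50)
        shifted = series_from_pct([100.0] * 50)
        shifted.time_s = shifted.time_s + 0.5
        pairs, dropped = pair_breaths(test, shifted)
        assert len(pairs) == 50
        assert dropped == 0


class TestStratifiedErrors:
    def test_constructed_small_breaths(self):
        pairs = [BreathPair(0, 62.0, 50.0), BreathPair(4, 70.0, 60.0),
                 BreathPair(8, 77.0, 65.0)]
        out = stratified_errors(pairs)
        assert out["small"]["n"] == 3
        # per-pair biases are {12, 10, 12}
        assert out["small"]["median_bias"] == pytest.approx(12.0)
        assert "large" not in out

    def test_identity_has_zero_errors(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 300, 200)
        pairs = [BreathPair(i, v, v) for i, v in enumerate(vals)]
        out = stratified_errors(pairs)
        for s in out.values():
            assert s["median_bias"] == 0.0
            assert s["median_abs_error"] == 0.0

    def test_relative_excludes_tiny_reference_only(self):
        pairs = [BreathPair(0, 10.0, 3.0)] + \
                [BreathPair(i, 55.0, 50.0) for i in range(1, 6)]
        out = stratified_errors(pairs)
        assert out["small"]["n"] == 6                      # absolute keeps it
        assert out["small"]["median_relative_bias_pct"] == pytest.approx(10.0)

    def test_strata_partition_and_order_invariance(self):
        rng = np.random.default_rng(1)
        pairs = [BreathPair(i, float(t), float(r)) for i, (t, r) in
                 enumerate(rng.uniform(0, 300, (300, 2)))]
        out = stratified_errors(pairs)
        n = sum(out[s]["n"] for s in ("small", "medium", "large") if s in out)
        assert n == out["all"]["n"] == 300
        shuffled = list(pairs)
        rng.shuffle(shuffled)
        assert stratified_errors(shuffled) == out

    def test_boundaries_are_medium(self):
        cfg = StatsConfig()
        assert BreathPair(0, 0, 70.0).stratum(cfg) == "medium"
        assert BreathPair(0, 0, 130.0).stratum(cfg) == "medium"
        assert BreathPair(0, 0, 69.9).stratum(cfg) == "small"
        assert BreathPair(0, 0, 130.1).stratum(cfg) == "large"


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert icc_2_1(x, x) == pytest.approx(1.0)

    def test_offset_reduces_icc_monotonically(self):
        x = np.arange(20.0)
        vals = [icc_2_1(x, x + c) for c in (0.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert abs(icc_2_1(x, y)) < 0.1

    def test_matches_pingouin_on_random_tables(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        for _ in range(25):
            x = rng.normal(size=5)
            y = x + rng.normal(scale=0.5, size=5)
            df = pd.DataFrame({
                "targets": np.repeat(np.arange(5), 2),
                "raters": np.tile(["a", "b"], 5),
                "ratings": np.column_stack([x, y]).ravel(),
            })
            ref = pingouin.intraclass_corr(
                df, targets="targets", raters="raters", ratings="ratings")
            # two-way random, absolute agreement, single rater
            want = float(ref.loc[ref.Type.isin(["ICC2", "ICC(A,1)"]),
                                 "ICC"].iloc[0])
            assert icc_2_1(x, y) == pytest.approx(want, abs=1e-10)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            icc_2_1(np.full(5, 3.0), np.full(5, 3.0))


class TestBootstrapDeltaICC:
    def test_identical_methods_give_zero_delta(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        y = x + rng.normal(scale=0.3, size=100)
        out = bootstrap_delta_icc((x, y), (x, y), n_boot=500, seed=5)
        assert out["delta_icc"] == 0.0
        assert out["ci_low"] <= 0.0 <= out["ci_high"]

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        ya = x + rng.normal(scale=0.2, size=80)
        yb = x + rng.normal(scale=1.0, size=80)
        a = bootstrap_delta_icc((x, ya), (x, yb), n_boot=1000, seed=11)
        b = bootstrap_delta_icc((x, ya), (x, yb), n_boot=1000, seed=11)
        assert a == b

    def test_better_method_is_significant(self):
        rng = np.random.default_rng(2)
        truth = rng.normal(size=200)
        low_noise = truth + rng.normal(scale=0.2, size=200)
        high_noise = truth + rng.normal(scale=1.5, size=200)
        out = bootstrap_delta_icc((truth, low_noise), (truth, high_noise),
                                  n_boot=2000, seed=3)
        assert out["significant"]
        assert out["ci_low"] > 0

    def test_small_n_boot_warns(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning):
            bootstrap_delta_icc((x, x), (x, x), n_boot=50, seed=0)


class TestBlandAltman:
    def test_identity(self):
        x = np.arange(10.0)
        out = bland_altman(x, x)
        assert out["bias"] == 0.0
        assert out["loa_low"] == out["loa_high"] == 0.0

    def test_constant_offset(self):
        x = np.arange(10.0)
        out = bland_altman(x + 5.0, x)
        assert out["bias"] == pytest.approx(5.0)
        assert out["loa_low"] == pytest.approx(5.0)
        assert out["loa_high"] == pytest.approx(5.0)

    def test_normal_differences_match_1p96_sd(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=10_000)
        x = y + rng.normal(size=10_000)
        out = bland_altman(x, y)
        assert out["loa_low"] == pytest.approx(-1.96, abs=0.1)
        assert out["loa_high"] == pytest.approx(1.96, abs=0.1)


class TestBinnedAgreement:
    def test_uniform_coverage_fills_every_bin(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.0, 300.0, 5000)
        pairs = [BreathPair(i, v, v) for i, v in enumerate(vals)]
        out = binned_agreement(pairs, 10.0, 30, "mean")
        assert len(out) == 30
        assert all(b["median_error"] == 0.0 for b in out)

    def test_known_mixture_median(self):
        pairs = [BreathPair(0, 1.0, 5.0), BreathPair(1, 2.0, 5.0),
                 BreathPair(2, 3.0, 5.0)]
        out = binned_agreement(pairs, 10.0, 1, "reference")
        assert len(out) == 1
        assert out[0]["median"] == 2.0

    def test_bad_convention_rejected(self):
        with pytest.raises(ValueError):
            binned_agreement([], 10.0, 10, "nonsense")
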