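"""Agreement statistics between a test and a reference ventilation series.

Covers the comparison battery used to validate belt-derived ventilation
against a pneumotach reference: breath pairing, stratified median bias /
median absolute error (small / medium / large breaths), ICC(2,1),
bootstrap confidence intervals for paired ICC differences, Bland-Altman
bias and limits of agreement, and binned agreement curves for plotting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import StatsConfig
from .events import RespiratoryEvent
from .ventilation import VentilationSeries

log = logging.getLogger(__name__)


@dataclass
class BreathPair:
    time_s: float
    test: float        # %eupnea, method under evaluation
    reference: float   # %eupnea, gold standard

    def stratum(self, cfg: StatsConfig) -> str:
        if self.reference < cfg.small_max:
            return "small"
        if self.reference > cfg.large_min:
            return "large"
        return "medium"


def pair_breaths(test: VentilationSeries, reference: VentilationSeries,
                 tolerance_s: float = 2.0) -> tuple[list[BreathPair], int]:
    """Greedy one-to-one matching of breaths by midpoint proximity.

    Candidate matches are taken closest-first within ``tolerance_s``;
    unmatched breaths on either side are dropped.  Returns the pairs and the
    number of dropped breaths.
    """
    ti = np.asarray(test.time_s)
    ri = np.asarray(reference.time_s)
    cands = []
    for i, t in enumerate(ti):
        j0 = np.searchsorted(ri, t - tolerance_s, side="left")
        j1 = np.searchsorted(ri, t + tolerance_s, side="right")
        for j in range(j0, j1):
            cands.append((abs(t - ri[j]), i, j))
    cands.sort()
    used_i, used_j = set(), set()
    pairs = []
    for _, i, j in cands:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append(BreathPair(float(ti[i]), float(test.percent_eupnea[i]),
                                float(reference.percent_eupnea[j])))
    pairs.sort(key=lambda p: p.time_s)
    dropped = (len(ti) - len(pairs)) + (len(ri) - len(pairs))
    return pairs, dropped


def stratified_errors(pairs: list[BreathPair],
                      cfg: StatsConfig | None = None) -> dict:
    """Median bias and median absolute error per breath-size stratum.

    Bias is test minus reference.  Relative errors (percent of reference)
    exclude pairs whose reference is below ``relative_floor`` %eupnea; the
    absolute summaries keep them.  Empty strata are reported as absent.
    """
    cfg = cfg or StatsConfig()
    out: dict = {}
    by = {"small": [], "medium": [], "large": [], "all": []}
    for p in pairs:
        by[p.stratum(cfg)].append(p)
        by["all"].append(p)
    for name, ps in by.items():
        if not ps:
            continue
        bias = np.array([p.test - p.reference for p in ps])
        ref = np.array([p.reference for p in ps])
        rel_ok = ref >= cfg.relative_floor
        entry = {
            "n": len(ps),
            "median_bias": float(np.median(bias)),
            "median_abs_error": float(np.median(np.abs(bias))),
        }
        if rel_ok.any():
            rel = 100.0 * bias[rel_ok] / ref[rel_ok]
            entry["median_relative_bias_pct"] = float(np.median(rel))
            entry["median_relative_abs_error_pct"] = float(np.median(np.abs(rel)))
        out[name] = entry
    return out


# ---------------------------------------------------------------------------
# ICC


def icc_2_1(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    From the two-way ANOVA mean squares over n targets and 2 raters:
    ICC = (MSR - MSE) / (MSR + MSE + 2 * (MSC - MSE) / n).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    data = np.column_stack([x, y])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sst = np.sum((data - grand) ** 2)
    sse = sst - k * np.sum((row_means - grand) ** 2) - n * np.sum((col_means - grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero total variance; ICC undefined")
    return float((msr - mse) / denom)


def bootstrap_delta_icc(pairs_a: tuple[np.ndarray, np.ndarray],
                        pairs_b: tuple[np.ndarray, np.ndarray],
                        n_boot: int = 10_000, seed: int = 0,
                        ci: float = 95.0) -> dict:
    """Paired bootstrap CI for ICC(A) - ICC(B) over shared targets.

    Targets (rows) are resampled with replacement; both methods are
    evaluated on the same resample in each of ``n_boot`` replicates.
    Deterministic under a fixed seed.
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable CIs", stacklevel=2)
    xa, ya = (np.asarray(v, float) for v in pairs_a)
    xb, yb = (np.asarray(v, float) for v in pairs_b)
    if xa.size != xb.size:
        raise ValueError("methods must share the same targets")
    n = xa.size
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    deltas.fill(np.nan)
    for it in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            deltas[it] = icc_2_1(xa[idx], ya[idx]) - icc_2_1(xb[idx], yb[idx])
        except ValueError:
            continue
    deltas = deltas[np.isfinite(deltas)]
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(deltas, [alpha, 100.0 - alpha])
    point = icc_2_1(xa, ya) - icc_2_1(xb, yb)
    return {
        "delta_icc": float(point),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "significant": bool(lo > 0),
        "n_boot": int(n_boot),
        "n_targets": int(n),
        "seed": int(seed),
    }


# ---------------------------------------------------------------------------
# Bland-Altman and binned curves


def bland_altman(x, y) -> dict:
    """Bias and 95% limits of agreement for differences d = test - reference.

    Emits both x-axis conventions: the reference value (primary) and the
    mean of the two methods (supplementary).
    """
    x = np.asarray(x, float)   # test
    y = np.asarray(y, float)   # reference
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length inputs with n >= 2")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "sd": sd,
        "reference_axis": np.column_stack([y, d]),
        "mean_axis": np.column_stack([(x + y) / 2.0, d]),
    }


def binned_agreement(pairs: list[BreathPair], bin_step: float, n_bins: int,
                     x_convention: str = "mean", x_start: float = 0.0) -> list[dict]:
    """Per-bin medians and percentile envelopes of the test values.

    ``x_convention`` is "mean" (mean of the two methods, used for
    breath-level plots) or "reference" (used for event-level plots).
    Empty bins are omitted.
    """
    if x_convention not in ("mean", "reference"):
        raise ValueError("x_convention must be 'mean' or 'reference'")
    xs = np.array([(p.test + p.reference) / 2.0 if x_convention == "mean"
                   else p.reference for p in pairs])
    ys = np.array([p.test for p in pairs])
    refs = np.array([p.reference for p in pairs])
    out = []
    for b in range(n_bins):
        lo = x_start + b * bin_step
        m = (xs >= lo) & (xs < lo + bin_step)
        if not m.any():
            continue
        q = np.percentile(ys[m], [25, 50, 75, 90])
        err = ys[m] - refs[m]
        out.append({
            "bin_low": lo, "bin_high": lo + bin_step, "n": int(m.sum()),
            "median": float(q[1]), "q25": float(q[0]), "q75": float(q[2]),
            "p90": float(q[3]), "median_error": float(np.median(err)),
        })
    return out


# ---------------------------------------------------------------------------
# event-level agreement


def event_depths_on_series(events: list[RespiratoryEvent],
                           vent: VentilationSeries) -> np.ndarray:
    """Depth of each reference-scored event interval evaluated on ``vent``.

    Mirrors the validation design where events are scored on the reference
    signal and the test method's depth is measured over the same interval:
    the nadir is the minimum %eupnea among test breaths whose midpoints fall
    inside [start_s, end_s).
    """
    depths = np.empty(len(events))
    mids = vent.time_s
    for i, ev in enumerate(events):
        m = (mids >= ev.start_s) & (mids < ev.end_s)
        if not m.any():   # no test breath in the interval: nearest breath
            j = int(np.argmin(np.abs(mids - 0.5 * (ev.start_s + ev.end_s))))
            m = np.zeros(len(mids), bool)
            m[j] = True
        nadir = float(np.min(vent.percent_eupnea[m]))
        depths[i] = np.clip(100.0 - nadir, 0.0, 100.0)
    return depths


@dataclass
class ConcordanceReport:
    """Bundle of every agreement statistic for one test/reference run."""

    breath_errors: dict
    n_pairs: int
    n_dropped: int
    event_bias: float | None = None
    event_mae: float | None = None
    event_icc: float | None = None
    bland_altman_events: dict | None = None
    binned_breaths: list = field(default_factory=list)
    binned_events: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [clean(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v
        return clean(self.__dict__)


def compare_series(test: VentilationSeries, reference: VentilationSeries,
                   ref_events: list[RespiratoryEvent] | None = None,
                   cfg: StatsConfig | None = None) -> ConcordanceReport:
    """Full breath- and event-level concordance of test vs reference."""
    cfg = cfg or StatsConfig()
    pairs, dropped = pair_breaths(test, reference, cfg.pair_tolerance_s)
    report = ConcordanceReport(
        breath_errors=stratified_errors(pairs, cfg),
        n_pairs=len(pairs), n_dropped=dropped,
        binned_breaths=binned_agreement(pairs, 10.0, 30, "mean"),
    )
    if ref_events:
        d_test = event_depths_on_series(ref_events, test)
        d_ref = np.array([e.depth for e in ref_events])
        report.event_bias = float(np.mean(d_test - d_ref))
        report.event_mae = float(np.mean(np.abs(d_test - d_ref)))
        if len(ref_events) >= 3:
            report.event_icc = icc_2_1(d_test, d_ref)
            report.bland_altman_events = {
                k: v for k, v in bland_altman(d_test, d_ref).items()
                if not isinstance(v, np.ndarray)
            }
        ev_pairs = [BreathPair(e.start_s, float(t), float(r))
                    for e, t, r in zip(ref_events, d_test, d_ref)]
        report.binned_events = binned_agreement(ev_pairs, 3.5, 20,
                                                "reference", x_start=30.0)
    return report
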