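"""Single-cell calcium trace metrics: amplitude, FWHM duration, AUC.

Raw fluorescence is normalized per cell as (F/F0) - 1 against the
pre-stimulus baseline; the three metrics are computed on the normalized
trace. Group-level summaries apply a single-pass mean +/- 2 SD outlier
filter per metric, then optional per-experiment normalization of condition
means (maximum condition mean = 1 for each metric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import DataError

__all__ = [
    "CalciumTrace",
    "NormalizedTrace",
    "TraceFeatures",
    "MetricStats",
    "ConditionSummary",
    "METRICS",
    "normalize_trace",
    "peak_amplitude",
    "width_at_half_max",
    "area_under_curve",
    "extract_features",
    "remove_outliers",
    "summarize_condition",
    "amplitude_duration_relation",
]

METRICS = ("amplitude", "duration", "auc")

DEFAULT_BASELINE_WINDOW_S = 5.0


@dataclass(frozen=True)
class CalciumTrace:
    """One cell's raw fluorescence time series plus stimulus metadata."""

    time: np.ndarray
    fluorescence: np.ndarray
    stimulus_time: float
    cell_id: str
    experiment_id: str
    concentration: float  # molar; 0 for vehicle

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.shape != f.shape:
            raise DataError("time and fluorescence must be 1-D and equal length")
        dt = np.diff(t)
        if t.size < 3 or np.any(dt <= 0):
            raise DataError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise DataError("time must be uniformly sampled")
        if np.count_nonzero(t < self.stimulus_time) < 2:
            raise DataError("need >= 2 samples before stimulus_time")
        if np.any(f <= 0) or np.any(~np.isfinite(f)):
            raise DataError("fluorescence must be finite and > 0")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "fluorescence", f)

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class NormalizedTrace:
    """Baseline-normalized response (F/F0) - 1 with its provenance."""

    time: np.ndarray
    response: np.ndarray
    baseline_f0: float
    stimulus_time: float
    cell_id: str = ""
    experiment_id: str = ""
    concentration: float = 0.0


@dataclass(frozen=True)
class TraceFeatures:
    """Per-cell response metrics; duration is NaN for non-responding cells."""

    amplitude: float
    duration: float
    auc: float
    truncated: bool
    cell_id: str = ""
    experiment_id: str = ""
    concentration: float = 0.0


@dataclass(frozen=True)
class MetricStats:
    mean: float
    sd: float
    sem: float
    n: int
    n_outliers_removed: int


@dataclass(frozen=True)
class ConditionSummary:
    """Summary statistics per (experiment, concentration) condition."""

    experiment_id: str
    concentration: float
    metrics: Dict[str, MetricStats]


def normalize_trace(
    trace: CalciumTrace, baseline_window: float = DEFAULT_BASELINE_WINDOW_S
) -> NormalizedTrace:
    """Divide by the mean pre-stimulus fluorescence and subtract 1.

    The baseline F0 is the mean fluorescence over the ``baseline_window``
    seconds immediately preceding the stimulus (all pre-stimulus samples
    that fall inside it; at least 2 required).
    """
    mask = (trace.time < trace.stimulus_time) & (
        trace.time >= trace.stimulus_time - baseline_window
    )
    if np.count_nonzero(mask) < 2:
        raise DataError("baseline window must contain >= 2 pre-stimulus samples")
    f0 = float(np.mean(trace.fluorescence[mask]))
    if f0 <= 0:
        raise DataError(f"baseline F0 must be > 0, got {f0}")
    return NormalizedTrace(
        time=trace.time,
        response=trace.fluorescence / f0 - 1.0,
        baseline_f0=f0,
        stimulus_time=trace.stimulus_time,
        cell_id=trace.cell_id,
        experiment_id=trace.experiment_id,
        concentration=trace.concentration,
    )


def _post_stimulus(trace: NormalizedTrace) -> Tuple[np.ndarray, np.ndarray]:
    mask = trace.time >= trace.stimulus_time
    if not np.any(mask):
        raise DataError("no samples at or after stimulus_time")
    return trace.time[mask], trace.response[mask]


def peak_amplitude(trace: NormalizedTrace) -> float:
    """Maximal post-stimulus rise of the normalized response."""
    _, r = _post_stimulus(trace)
    return float(np.max(r))


def _interp_crossing(t0, r0, t1, r1, level):
    # linear interpolation of the time where the response crosses `level`
    return t0 + (level - r0) * (t1 - t0) / (r1 - r0)


def width_at_half_max(trace: NormalizedTrace) -> Tuple[float, bool]:
    """Width of the response at half its peak, by linear interpolation.

    Measured between the first upward crossing of peak/2 preceding the peak
    (scanning forward from the stimulus) and the first downward crossing
    after the peak. If the response never falls back below half maximum the
    width runs to the end of the trace and the truncated flag is set.
    """
    t, r = _post_stimulus(trace)
    peak_idx = int(np.argmax(r))
    peak = float(r[peak_idx])
    if peak <= 0:
        raise DataError("width undefined: non-positive peak amplitude")
    half = peak / 2.0

    # first upward crossing at or before the peak
    t_up = t[0]
    if r[0] < half:
        for i in range(peak_idx):
            if r[i] < half <= r[i + 1]:
                t_up = _interp_crossing(t[i], r[i], t[i + 1], r[i + 1], half)
                break
    # first downward crossing after the peak
    for i in range(peak_idx, len(r) - 1):
        if r[i] >= half > r[i + 1]:
            t_down = _interp_crossing(t[i], r[i], t[i + 1], r[i + 1], half)
            return float(t_down - t_up), False
    return float(t[-1] - t_up), True


def area_under_curve(trace: NormalizedTrace) -> float:
    """Trapezoidal integral of the response from the stimulus to trace end.

    Negative excursions are included, not clipped.
    """
    t, r = _post_stimulus(trace)
    return float(np.trapezoid(r, t))


def extract_features(
    trace: CalciumTrace, baseline_window: float = DEFAULT_BASELINE_WINDOW_S
) -> TraceFeatures:
    """Normalize one trace and compute its three metrics."""
    norm = normalize_trace(trace, baseline_window)
    amp = peak_amplitude(norm)
    if amp > 0:
        duration, truncated = width_at_half_max(norm)
    else:
        duration, truncated = float("nan"), False
    return TraceFeatures(
        amplitude=amp,
        duration=duration,
        auc=area_under_curve(norm),
        truncated=truncated,
        cell_id=trace.cell_id,
        experiment_id=trace.experiment_id,
        concentration=trace.concentration,
    )


def remove_outliers(values: Sequence[float]) -> Tuple[np.ndarray, List[int]]:
    """Single-pass mean +/- 2 SD filter (sample SD, ddof=1).

    Values strictly outside the band are dropped. Returns the kept values
    and the indices of the removed ones. Fewer than 3 values is a no-op
    with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise DataError("values must be 1-D")
    if v.size < 3:
        warnings.warn("fewer than 3 values: outlier filter skipped", stacklevel=2)
        return v.copy(), []
    mean = v.mean()
    sd = v.std(ddof=1)
    lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    removed = [i for i, x in enumerate(v) if x < lo or x > hi]
    kept = np.delete(v, removed)
    return kept, removed


def _metric_values(feats: List[TraceFeatures], metric: str) -> np.ndarray:
    return np.array([getattr(f, metric) for f in feats], dtype=float)


def summarize_condition(
    features: Sequence[TraceFeatures],
    normalize_within_experiment: bool = False,
) -> List[ConditionSummary]:
    """Summarize features per (experiment, concentration) condition.

    Per metric and condition: drop NaNs (cells without a defined duration),
    apply the outlier filter, then report mean, SD, SEM and counts. With
    ``normalize_within_experiment`` each metric's statistics are divided by
    the maximum condition mean of that metric within the same experiment,
    so the largest condition mean becomes exactly 1.
    """
    groups: Dict[Tuple[str, float], List[TraceFeatures]] = {}
    for f in features:
        groups.setdefault((f.experiment_id, f.concentration), []).append(f)

    summaries: List[ConditionSummary] = []
    for (exp, conc) in sorted(groups, key=lambda k: (k[0], k[1])):
        feats = groups[(exp, conc)]
        if not feats:  # pragma: no cover - defensive
            warnings.warn(f"empty condition group {(exp, conc)} skipped")
            continue
        metrics: Dict[str, MetricStats] = {}
        for m in METRICS:
            vals = _metric_values(feats, m)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                warnings.warn(f"no finite {m} values for {(exp, conc)}; skipped")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, removed = remove_outliers(vals)
            n = int(kept.size)
            sd = float(kept.std(ddof=1)) if n > 1 else 0.0
            metrics[m] = MetricStats(
                mean=float(kept.mean()),
                sd=sd,
                sem=sd / np.sqrt(n) if n > 0 else float("nan"),
                n=n,
                n_outliers_removed=len(removed),
            )
        summaries.append(ConditionSummary(experiment_id=exp, concentration=conc, metrics=metrics))

    if not normalize_within_experiment:
        return summaries

    # per-experiment, per-metric scale: maximum of the condition means
    scales: Dict[Tuple[str, str], float] = {}
    for s in summaries:
        for m, st in s.metrics.items():
            key = (s.experiment_id, m)
            scales[key] = max(scales.get(key, -np.inf), st.mean)
    out: List[ConditionSummary] = []
    for s in summaries:
        new_metrics = {}
        for m, st in s.metrics.items():
            scale = scales[(s.experiment_id, m)]
            if scale == 0 or not np.isfinite(scale):
                new_metrics[m] = st
                continue
            new_metrics[m] = MetricStats(
                mean=st.mean / scale,
                sd=st.sd / abs(scale),
                sem=st.sem / abs(scale),
                n=st.n,
                n_outliers_removed=st.n_outliers_removed,
            )
        out.append(replace(s, metrics=new_metrics))
    return out


def amplitude_duration_relation(
    cells: Sequence[TraceFeatures],
) -> Tuple[float, Tuple[float, float]]:
    """Pearson r of amplitude vs duration plus an exponential regression.

    Fits ``duration = a * exp(b * amplitude)`` by nonlinear least squares
    (initialized from the log-linear solution). Cells without a defined
    duration are ignored; at least 3 usable cells are required.
    """
    amp = np.array([c.amplitude for c in cells], dtype=float)
    dur = np.array([c.duration for c in cells], dtype=float)
    ok = np.isfinite(amp) & np.isfinite(dur)
    amp, dur = amp[ok], dur[ok]
    if amp.size < 3:
        raise DataError("need >= 3 cells with defined duration")
    if np.ptp(amp) == 0 or np.ptp(dur) == 0:
        raise DataError("zero variance in amplitude or duration: correlation undefined")
    r = float(stats.pearsonr(amp, dur)[0])

    if np.all(dur > 0):
        slope, intercept = np.polyfit(amp, np.log(dur), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (float(np.mean(np.abs(dur)) or 1.0), -1.0)

    def model(x, a, b):
        return a * np.exp(b * x)

    popt, _ = optimize.curve_fit(model, amp, dur, p0=p0, maxfev=20000)
    return r, (float(popt[0]), float(popt[1]))
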