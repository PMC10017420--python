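"""Perfusion milestone features of a single ICG time-fluorescence trace.

The twelve milestones characterize bolus inflow and washout over a 90 s
window: time to peak (tmax), peak intensity (fmax), end intensity, upslope,
half-rise/peak time ratio, the 10 s post-peak intensity change and the
10/20/60 s post-peak slopes, value-distribution skew and excess kurtosis,
and the intensity-weighted centre of mass of the curve.

Healthy parenchyma concentrates ICG and has no early peak, so its post-peak
slopes are anchored at a mapped reference peak: the lesion's peak time (or
the mean peak time when several lesion ROIs were tracked) rather than the
healthy curve's own late peak.

Conventions (documented constants, applied uniformly):
- a 1.0 s centred moving average is applied before argmax and slope reads;
  the centre of mass and the value moments use the raw samples;
- the baseline is the mean of the first second of the raw trace and is used
  only for the half-rise and onset thresholds (tabulated intensities are
  raw, not baseline-subtracted);
- the upslope onset is the first crossing of 10 % of the dynamic range;
- ties in the argmax resolve to the earliest sample;
- crossings are located with linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, UndefinedFeatureError
from .reference import FEATURE_ORDER
from .trace_extraction import ROITrace

__all__ = [
    "PerfusionFeatures",
    "ReferencePeak",
    "smooth_trace",
    "peak_milestones",
    "half_time_and_ratio",
    "upslope",
    "reference_peak",
    "slope_after",
    "delta_after",
    "centre_of_mass",
    "shape_moments",
    "compute_features",
    "compute_feature_table",
]

DEFAULT_SMOOTH_WINDOW_S = 1.0
BASELINE_WINDOW_S = 1.0
ONSET_FRACTION = 0.10


@dataclass
class PerfusionFeatures:
    """The 12 milestone features of one trace; NaN marks undefined values."""

    tmax: float
    fmax: float
    f_end: float
    upslope: float
    t_half: float
    time_ratio: float
    delta10: float
    slope10: float
    slope20: float
    slope60: float
    kurtosis: float
    skew: float
    com: float
    roi_id: str = ""
    patient_id: str = ""
    label: str = ""
    reference_time: float = float("nan")

    def as_series(self) -> pd.Series:
        return pd.Series({f.name: getattr(self, f.name) for f in dataclass_fields(self)})


@dataclass(frozen=True)
class ReferencePeak:
    """Mapped slope anchor for tissue without an early peak."""

    t_star: float
    provenance: str  # own_peak | single_crlm_peak | mean_crlm_peaks


def _moving_average(values: np.ndarray, n: int) -> np.ndarray:
    """Centred moving average with shrinking windows at the edges."""
    if n <= 1:
        return values.astype(float)
    half = n // 2
    padded = np.concatenate([[0.0], np.cumsum(values, dtype=float)])
    idx = np.arange(len(values))
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, len(values) - 1)
    return (padded[hi + 1] - padded[lo]) / (hi + 1 - lo)


def _rel_times(trace: ROITrace) -> np.ndarray:
    """Times relative to the window start (features are shift-invariant)."""
    return trace.times - trace.times[0]


def smooth_trace(trace: ROITrace, window_s: float = DEFAULT_SMOOTH_WINDOW_S) -> ROITrace:
    """Centred moving-average smoothing; window_s = 0 returns the input."""
    if window_s < 0:
        raise InvalidParameterError("window_s must be >= 0")
    n = int(round(window_s * trace.fps))
    if n <= 1:
        return trace
    return ROITrace(
        times=trace.times,
        intensities=_moving_average(trace.intensities, n),
        fps=trace.fps,
        label=trace.label,
        roi_id=trace.roi_id,
        patient_id=trace.patient_id,
        meta={**trace.meta, "smoothed_window_s": window_s},
    )


def _smoothed(trace: ROITrace, window_s: float) -> np.ndarray:
    n = int(round(window_s * trace.fps))
    return _moving_average(trace.intensities, n) if n > 1 else trace.intensities.astype(float)


def baseline_intensity(trace: ROITrace, window_s: float = BASELINE_WINDOW_S) -> float:
    """Mean raw intensity over the first ``window_s`` seconds."""
    sel = _rel_times(trace) <= window_s
    return float(trace.intensities[sel].mean())


def peak_milestones(
    trace: ROITrace, smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S
) -> tuple[float, float, float]:
    """(tmax, fmax, f_end): earliest smoothed argmax, its value, last value."""
    if trace.n_samples == 0:
        raise InvalidParameterError("empty trace")
    sm = _smoothed(trace, smooth_window_s)
    i = int(np.argmax(sm))  # first occurrence on ties
    return float(_rel_times(trace)[i]), float(sm[i]), float(sm[-1])


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float:
    """Earliest time the series reaches ``level``, linearly interpolated."""
    above = values >= level
    if not above.any():
        raise UndefinedFeatureError(f"series never reaches level {level:.3f}")
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    f = (level - values[i - 1]) / (values[i] - values[i - 1])
    return float(times[i - 1] + f * (times[i] - times[i - 1]))


def half_time_and_ratio(
    trace: ROITrace,
    tmax: float | None = None,
    fmax: float | None = None,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> tuple[float, float]:
    """Half-rise time and the time ratio t_half / tmax.

    t_half is the first time the baseline-subtracted smoothed intensity
    reaches half of (fmax - baseline); baseline = mean of the first second.
    """
    if tmax is None or fmax is None:
        tmax, fmax, _ = peak_milestones(trace, smooth_window_s)
    base = baseline_intensity(trace)
    if fmax - base <= 1e-9:
        raise UndefinedFeatureError("flat trace: half-rise undefined")
    sm = _smoothed(trace, smooth_window_s)
    t_half = _first_crossing(_rel_times(trace), sm, base + 0.5 * (fmax - base))
    if tmax <= 0:
        raise UndefinedFeatureError("tmax at the first sample: ratio undefined")
    return t_half, t_half / tmax


def upslope(
    trace: ROITrace,
    tmax: float | None = None,
    fmax: float | None = None,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> float:
    """Inflow slope (fmax - F_onset) / (tmax - t_onset).

    Onset is the first crossing of baseline + 10 % of the dynamic range.
    """
    if tmax is None or fmax is None:
        tmax, fmax, _ = peak_milestones(trace, smooth_window_s)
    base = baseline_intensity(trace)
    if fmax - base <= 1e-9:
        raise UndefinedFeatureError("flat trace: upslope undefined")
    f_onset = base + ONSET_FRACTION * (fmax - base)
    sm = _smoothed(trace, smooth_window_s)
    t_onset = _first_crossing(_rel_times(trace), sm, f_onset)
    if tmax - t_onset <= 1e-9:
        raise UndefinedFeatureError("peak coincides with onset: upslope undefined")
    return float((fmax - f_onset) / (tmax - t_onset))


def reference_peak(
    crlm_traces: Sequence[ROITrace] | Iterable[ROITrace],
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> ReferencePeak:
    """Mapped slope anchor from the lesion curves of the same recording.

    One lesion ROI -> its own peak time; several -> the arithmetic mean of
    their peak times.
    """
    traces = list(crlm_traces)
    if not traces:
        raise InvalidParameterError("reference_peak needs at least one lesion trace")
    tmaxes = [peak_milestones(t, smooth_window_s)[0] for t in traces]
    if len(tmaxes) == 1:
        return ReferencePeak(t_star=tmaxes[0], provenance="single_crlm_peak")
    return ReferencePeak(t_star=float(np.mean(tmaxes)), provenance="mean_crlm_peaks")


def delta_after(
    trace: ROITrace,
    t_ref: float,
    k: float,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> float:
    """F(t_ref + k) - F(t_ref) on the smoothed trace."""
    t = _rel_times(trace)
    if t_ref < t[0] or t_ref + k > t[-1] + 1e-9:
        raise UndefinedFeatureError(
            f"interval [{t_ref:.2f}, {t_ref + k:.2f}] outside trace window"
        )
    sm = _smoothed(trace, smooth_window_s)
    f1, f2 = np.interp([t_ref, t_ref + k], t, sm)
    return float(f2 - f1)


def slope_after(
    trace: ROITrace,
    t_ref: float,
    k: float,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> float:
    """delta_after / k (g.u./s); exactly delta/k by construction."""
    if k <= 0:
        raise InvalidParameterError("k must be > 0")
    return delta_after(trace, t_ref, k, smooth_window_s) / k


def centre_of_mass(trace: ROITrace) -> float:
    """Intensity-weighted mean sample time, on the raw (unsmoothed) trace."""
    total = trace.intensities.sum()
    if total <= 0:
        raise UndefinedFeatureError("all-zero trace: centre of mass undefined")
    return float((_rel_times(trace) * trace.intensities).sum() / total)


def shape_moments(trace: ROITrace) -> tuple[float, float]:
    """(skew, excess kurtosis) of the intensity-value distribution.

    Fisher-Pearson g1 and excess g2 over the window's raw sample values
    (the curve is treated as a sample of intensities, not as a density over
    time). A saturating inflow spends most samples near the maximum, giving
    the characteristic negative skew of liver ICG curves.
    """
    v = trace.intensities
    if len(v) < 4:
        raise InvalidParameterError("need >= 4 samples for shape moments")
    if np.var(v) <= 1e-12:
        raise UndefinedFeatureError("zero variance: moments undefined")
    return float(sps.skew(v, bias=True)), float(sps.kurtosis(v, fisher=True, bias=True))


def compute_features(
    trace: ROITrace,
    t_star: float | None = None,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> PerfusionFeatures:
    """Assemble all 12 milestone features for one trace.

    Lesion and benign/unknown labels anchor the post-peak slopes at the
    trace's own peak; ``healthy`` traces use the mapped reference peak
    ``t_star`` when provided. Undefined milestones become NaN, never 0.
    """
    tmax, fmax, f_end = peak_milestones(trace, smooth_window_s)

    def _try(fn, *args):
        try:
            return fn(*args)
        except UndefinedFeatureError:
            return float("nan")

    t_half, ratio = float("nan"), float("nan")
    try:
        t_half, ratio = half_time_and_ratio(trace, tmax, fmax, smooth_window_s)
    except UndefinedFeatureError:
        pass
    up = _try(upslope, trace, tmax, fmax, smooth_window_s)

    if trace.label == "healthy" and t_star is not None:
        t_ref = float(t_star)
    else:
        t_ref = tmax
    delta10 = _try(delta_after, trace, t_ref, 10.0, smooth_window_s)
    slope10 = delta10 / 10.0  # exact identity with delta10
    slope20 = _try(slope_after, trace, t_ref, 20.0, smooth_window_s)
    slope60 = _try(slope_after, trace, t_ref, 60.0, smooth_window_s)

    skew = kurt = float("nan")
    try:
        skew, kurt = shape_moments(trace)
    except UndefinedFeatureError:
        pass
    com = _try(centre_of_mass, trace)

    return PerfusionFeatures(
        tmax=tmax,
        fmax=fmax,
        f_end=f_end,
        upslope=up,
        t_half=t_half,
        time_ratio=ratio,
        delta10=delta10,
        slope10=slope10,
        slope20=slope20,
        slope60=slope60,
        kurtosis=kurt,
        skew=skew,
        com=com,
        roi_id=trace.roi_id,
        patient_id=trace.patient_id,
        label=trace.label,
        reference_time=t_ref,
    )


def compute_feature_table(
    traces: Sequence[ROITrace],
    t_star: float | str | None = "auto",
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
) -> pd.DataFrame:
    """Feature table (one row per ROI) for a set of traces.

    ``t_star="auto"`` derives the mapped reference peak per patient from
    that patient's lesion traces (falling back to the cohort mean peak time
    when a patient has none); a float applies one anchor to all healthy
    traces; None makes every trace use its own peak.
    """
    per_patient: dict[str, float] = {}
    global_star: float | None = None
    if t_star == "auto":
        crlm = [t for t in traces if t.label == "crlm"]
        if crlm:
            global_star = reference_peak(crlm, smooth_window_s).t_star
            patients = {t.patient_id for t in crlm}
            for pid in patients:
                own = [t for t in crlm if t.patient_id == pid]
                per_patient[pid] = reference_peak(own, smooth_window_s).t_star
    elif t_star is not None:
        global_star = float(t_star)

    rows = []
    for tr in traces:
        anchor = per_patient.get(tr.patient_id, global_star)
        rows.append(compute_features(tr, anchor, smooth_window_s).as_series())
    df = pd.DataFrame(rows)
    cols = ["roi_id", "patient_id", "label", *FEATURE_ORDER]
    extra = [c for c in df.columns if c not in cols]
    return df[cols + extra].set_index("roi_id", drop=False)
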