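"""Bolus-kinetic curve family and milestone-targeted calibration.

The generative model for a single tissue class rises as a gamma-variate
bolus and washes out through one of two post-peak branches:

    F(t) = baseline                                 for t <= d
    F(t) = baseline + A * g(u)                      for d < t <= d+tp

with u = (t-d)/tp and the unit-peak gamma variate g(u) = u**a * exp(a*(1-u)).
``d`` is the arrival delay, ``tp`` the time to peak measured from arrival,
``A`` the amplitude and ``a`` the (unitless) sharpness; F attains
baseline + A exactly at t = d + tp.

After the peak (tau' = t - d - tp > 0):

* retention branch (healthy parenchyma, cysts): a convex mix of the
  gamma-variate decay and a retained plateau,
  F = baseline + A * [(1-rho) * g + rho], modelling hepatic ICG
  concentration that keeps the late signal well above baseline;

* dip-recovery branch (metastases): a fast bolus washout superimposed on
  slow re-accumulation,
  F = peak - D * (1 - exp(-tau'/tau_w)) + U * (1 - exp(-tau'/tau_r)),
  with washout time constant tau_w << recovery time constant tau_r. This
  reproduces the characteristic lesion profile of a sharp early peak, a
  steep 10 s washout, and a late plateau that sits between the dip bottom
  and the peak. D and U never push the curve above the peak, so the
  global maximum stays at d + tp.

Calibration is closed-form: shape from the half-rise target, retention
from the end intensity (retention branch), or (D, U) from the 10 s
intensity-change and end-intensity targets via a 2x2 linear system
(dip-recovery branch); the result is verified by running the noise-free
curve through the milestone extractor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from ..errors import CalibrationError, InvalidParameterError
from ..reference import ANALYSIS_WINDOW_S, REFERENCE_MILESTONES, VIDEO_FPS

__all__ = [
    "KineticParams",
    "gamma_variate",
    "perfusion_curve",
    "calibrate_kinetics",
    "solve_kinetics",
]


@dataclass(frozen=True)
class KineticParams:
    """Parameters of one tissue class's noise-free time-fluorescence curve.

    baseline      pre-arrival intensity, greyscale units in [0, 255]
    arrival_delay seconds >= 0 before any signal rise
    time_to_peak  seconds > 0 from arrival to the peak
    amplitude     peak rise above baseline, g.u. > 0
    shape         gamma-variate sharpness, unitless > 0
    retention     fraction of the amplitude retained as a late plateau,
                  in [0, 1); 0 gives the pure gamma variate
    """

    baseline: float
    arrival_delay: float
    time_to_peak: float
    amplitude: float
    shape: float
    retention: float = 0.0
    # dip-recovery washout (used when dip_amplitude > 0; overrides retention)
    dip_amplitude: float = 0.0  # g.u. washout depth coefficient (D)
    recovery_amplitude: float = 0.0  # g.u. re-accumulation coefficient (U)
    washout_tau: float = 6.0  # s, bolus washout time constant
    recovery_tau: float = 45.0  # s, recirculation/re-accumulation constant

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 255.0:
            raise InvalidParameterError(f"baseline {self.baseline} outside [0, 255]")
        if self.arrival_delay < 0:
            raise InvalidParameterError("arrival_delay must be >= 0")
        if self.time_to_peak <= 0:
            raise InvalidParameterError("time_to_peak must be > 0")
        if self.amplitude <= 0:
            raise InvalidParameterError("amplitude must be > 0")
        if self.shape <= 0:
            raise InvalidParameterError("shape must be > 0")
        if not 0.0 <= self.retention < 1.0:
            raise InvalidParameterError("retention must be in [0, 1)")
        if self.dip_amplitude < 0 or self.recovery_amplitude < 0:
            raise InvalidParameterError("dip/recovery amplitudes must be >= 0")
        if self.washout_tau <= 0 or self.recovery_tau <= 0:
            raise InvalidParameterError("washout/recovery time constants must be > 0")
        if self.dip_amplitude > 0:
            # the peak must remain the global maximum: initial slope <= 0
            # and the late plateau below the peak
            if self.recovery_amplitude / self.recovery_tau > self.dip_amplitude / self.washout_tau:
                raise InvalidParameterError(
                    "recovery slope exceeds washout slope at the peak: "
                    "curve would keep rising past its nominal peak"
                )

    @property
    def peak_time(self) -> float:
        """Absolute time of the peak (arrival_delay + time_to_peak)."""
        return self.arrival_delay + self.time_to_peak

    @property
    def peak_value(self) -> float:
        return self.baseline + self.amplitude


def _unit_gamma_variate(u: np.ndarray, shape: float) -> np.ndarray:
    """g(u) = u^a exp(a(1-u)) for u >= 0; peaks at exactly 1 for u = 1."""
    u = np.maximum(u, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.exp(shape * (np.log(np.where(u > 0, u, 1.0)) + 1.0 - u))
    return np.where(u > 0, out, 0.0)


def gamma_variate(t, p: KineticParams):
    """Pure gamma-variate curve (retention ignored).

    Returns ``baseline`` for t <= arrival_delay and
    baseline + amplitude * (tau/tp)^shape * exp(shape*(1 - tau/tp)) after,
    with tau = t - arrival_delay. Continuous in t; scalar in, scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    tau = t_arr - p.arrival_delay
    val = p.baseline + p.amplitude * _unit_gamma_variate(tau / p.time_to_peak, p.shape)
    return float(val) if np.isscalar(t) or t_arr.ndim == 0 else val


def perfusion_curve(t, p: KineticParams):
    """Gamma-variate inflow with the class's post-peak washout branch.

    Identical to :func:`gamma_variate` up to and including the peak. After
    the peak, either the retained-plateau mix (retention branch) or the
    dip-recovery washout (when ``dip_amplitude`` > 0) applies.
    """
    t_arr = np.asarray(t, dtype=float)
    tau = t_arr - p.arrival_delay
    g = _unit_gamma_variate(tau / p.time_to_peak, p.shape)
    val = p.baseline + p.amplitude * g
    post = tau > p.time_to_peak
    if p.dip_amplitude > 0:
        tau2 = np.maximum(tau - p.time_to_peak, 0.0)
        washed = (
            p.baseline
            + p.amplitude
            - p.dip_amplitude * (1.0 - np.exp(-tau2 / p.washout_tau))
            + p.recovery_amplitude * (1.0 - np.exp(-tau2 / p.recovery_tau))
        )
        val = np.where(post, np.maximum(washed, 0.0), val)
    elif p.retention > 0:
        val = np.where(
            post,
            p.baseline + p.amplitude * ((1.0 - p.retention) * g + p.retention),
            val,
        )
    return float(val) if np.isscalar(t) or t_arr.ndim == 0 else val


def _h(u: float) -> float:
    """log g(u) / shape = ln u + 1 - u  (0 at u=1, negative elsewhere)."""
    return float(np.log(u) + 1.0 - u)


def _extracted_peak_time(
    p: KineticParams, window_s: float, fps: float = VIDEO_FPS, smooth_s: float = 1.0
) -> float:
    """Peak time as the milestone extractor would measure it (smoothed argmax)."""
    n = int(round(window_s * fps))
    t = np.arange(n) / fps
    v = perfusion_curve(t, p)
    w = int(round(smooth_s * fps))
    if w > 1:
        half = w // 2
        c = np.concatenate([[0.0], np.cumsum(v)])
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, n - 1)
        v = (c[hi + 1] - c[lo]) / (hi + 1 - lo)
    return float(t[int(np.argmax(v))])


def solve_kinetics(
    tmax: float,
    fmax: float,
    f_end: float,
    time_ratio: float | None = None,
    *,
    delta10: float | None = None,
    baseline: float = 8.0,
    arrival_delay: float | None = None,
    window_s: float = ANALYSIS_WINDOW_S,
    washout_tau: float = 6.0,
    recovery_tau: float = 45.0,
    washout_infeasible: str = "raise",
) -> KineticParams:
    """Closed-form solve of KineticParams from milestone targets.

    ``tmax`` is the absolute peak time, ``fmax`` the peak intensity,
    ``f_end`` the intensity at the window end. If ``time_ratio``
    (= t_half / tmax) is given, the shape is chosen so the baseline-
    subtracted half-rise occurs at time_ratio * tmax; otherwise the shape
    is solved from the end intensity alone.

    ``delta10`` (intensity change from the peak to peak + 10 s, negative
    for a washing-out lesion; requires ``time_ratio``) selects the
    dip-recovery washout: its D and U coefficients are the solution of the
    2x2 linear system fixing the 10 s change and the end intensity.
    Without ``delta10`` the retention branch absorbs the end-intensity
    constraint.

    A broad curve (small shape) may be unable to wash *down* to the end
    target by the window end; ``washout_infeasible='clip'`` then accepts
    the closest reachable end intensity instead of raising.

    Raises CalibrationError (with residual info) for infeasible targets.
    """
    if fmax <= baseline + 1e-9:
        raise CalibrationError(
            f"peak target {fmax} does not exceed baseline {baseline}: flat curve, "
            "time-to-peak undefined",
            {"fmax_minus_baseline": fmax - baseline},
        )
    if not baseline < f_end:
        raise CalibrationError(
            f"end-intensity target {f_end} must exceed baseline {baseline}",
            {"f_end_minus_baseline": f_end - baseline},
        )
    if time_ratio is not None:
        t_half = time_ratio * tmax
        delay = max(1.0, 0.3 * t_half) if arrival_delay is None else arrival_delay
    else:
        delay = 3.0 if arrival_delay is None else arrival_delay
    tp = tmax - delay
    if tp <= 0:
        raise CalibrationError(
            f"time-to-peak target {tmax} s not after arrival delay {delay} s",
            {"tmax": tmax, "delay": delay},
        )
    amp = fmax - baseline
    c_end = (f_end - baseline) / amp  # unit-curve value required at window end
    x_end = (window_s - delay) / tp

    if delta10 is not None and time_ratio is None:
        raise InvalidParameterError("delta10 target requires a time_ratio target")
    if time_ratio is not None:
        u_half = (t_half - delay) / tp
        if not 0.0 < u_half < 1.0:
            raise CalibrationError(
                f"half-rise time {t_half:.3f} s infeasible for peak at {tmax:.3f} s "
                f"with arrival delay {delay:.3f} s",
                {"u_half": u_half},
            )
        shape = float(np.log(2.0) / -_h(u_half))
    else:
        if not 0.0 < c_end < 1.0:
            raise CalibrationError(
                f"end intensity {f_end} not between baseline and peak {fmax}",
                {"c_end": c_end},
            )
        shape = float(np.log(c_end) / _h(x_end))

    if c_end >= 1.0:
        raise CalibrationError(
            f"end intensity {f_end} >= peak {fmax}: washout direction infeasible",
            {"c_end": c_end},
        )

    tail = window_s - tmax  # time from the peak to the window end
    if delta10 is not None and tail > 10.0:
        if delta10 >= 0:
            raise CalibrationError(
                f"delta10 target {delta10} must be negative for the "
                "dip-recovery washout", {"delta10": delta10},
            )
        a1 = 1.0 - np.exp(-10.0 / washout_tau)
        b1 = 1.0 - np.exp(-10.0 / recovery_tau)
        a2 = 1.0 - np.exp(-tail / washout_tau)
        b2 = 1.0 - np.exp(-tail / recovery_tau)
        # [-a1 b1; -a2 b2] [D U]^T = [delta10, f_end - fmax]^T
        mat = np.array([[-a1, b1], [-a2, b2]])
        rhs = np.array([delta10, f_end - fmax])
        D, U = np.linalg.solve(mat, rhs)
        if U < 0:
            # drawn 10 s drop shallower than the total end drop allows:
            # monotone washout, match the end intensity exactly
            U = 0.0
            D = (fmax - f_end) / a2
        # peak must stay the global max: initial washout dominates recovery
        if U / recovery_tau > D / washout_tau:
            U = 0.999 * D * recovery_tau / washout_tau
        # dip bottom must stay above baseline (fmax - D bounds it below)
        if fmax - D < baseline:
            if washout_infeasible != "clip":
                raise CalibrationError(
                    f"washout depth D={D:.2f} would undershoot the baseline",
                    {"D": D, "dip_floor": fmax - D},
                )
            D = fmax - baseline

        def build(tmax_w: float) -> KineticParams:
            tp_w = tmax_w - delay
            u_h = (t_half - delay) / tp_w if time_ratio is not None else None
            shape_w = (
                float(np.log(2.0) / -_h(u_h)) if u_h and 0 < u_h < 1 else shape
            )
            return KineticParams(
                baseline=baseline,
                arrival_delay=delay,
                time_to_peak=tp_w,
                amplitude=amp,
                shape=shape_w,
                dip_amplitude=float(D),
                recovery_amplitude=float(U),
                washout_tau=washout_tau,
                recovery_tau=recovery_tau,
            )

        # the sharp post-peak kink pulls the extractor's smoothed argmax
        # slightly early; a fixed-point nudge of the working peak time makes
        # the *extracted* peak land on the target (deterministic)
        tmax_w = tmax
        params = build(tmax_w)
        for _ in range(2):
            err = tmax - _extracted_peak_time(params, window_s)
            if abs(err) < 1e-3:
                break
            tmax_w += err
            if tmax_w - delay <= 0.5:
                break
            params = build(tmax_w)
        return params

    g_end = float(_unit_gamma_variate(np.asarray(x_end), shape))
    retention = (c_end - g_end) / (1.0 - g_end)
    if retention < 0.0:
        # the shape's natural washout ends *above* the requested end
        # intensity (c_end < g_end): the family cannot wash down that far
        if retention < -0.02 and washout_infeasible != "clip":
            raise CalibrationError(
                "end-intensity target below the natural gamma-variate washout "
                f"(required retention {retention:.4f} < 0)",
                {"retention": retention, "g_end": g_end, "c_end": c_end},
            )
        retention = 0.0
    if retention >= 1.0:
        raise CalibrationError(
            f"retention {retention:.4f} >= 1 infeasible", {"retention": retention}
        )
    return KineticParams(
        baseline=baseline,
        arrival_delay=delay,
        time_to_peak=tp,
        amplitude=amp,
        shape=shape,
        retention=float(retention),
    )


_REQUIRED_TARGETS = ("tmax", "fmax", "f_end")


def calibrate_kinetics(
    target_milestones: Mapping[str, Mapping[str, float]] | None = None,
    *,
    baseline: float = 8.0,
    window_s: float = ANALYSIS_WINDOW_S,
    fps: float = VIDEO_FPS,
    rtol: float = 0.02,
    verify: bool = True,
) -> dict[str, KineticParams]:
    """Per-class KineticParams whose noise-free curves reproduce the targets.

    ``target_milestones`` maps class name -> {milestone: value}; each class
    must provide at least tmax, fmax and f_end, and may provide time_ratio.
    Defaults to the published reference milestones (with time_ratio targeted
    for the CRLM class, for which the family can satisfy all four).

    When ``verify`` is set the noise-free curve is sampled at ``fps`` over
    ``window_s`` and pushed through the milestone extractor; any targeted
    milestone off by more than ``rtol`` (relative) raises CalibrationError
    with the residuals. Deterministic: no randomness involved.
    """
    if target_milestones is None:
        target_milestones = {
            "crlm": {
                k: REFERENCE_MILESTONES["crlm"][k][0]
                for k in ("tmax", "fmax", "f_end", "time_ratio", "delta10")
            },
            "healthy": {
                k: REFERENCE_MILESTONES["healthy"][k][0]
                for k in ("tmax", "fmax", "f_end")
            },
        }
    out: dict[str, KineticParams] = {}
    for cls, targets in target_milestones.items():
        missing = [k for k in _REQUIRED_TARGETS if k not in targets]
        if missing:
            raise InvalidParameterError(
                f"class {cls!r}: calibration targets missing {missing}"
            )
        params = solve_kinetics(
            targets["tmax"],
            targets["fmax"],
            targets["f_end"],
            targets.get("time_ratio"),
            delta10=targets.get("delta10"),
            baseline=baseline,
            window_s=window_s,
        )
        if verify:
            _verify_calibration(params, targets, window_s, fps, rtol)
        out[cls] = params
    return out


def _verify_calibration(
    params: KineticParams,
    targets: Mapping[str, float],
    window_s: float,
    fps: float,
    rtol: float,
) -> None:
    # local import: perfusion_features must stay import-independent of synth_scene
    from .. import perfusion_features as pf
    from ..trace_extraction import ROITrace

    n = int(round(window_s * fps))
    times = np.arange(n) / fps
    trace = ROITrace(
        times=times,
        intensities=np.clip(perfusion_curve(times, params), 0, 255),
        fps=fps,
        label="calibration",
        roi_id="calibration",
        patient_id="calibration",
    )
    tmax, fmax, f_end = pf.peak_milestones(trace)
    achieved = {"tmax": tmax, "fmax": fmax, "f_end": f_end}
    if "time_ratio" in targets:
        _, ratio = pf.half_time_and_ratio(trace, tmax, fmax)
        achieved["time_ratio"] = ratio
    if "delta10" in targets:
        achieved["delta10"] = pf.delta_after(trace, tmax, 10.0)
    residuals = {
        k: achieved[k] - targets[k] for k in achieved if k in targets
    }
    bad = {
        k: r
        for k, r in residuals.items()
        if abs(r) > rtol * max(abs(targets[k]), 1.0)
    }
    if bad:
        raise CalibrationError(
            f"calibration verification failed beyond rtol={rtol}: {bad}", residuals
        )


def rim_kinetics(healthy: KineticParams) -> KineticParams:
    """Peri-lesional rim: compressed parenchyma with boosted, retained signal."""
    return replace(
        healthy,
        amplitude=min(1.3 * healthy.amplitude, 255.0 - healthy.baseline - 1e-6),
        retention=max(healthy.retention, 0.3),
    )


def cyst_kinetics(healthy: KineticParams) -> KineticParams:
    """Benign cyst: avascular fluid, healthy-like timing at low amplitude."""
    return replace(healthy, amplitude=0.22 * healthy.amplitude)
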