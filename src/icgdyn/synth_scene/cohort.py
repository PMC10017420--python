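"""Per-ROI trace simulation emulating the study cohort's variability.

Biological variability is sampled in *milestone space*: each synthetic ROI
draws its own (tmax, fmax, time_ratio, washout fraction) from mean-matched
truncated lognormal distributions whose means and coefficients of variation
come from the published reference table, and the kinetic parameters are
then solved in closed form from those per-ROI milestones. Sampling in
milestone space (rather than jittering kinetic parameters) keeps the
recovered milestone *means* unbiased — nonlinear parameter-to-milestone
maps would otherwise shift them — while the lognormal CVs reproduce the
reference SDs approximately.

Right truncation at 250 g.u. for peak intensity models the acquisition
protocol's saturation avoidance (the 0.05 mg/kg dose was chosen to keep the
8-bit sensor out of saturation); the lognormal location is re-solved under
truncation so the truncated mean still equals the target mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr
from scipy.stats import truncnorm

from ..errors import InvalidParameterError
from ..reference import ANALYSIS_WINDOW_S, COHORT_ROIS, REFERENCE_MILESTONES, VIDEO_FPS
from ..trace_extraction import ROITrace
from dataclasses import replace as _dc_replace
from .kinetics import KineticParams, perfusion_curve, solve_kinetics

__all__ = [
    "MilestoneDistribution",
    "CLASS_MILESTONE_MODELS",
    "sample_roi_milestones",
    "sample_roi_kinetics",
    "simulate_roi_traces",
    "simulate_cohort",
]


@dataclass(frozen=True)
class MilestoneDistribution:
    """Mean-matched lognormal, truncated to [lo, hi], for one milestone."""

    mean: float
    cv: float
    lo: float
    hi: float

    def _sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.cv**2)))

    def _mu(self) -> float:
        """Location such that the *truncated* mean equals ``mean``."""
        s = self._sigma()
        a, b = np.log(self.lo), np.log(self.hi)

        def trunc_mean(mu: float) -> float:
            za, zb = (a - mu) / s, (b - mu) / s
            denom = ndtr(zb) - ndtr(za)
            if denom < 1e-12:
                return np.exp(mu + s**2 / 2)
            return float(
                np.exp(mu + s**2 / 2) * (ndtr(zb - s) - ndtr(za - s)) / denom
            )

        lo_mu, hi_mu = np.log(self.mean) - 4 * s, b + 4 * s
        if trunc_mean(lo_mu) > self.mean or trunc_mean(hi_mu) < self.mean:
            raise InvalidParameterError(
                f"cannot mean-match lognormal to {self.mean} within [{self.lo}, {self.hi}]"
            )
        return float(brentq(lambda mu: trunc_mean(mu) - self.mean, lo_mu, hi_mu, xtol=1e-10))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        s = self._sigma()
        if s < 1e-12:
            return np.full(n, np.clip(self.mean, self.lo, self.hi))
        mu = self._mu()
        za, zb = (np.log(self.lo) - mu) / s, (np.log(self.hi) - mu) / s
        z = truncnorm.rvs(za, zb, size=n, random_state=rng)
        return np.exp(mu + s * z)


def _ref_cv(cls: str, key: str) -> float:
    mean, sd = REFERENCE_MILESTONES[cls][key]
    return sd / mean


# Washout fraction w = (f_end - baseline) / (fmax - baseline) at the default
# baseline of 8 g.u., derived from the reference end/peak intensities.
_BASELINE = 8.0
_W_CRLM = (102.861 - _BASELINE) / (123.594 - _BASELINE)
_W_HEALTHY = (188.988 - _BASELINE) / (195.322 - _BASELINE)

CLASS_MILESTONE_MODELS: dict[str, dict[str, MilestoneDistribution]] = {
    "crlm": {
        "tmax": MilestoneDistribution(23.931, _ref_cv("crlm", "tmax"), 6.0, 85.0),
        "fmax": MilestoneDistribution(123.594, _ref_cv("crlm", "fmax"), _BASELINE + 15.0, 250.0),
        "time_ratio": MilestoneDistribution(0.341, _ref_cv("crlm", "time_ratio"), 0.05, 0.93),
        "washout": MilestoneDistribution(_W_CRLM, 0.08, 0.30, 0.985),
        # magnitude of the peak -> peak+10 s intensity drop
        "delta10_mag": MilestoneDistribution(24.471, 13.700 / 24.471, 3.0, 80.0),
    },
    "healthy": {
        "tmax": MilestoneDistribution(82.616, _ref_cv("healthy", "tmax"), 40.0, 88.0),
        "fmax": MilestoneDistribution(195.322, _ref_cv("healthy", "fmax"), 60.0, 250.0),
        "washout": MilestoneDistribution(_W_HEALTHY, 0.012, 0.85, 0.995),
    },
    # Benign cysts are avascular: healthy-like timing, strongly reduced
    # enhancement, near-total signal retention (no active washout).
    "benign_cyst": {
        "tmax": MilestoneDistribution(80.0, 0.08, 55.0, 88.0),
        "fmax": MilestoneDistribution(45.0, 0.18, 25.0, 90.0),
        "washout": MilestoneDistribution(0.95, 0.02, 0.85, 0.99),
    },
}


# spatial heterogeneity of enhancement across one lesion: ROIs of the same
# lesion share the lesion's kinetic *shape* (timing, washout fractions are
# lesion-level properties within one video) and differ by an amplitude
# factor; measurement noise adds the rest of the observed scatter
WITHIN_LESION_AMPLITUDE_CV = 0.12


def sample_roi_milestones(
    label: str, n: int, rng: np.random.Generator, n_lesions: int | None = None
) -> pd.DataFrame:
    """Per-ROI milestone targets for one tissue class (one row per ROI).

    ``n_lesions`` groups the ROIs: lesion-level milestones are drawn from
    the class distributions (whose SDs describe between-lesion/patient
    spread) and shared by that lesion's ROIs, apart from a mean-preserving
    lognormal amplitude factor (column ``amp_factor``) describing spatial
    enhancement heterogeneity. Default: every ROI its own lesion.
    """
    try:
        model = CLASS_MILESTONE_MODELS[label]
    except KeyError as e:
        raise InvalidParameterError(f"unknown tissue class {label!r}") from e
    if n_lesions is not None and 0 < n_lesions < n:
        groups = pd.DataFrame({k: d.sample(n_lesions, rng) for k, d in model.items()})
        assign = np.arange(n) % n_lesions
        df = groups.iloc[assign].reset_index(drop=True)
        sigma = np.sqrt(np.log1p(WITHIN_LESION_AMPLITUDE_CV**2))
        df["amp_factor"] = np.exp(rng.normal(-sigma**2 / 2, sigma, size=n))
        df["lesion"] = assign
    else:
        df = pd.DataFrame({k: d.sample(n, rng) for k, d in model.items()})
        df["amp_factor"] = 1.0
        df["lesion"] = np.arange(n)
    if "time_ratio" in df:
        # the half-rise must happen after signal arrival (>= ~1.2 s so the
        # 1 s baseline window stays signal-free); resample the rare violators
        for _ in range(100):
            bad = df["time_ratio"] * df["tmax"] < 1.2
            if not bad.any():
                break
            k = int(bad.sum())
            df.loc[bad, "time_ratio"] = model["time_ratio"].sample(k, rng)
            df.loc[bad, "tmax"] = model["tmax"].sample(k, rng)
    return df


def sample_roi_kinetics(
    label: str,
    n: int,
    rng: np.random.Generator,
    *,
    baseline: float = _BASELINE,
    window_s: float = ANALYSIS_WINDOW_S,
    n_lesions: int | None = None,
) -> tuple[list[KineticParams], pd.DataFrame]:
    """Draw per-ROI milestones and solve each ROI's KineticParams."""
    draws = sample_roi_milestones(label, n, rng, n_lesions=n_lesions)
    params: list[KineticParams] = []
    solved: dict[int, KineticParams] = {}
    for _, row in draws.iterrows():
        lesion = int(row["lesion"])
        if lesion not in solved:
            f_end = baseline + row["washout"] * (row["fmax"] - baseline)
            delta10 = None
            if "delta10_mag" in row and np.isfinite(row["delta10_mag"]):
                # washout depth cannot exceed the enhancement itself
                delta10 = -min(row["delta10_mag"], 0.6 * (row["fmax"] - baseline))
            solved[lesion] = solve_kinetics(
                row["tmax"],
                row["fmax"],
                f_end,
                row.get("time_ratio"),
                delta10=delta10,
                baseline=baseline,
                window_s=window_s,
                washout_infeasible="clip",
            )
        base_params = solved[lesion]
        k = float(row["amp_factor"])
        if k != 1.0:
            # scale enhancement (and with it the washout depth/recovery so
            # the curve shape is preserved); keep the 8-bit peak reachable
            k = min(k, (250.0 - baseline) / base_params.amplitude)
            params.append(
                _dc_replace(
                    base_params,
                    amplitude=k * base_params.amplitude,
                    dip_amplitude=k * base_params.dip_amplitude,
                    recovery_amplitude=k * base_params.recovery_amplitude,
                )
            )
        else:
            params.append(base_params)
    return params, draws


@dataclass
class TraceNoiseModel:
    """Sensor noise as seen by an ROI-mean trace.

    Per-pixel Gaussian noise of SD ``pixel_noise_sd`` averaged over
    ``roi_area_px`` pixels; the ROI mean is clipped to the 8-bit range.
    """

    pixel_noise_sd: float = 2.0
    roi_area_px: int = 64

    @property
    def trace_sd(self) -> float:
        return self.pixel_noise_sd / np.sqrt(self.roi_area_px)


def simulate_roi_traces(
    label: str,
    n: int,
    seed: int | np.random.Generator,
    *,
    fps: float = VIDEO_FPS,
    window_s: float = ANALYSIS_WINDOW_S,
    noise: TraceNoiseModel | None = None,
    baseline: float = _BASELINE,
    patient_ids: list[str] | None = None,
    n_lesions: int | None = None,
) -> list[ROITrace]:
    """Simulate ``n`` noisy ROI traces of one tissue class.

    Deterministic for a fixed seed. Each trace samples its own milestone
    draw (optionally grouped into lesions); noise emulates per-pixel
    sensor noise averaged over the ROI.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = noise or TraceNoiseModel()
    params, draws = sample_roi_kinetics(
        label, n, rng, baseline=baseline, window_s=window_s, n_lesions=n_lesions
    )
    n_samples = int(round(window_s * fps))
    times = np.arange(n_samples) / fps
    traces = []
    for i, p in enumerate(params):
        curve = perfusion_curve(times, p)
        curve = curve + rng.normal(0.0, noise.trace_sd, size=n_samples)
        pid = patient_ids[i] if patient_ids is not None else f"{label}_p{i:03d}"
        traces.append(
            ROITrace(
                times=times,
                intensities=np.clip(curve, 0.0, 255.0),
                fps=fps,
                label=label,
                roi_id=f"{label}_{i:03d}",
                patient_id=pid,
                meta={"true_milestones": draws.iloc[i].to_dict()},
            )
        )
    return traces


def simulate_cohort(
    n_per_class: dict[str, int] | None = None,
    seed: int | np.random.Generator = 0,
    *,
    fps: float = VIDEO_FPS,
    window_s: float = ANALYSIS_WINDOW_S,
    noise: TraceNoiseModel | None = None,
) -> list[ROITrace]:
    """The study-shaped synthetic cohort (default 132 CRLM / 24 healthy /
    6 benign-cyst ROIs across 25 patients).

    CRLM ROIs are spread round-robin over 24 patients (one lesion each,
    with tight within-lesion scatter across that lesion's ROIs), each of
    whom also contributes one healthy reference ROI; the 6 cyst ROIs all
    sample the single benign cyst of one additional patient.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per_class = dict(COHORT_ROIS) if n_per_class is None else n_per_class
    traces: list[ROITrace] = []
    n_crlm_patients = max(n_per_class.get("healthy", 1), 1)
    for label, n in n_per_class.items():
        if label == "crlm":
            pids = [f"patient_{i % n_crlm_patients:02d}" for i in range(n)]
        elif label == "healthy":
            pids = [f"patient_{i:02d}" for i in range(n)]
        else:
            pids = [f"patient_{n_crlm_patients:02d}"] * n
        if label == "crlm":
            n_lesions = min(n_crlm_patients, n)
        elif label == "benign_cyst":
            n_lesions = 1
        else:
            n_lesions = None
        traces.extend(
            simulate_roi_traces(
                label, n, rng, fps=fps, window_s=window_s, noise=noise,
                patient_ids=pids, n_lesions=n_lesions,
            )
        )
    return traces
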