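"""Published reference milestones for ICG perfusion in liver tissue.

These are the cohort-level milestone statistics (mean, SD) for colorectal
liver metastases (CRLM) versus healthy liver parenchyma after intravenous
ICG at 0.05 mg/kg, extracted from 90 s time-fluorescence curves sampled at
30 fps. They serve as the default calibration targets for the synthetic
angiogram generator and as the worked-example constants for the internal
consistency checks (e.g. the 10 s intensity change equals ten times the
10 s slope).

Units: times in seconds, intensities in 8-bit greyscale units (g.u.),
slopes in g.u./s; ``time_ratio``, ``kurtosis`` and ``skew`` are unitless.
"""

from __future__ import annotations

# Order of the 12 milestone features as conventionally tabulated.
FEATURE_ORDER: tuple[str, ...] = (
    "tmax",
    "fmax",
    "f_end",
    "upslope",
    "time_ratio",
    "delta10",
    "slope10",
    "slope20",
    "slope60",
    "kurtosis",
    "skew",
    "com",
)

FEATURE_LABELS: dict[str, str] = {
    "tmax": "Tmax (time to peak intensity) (s)",
    "fmax": "Fmax (peak intensity) (g.u.)",
    "f_end": "End intensity (g.u.)",
    "upslope": "Upslope (g.u./s)",
    "time_ratio": "Time ratio (T_1/2 / T_max)",
    "delta10": "Intensity change: peak to peak+10 s (g.u.)",
    "slope10": "Slope 10 s from peak (g.u./s)",
    "slope20": "Slope 20 s from peak (g.u./s)",
    "slope60": "Slope 60 s from peak (g.u./s)",
    "kurtosis": "Kurtosis",
    "skew": "Skew",
    "com": "Centre of mass (s)",
}

# (mean, SD) per milestone per tissue class.
REFERENCE_MILESTONES: dict[str, dict[str, tuple[float, float]]] = {
    "crlm": {
        "tmax": (23.931, 13.370),
        "fmax": (123.594, 51.253),
        "f_end": (102.861, 48.899),
        "upslope": (6.951, 4.458),
        "time_ratio": (0.341, 0.208),
        "delta10": (-24.471, 13.700),
        "slope10": (-2.447, 1.370),
        "slope20": (-1.190, 0.727),
        "slope60": (-0.283, 0.326),
        "kurtosis": (2.053, 2.037),
        "skew": (-1.399, 0.966),
        "com": (49.536, 6.504),
    },
    "healthy": {
        "tmax": (82.616, 12.888),
        "fmax": (195.322, 57.883),
        "f_end": (188.988, 57.948),
        "upslope": (2.660, 1.446),
        "time_ratio": (0.127, 0.076),
        "delta10": (36.726, 30.341),
        "slope10": (3.672, 3.034),
        "slope20": (0.831, 0.837),
        "slope60": (0.673, 0.488),
        "kurtosis": (1.366, 2.164),
        "skew": (-1.495, 0.589),
        "com": (53.995, 3.262),
    },
}

# Study-shape cohort: 132 lesion ROIs and 6 benign-cyst ROIs across 25
# patients; one healthy-parenchyma reference per CRLM patient.
COHORT_ROIS: dict[str, int] = {"crlm": 132, "healthy": 24, "benign_cyst": 6}

# Reference microscopy signal/area values (arbitrary units) and the
# fluorescence attenuation factor caused by H&E staining + cover slipping.
MICROSCOPY_SIGNAL_PER_AREA: dict[str, tuple[float, float]] = {
    "healthy": (507.43, 160.82),
    "crlm": (2.46, 9.56),
}
STAINING_ATTENUATION: float = 6.5

# Acquisition protocol constants.
VIDEO_FPS: float = 30.0
ANALYSIS_WINDOW_S: float = 90.0
POSTPROCESS_FPS: float = 7.0
ICG_DOSE_MG_PER_KG: float = 0.05
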