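"""Group-level milestone statistics and microscopy section quantification.

Milestone features are compared between lesion and healthy groups with
two-sided Mann-Whitney U tests after Shapiro-Wilk normality screening
(the milestone distributions are generally non-normal), reported as a
mean ± SD table with per-row p-values and significance stars at 0.05,
with no multiple-testing correction (raw p per row). SDs use the sample
(n-1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError
from .reference import FEATURE_LABELS, FEATURE_ORDER
from .synth_scene.microscopy import SectionImage

__all__ = [
    "normality",
    "compare_groups",
    "build_table",
    "SectionQuantification",
    "section_signal_per_area",
    "attenuation_ratio",
]

ALPHA = 0.05


def normality(values) -> tuple[float, float]:
    """Shapiro-Wilk statistic and p-value; defined for 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not 3 <= len(v) <= 5000:
        raise InvalidParameterError(f"Shapiro-Wilk needs 3..5000 values, got {len(v)}")
    if np.ptp(v) == 0:
        raise InvalidParameterError("constant sample: normality test undefined")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def compare_groups(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact p for small tie-free samples, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def build_table(
    feature_table: pd.DataFrame,
    groups: tuple[str, str] = ("crlm", "healthy"),
    label_col: str = "label",
) -> pd.DataFrame:
    """Per-milestone group means ± SD with Mann-Whitney p and stars.

    One row per milestone present in the input, in the conventional
    ordering. A milestone entirely missing in one group is flagged and
    carries no p-value.
    """
    present = set(feature_table[label_col])
    missing_groups = [g for g in groups if g not in present]
    if missing_groups:
        raise InvalidParameterError(f"groups {missing_groups} absent from table")
    ga = feature_table[feature_table[label_col] == groups[0]]
    gb = feature_table[feature_table[label_col] == groups[1]]
    rows = []
    for feat in [f for f in FEATURE_ORDER if f in feature_table.columns]:
        va = ga[feat].to_numpy(dtype=float)
        vb = gb[feat].to_numpy(dtype=float)
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        row = {
            "feature": feat,
            "description": FEATURE_LABELS.get(feat, feat),
            f"mean_{groups[0]}": va.mean() if len(va) else np.nan,
            f"sd_{groups[0]}": va.std(ddof=1) if len(va) > 1 else np.nan,
            f"mean_{groups[1]}": vb.mean() if len(vb) else np.nan,
            f"sd_{groups[1]}": vb.std(ddof=1) if len(vb) > 1 else np.nan,
        }
        if len(va) and len(vb):
            u, p = compare_groups(va, vb)
            row.update(U=u, p_value=p, significant=bool(p < ALPHA), flagged=False)
        else:
            row.update(U=np.nan, p_value=np.nan, significant=False, flagged=True)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def format_table(table: pd.DataFrame, groups: tuple[str, str] = ("crlm", "healthy")) -> str:
    """Human-readable rendering of :func:`build_table` output."""
    lines = []
    for feat, row in table.iterrows():
        star = "*" if row.get("significant") else " "
        p = row.get("p_value")
        p_txt = "   n/a " if not np.isfinite(p) else ("<0.001" if p < 0.001 else f"{p:6.3f}")
        lines.append(
            f"{row['description']:<45} "
            f"{row[f'mean_{groups[0]}']:9.3f} ± {row[f'sd_{groups[0]}']:7.3f}  "
            f"{row[f'mean_{groups[1]}']:9.3f} ± {row[f'sd_{groups[1]}']:7.3f}  "
            f"p={p_txt}{star}"
        )
    return "\n".join(lines)


@dataclass
class SectionQuantification:
    """Signal-per-area summary of one microscopy section."""

    signal_per_area: dict[str, float]  # region -> mean signal per pixel
    areas: dict[str, int]
    contrast_ratio: float  # healthy / lesion
    contrast_capped: bool  # lesion signal was ~0; ratio reported as inf


def section_signal_per_area(section: SectionImage) -> SectionQuantification:
    """Mean fluorescence signal per unit area for each region mask."""
    if not section.masks:
        raise InvalidParameterError("section has no region masks")
    spa: dict[str, float] = {}
    areas: dict[str, int] = {}
    for name, mask in section.masks.items():
        area = int(mask.sum())
        if area == 0:
            raise InvalidParameterError(f"region {name!r} mask is empty")
        areas[name] = area
        spa[name] = float(section.image[mask].sum() / area)
    capped = False
    ratio = np.nan
    if "healthy" in spa and "lesion" in spa:
        if spa["lesion"] <= 0:
            ratio, capped = float("inf"), True
        else:
            ratio = spa["healthy"] / spa["lesion"]
    return SectionQuantification(
        signal_per_area=spa, areas=areas, contrast_ratio=float(ratio),
        contrast_capped=capped,
    )


def attenuation_ratio(
    unstained: SectionImage, stained: SectionImage, mask: np.ndarray | None = None
) -> float:
    """Whole-mask mean signal ratio unstained / stained.

    Invariant to a common intensity scaling of both sections. Default mask
    is the full section (masks must match between the two images).
    """
    if unstained.image.shape != stained.image.shape:
        raise InvalidParameterError("sections must have matching shapes")
    if mask is None:
        mask = np.ones(unstained.image.shape, dtype=bool)
    denom = float(stained.image[mask].mean())
    if denom <= 0:
        raise InvalidParameterError("stained section has zero mean signal")
    return float(unstained.image[mask].mean() / denom)
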