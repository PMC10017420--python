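"""Per-pixel perfusion milestone maps, piecewise-constant profile
compression and unsupervised clustering of a stabilized field.

The 2D delineation maps are: the centre of mass (COM) of each pixel's
time-fluorescence curve (early COM = fast bolus transit, typical of
metastases; late COM = ICG retention, typical of parenchyma), the outflow
slope between each pixel's own smoothed peak and peak + 10 s (negative =
washout), and an unsupervised k-means clustering of per-pixel profile
descriptors (optimal piecewise-constant segment levels, or the (COM,
slope) pair). Cluster labels are relabelled by ascending cluster-mean COM
so label identity is deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, TwoSlopeNorm
from sklearn.cluster import KMeans

from ..errors import InvalidParameterError
from .stabilize import StabilizedField

__all__ = [
    "pixel_milestones",
    "pwc_fit",
    "pwc_levels",
    "cluster_field",
    "render",
]


def _smooth_axis0(vol: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return vol.astype(np.float32)
    T = vol.shape[0]
    half = n // 2
    c = np.concatenate([np.zeros((1, *vol.shape[1:]), dtype=np.float64),
                        np.cumsum(vol, axis=0, dtype=np.float64)])
    idx = np.arange(T)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, T - 1)
    return ((c[hi + 1] - c[lo]).T / (hi + 1 - lo)).T.astype(np.float32)


def pixel_milestones(
    field: StabilizedField,
    smooth_window_s: float = 1.0,
    slope_offset_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(com_map, slope_map) over the valid mask; NaN elsewhere.

    COM uses raw samples; the outflow slope reads the smoothed curve at
    each pixel's own earliest peak and ``slope_offset_s`` later. Pixels
    whose peak lies within ``slope_offset_s`` of the window end get NaN
    slope (flagged missing).
    """
    vol = field.volume
    T, H, W = vol.shape
    if T < 2:
        raise InvalidParameterError("field needs at least 2 frames")
    times = field.times
    n = int(round(smooth_window_s * field.fps))
    sm = _smooth_axis0(vol, n)

    totals = vol.sum(axis=0)
    com = np.full((H, W), np.nan, dtype=np.float32)
    nz = totals > 0
    com[nz] = (np.tensordot(times, vol, axes=(0, 0))[nz] / totals[nz]).astype(np.float32)

    peak_idx = np.argmax(sm, axis=0)  # earliest on ties
    dt = np.median(np.diff(times))
    off = int(round(slope_offset_s / dt))
    late = peak_idx + off > T - 1
    idx2 = np.minimum(peak_idx + off, T - 1)
    ii, jj = np.mgrid[0:H, 0:W]
    f1 = sm[peak_idx, ii, jj]
    f2 = sm[idx2, ii, jj]
    span = times[idx2] - times[peak_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(span > 0, (f2 - f1) / np.where(span > 0, span, 1.0), np.nan)
    slope = slope.astype(np.float32)
    slope[late] = np.nan

    invalid = ~field.valid
    com[invalid] = np.nan
    slope[invalid] = np.nan
    return com, slope


def pwc_fit(curve: np.ndarray, n_segments: int) -> tuple[list[int], np.ndarray, float]:
    """Optimal contiguous piecewise-constant approximation of one curve.

    Exact dynamic programming over all segmentations into ``n_segments``
    contiguous blocks minimizing total squared error. Returns the start
    indices of segments 2..k (``breakpoints``), the segment means
    (``levels``) and the total squared error.
    """
    y = np.asarray(curve, dtype=float)
    T = len(y)
    if n_segments < 1 or n_segments > T:
        raise InvalidParameterError(f"n_segments must be in [1, {T}]")
    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def seg_cost(i: int, j: int) -> float:
        """SSE of fitting one constant on y[i:j] (half-open)."""
        n = j - i
        s = s1[j] - s1[i]
        return (s2[j] - s2[i]) - s * s / n

    INF = np.inf
    D = np.full((n_segments + 1, T + 1), INF)
    arg = np.zeros((n_segments + 1, T + 1), dtype=int)
    D[0, 0] = 0.0
    for k in range(1, n_segments + 1):
        for j in range(k, T + 1):
            best, best_i = INF, k - 1
            for i in range(k - 1, j):
                c = D[k - 1, i] + seg_cost(i, j)
                if c < best:
                    best, best_i = c, i
            D[k, j], arg[k, j] = best, best_i
    # backtrack
    bounds = [T]
    j = T
    for k in range(n_segments, 0, -1):
        j = arg[k, j]
        bounds.append(j)
    bounds = bounds[::-1]  # [0, b1, ..., T]
    levels = np.array(
        [(s1[bounds[k + 1]] - s1[bounds[k]]) / (bounds[k + 1] - bounds[k])
         for k in range(n_segments)]
    )
    return bounds[1:-1], levels, float(D[n_segments, T])


def pwc_levels(curves: np.ndarray, n_segments: int) -> np.ndarray:
    """Vectorized PWC segment levels for many curves (P, T) -> (P, k).

    Same dynamic program as :func:`pwc_fit`, batched across curves.
    """
    y = np.asarray(curves, dtype=np.float64)
    if y.ndim != 2:
        raise InvalidParameterError("curves must be (P, T)")
    P, T = y.shape
    if n_segments < 1 or n_segments > T:
        raise InvalidParameterError(f"n_segments must be in [1, {T}]")
    s1 = np.concatenate([np.zeros((P, 1)), np.cumsum(y, axis=1)], axis=1)
    s2 = np.concatenate([np.zeros((P, 1)), np.cumsum(y**2, axis=1)], axis=1)

    INF = np.inf
    D_prev = np.full((P, T + 1), INF)
    D_prev[:, 0] = 0.0
    args = np.zeros((n_segments + 1, P, T + 1), dtype=np.int32)
    for k in range(1, n_segments + 1):
        D = np.full((P, T + 1), INF)
        for j in range(k, T + 1):
            i_cand = np.arange(k - 1, j)
            n = j - i_cand  # (J,)
            s = s1[:, j][:, None] - s1[:, i_cand]
            cost = (s2[:, j][:, None] - s2[:, i_cand]) - s * s / n
            tot = D_prev[:, i_cand] + cost
            best = np.argmin(tot, axis=1)
            D[:, j] = tot[np.arange(P), best]
            args[k, :, j] = i_cand[best]
        D_prev = D

    levels = np.empty((P, n_segments))
    j = np.full(P, T, dtype=np.int64)
    for k in range(n_segments, 0, -1):
        i = args[k, np.arange(P), j]
        levels[:, k - 1] = (s1[np.arange(P), j] - s1[np.arange(P), i]) / (j - i)
        j = i
    return levels


def cluster_field(
    field: StabilizedField,
    k: int = 3,
    seed: int = 0,
    feature_mode: str = "pwc",
    n_segments: int = 5,
    max_samples_per_curve: int = 150,
) -> np.ndarray:
    """k-means clustering of per-pixel profile descriptors.

    ``feature_mode='pwc'``: optimal piecewise-constant segment levels of
    each (z-scored per feature, time-decimated) pixel curve;
    ``'milestones'``: the (COM, outflow slope) pair. Returns an (H, W)
    int map with labels ordered by ascending cluster-mean COM; invalid
    pixels carry -1.
    """
    if k < 2:
        raise InvalidParameterError("k must be >= 2")
    n_valid = int(field.valid.sum())
    if n_valid < k:
        raise InvalidParameterError(f"{n_valid} valid pixels < k={k}")
    com, slope = pixel_milestones(field)
    curves = field.curves().T  # (P, T)

    if feature_mode == "pwc":
        step = max(1, curves.shape[1] // max_samples_per_curve)
        feats = pwc_levels(curves[:, ::step], n_segments)
    elif feature_mode == "milestones":
        sl = slope[field.valid]
        finite = sl[np.isfinite(sl)]
        fill = float(np.median(finite)) if finite.size else 0.0
        sl = np.where(np.isfinite(sl), sl, fill)
        feats = np.column_stack([com[field.valid], sl])
    else:
        raise InvalidParameterError(f"unknown feature_mode {feature_mode!r}")

    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    feats = (feats - mu) / np.where(sd > 1e-12, sd, 1.0)

    if len(np.unique(feats, axis=0)) < k:
        warnings.warn(
            "fewer distinct profiles than clusters; some clusters will be empty",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed % (2**32))
    labels = km.fit_predict(feats)

    # deterministic relabelling by ascending cluster-mean COM
    com_valid = com[field.valid]
    means = np.array(
        [com_valid[labels == c].mean() if (labels == c).any() else np.inf
         for c in range(k)]
    )
    order = np.argsort(means, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]

    out = np.full(field.valid.shape, -1, dtype=int)
    out[field.valid] = labels
    return out


def render(
    map_: np.ndarray,
    valid: np.ndarray | None = None,
    kind: str = "sequential",
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Render a milestone map to an (H, W, 3) uint8 image.

    ``sequential`` (COM-style) uses viridis with late values at the yellow
    end; ``diverging`` (slope-style) uses a red-negative / blue-positive
    palette centred at zero; ``labels`` colors integer cluster ids.
    Invalid pixels render grey.
    """
    m = np.asarray(map_, dtype=float)
    valid = np.isfinite(m) if valid is None else (valid & np.isfinite(m))
    out = np.full((*m.shape, 3), 128, dtype=np.uint8)
    if not valid.any():
        return out
    vals = m[valid]
    if kind == "sequential":
        lo = vals.min() if vmin is None else vmin
        hi = vals.max() if vmax is None else vmax
        if hi <= lo:
            hi = lo + 1.0
        rgba = colormaps["viridis"](Normalize(lo, hi)(vals))
    elif kind == "diverging":
        amp = np.abs(vals).max() if vmax is None else vmax
        amp = amp if amp > 0 else 1.0
        # RdBu maps low->red, high->blue: negative slopes red, positive blue
        rgba = colormaps["RdBu"](TwoSlopeNorm(vcenter=0.0, vmin=-amp, vmax=amp)(vals))
    elif kind == "labels":
        rgba = colormaps["tab10"]((vals.astype(int) % 10) / 10.0 + 0.05)
    else:
        raise InvalidParameterError(f"unknown render kind {kind!r}")
    out[valid] = (rgba[:, :3] * 255).astype(np.uint8)
    return out
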