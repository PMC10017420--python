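"""Landmark detection and matching between white-light frame pairs.

Shi-Tomasi corners detected on frame A are matched into frame B by
normalized cross-correlation of small patches within a local search
window, refined to sub-pixel precision by parabolic interpolation of the
correlation peak, then filtered by deterministic trimmed least-squares
consensus against a similarity-transform motion model (robustness to the
occasional bad match without RANSAC's sampling randomness).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import corner_peaks, corner_shi_tomasi, match_template

from ..errors import InsufficientLandmarksError, InvalidParameterError

__all__ = [
    "LandmarkConfig",
    "LandmarkMatches",
    "detect_and_match",
    "detect_corners",
    "match_landmarks",
]


@dataclass
class LandmarkConfig:
    max_landmarks: int = 60
    min_matches: int = 6
    patch_half: int = 6  # template half-width (patch is 2h+1 square)
    search_radius: int = 8  # px around the source corner
    min_corner_distance: int = 7
    min_score: float = 0.5  # NCC acceptance threshold per landmark
    consensus_threshold_px: float = 2.0  # residual cut vs similarity model
    consensus_iters: int = 3


@dataclass
class LandmarkMatches:
    """Matched landmark pairs between two frames (row, col coordinates)."""

    src: np.ndarray  # (N, 2) in frame A
    dst: np.ndarray  # (N, 2) in frame B
    scores: np.ndarray  # (N,) NCC peak score

    def __len__(self) -> int:
        return len(self.src)

    @property
    def displacements(self) -> np.ndarray:
        return self.dst - self.src


def _subpixel_peak(ncc: np.ndarray, idx: tuple[int, int]) -> tuple[float, float]:
    """Parabolic refinement of an NCC peak, one axis at a time."""
    out = []
    for axis, i in enumerate(idx):
        if 0 < i < ncc.shape[axis] - 1:
            sl = list(idx)
            sl[axis] = slice(i - 1, i + 2)
            y0, y1, y2 = ncc[tuple(sl)]
            denom = y0 - 2 * y1 + y2
            out.append(i + (0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0))
        else:
            out.append(float(i))
    return out[0], out[1]


def _fit_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares similarity transform; returns predicted dst points."""
    # params [a, b, tr, tc] with rows: r' = a*r - b*c + tr ; c' = b*r + a*c + tc
    n = len(src)
    M = np.zeros((2 * n, 4))
    M[0::2, 0] = src[:, 0]
    M[0::2, 1] = -src[:, 1]
    M[0::2, 2] = 1.0
    M[1::2, 0] = src[:, 1]
    M[1::2, 1] = src[:, 0]
    M[1::2, 3] = 1.0
    rhs = dst.reshape(-1)
    params, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return (M @ params).reshape(-1, 2)


def detect_corners(frame: np.ndarray, cfg: LandmarkConfig | None = None) -> np.ndarray:
    """Shi-Tomasi corner landmarks of one frame, away from the border."""
    cfg = cfg or LandmarkConfig()
    A = np.asarray(frame, dtype=np.float64)
    if A.ndim != 2:
        raise InvalidParameterError("frame must be 2D")
    if A.std() < 1e-9:
        raise InsufficientLandmarksError("featureless (uniform) source frame")
    margin = cfg.patch_half + cfg.search_radius + 1
    corners = corner_peaks(
        corner_shi_tomasi(A),
        min_distance=cfg.min_corner_distance,
        threshold_rel=0.02,
        num_peaks=cfg.max_landmarks,
        exclude_border=margin,
    )
    if len(corners) < cfg.min_matches:
        raise InsufficientLandmarksError(
            f"only {len(corners)} corners detected (need {cfg.min_matches})"
        )
    return corners


def match_landmarks(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    corners: np.ndarray,
    cfg: LandmarkConfig | None = None,
    prior_dst: np.ndarray | None = None,
) -> LandmarkMatches:
    """Match known ``corners`` of ``frame_a`` into ``frame_b`` by NCC.

    ``prior_dst`` (N, 2) centres each landmark's search window on a
    predicted position (e.g. the previous frame's warp), so a small search
    radius tolerates large accumulated motion.
    """
    cfg = cfg or LandmarkConfig()
    A = np.asarray(frame_a, dtype=np.float64)
    B = np.asarray(frame_b, dtype=np.float64)
    if A.shape != B.shape or A.ndim != 2:
        raise InvalidParameterError("frames must be equal-size 2D arrays")
    H, W = A.shape
    h = cfg.patch_half
    s = cfg.search_radius
    src_pts, dst_pts, scores = [], [], []
    for i, (r, c) in enumerate(corners):
        patch = A[r - h : r + h + 1, c - h : c + h + 1]
        if patch.std() < 1e-9:
            continue
        if prior_dst is not None:
            gr, gc = int(round(prior_dst[i, 0])), int(round(prior_dst[i, 1]))
        else:
            gr, gc = int(r), int(c)
        r0, c0 = gr - h - s, gc - h - s
        r1, c1 = gr + h + s + 1, gc + h + s + 1
        if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
            continue
        ncc = match_template(B[r0:r1, c0:c1], patch)
        idx = np.unravel_index(np.argmax(ncc), ncc.shape)
        score = float(ncc[idx])
        if score < cfg.min_score:
            continue
        if score >= 0.9999:
            # integer-perfect match: parabolic refinement would only add
            # a spurious shift from asymmetric correlation falloff
            pr, pc = float(idx[0]), float(idx[1])
        else:
            pr, pc = _subpixel_peak(ncc, idx)
        dst_pts.append((gr - s + pr, gc - s + pc))
        src_pts.append((float(r), float(c)))
        scores.append(score)

    if len(src_pts) < cfg.min_matches:
        raise InsufficientLandmarksError(
            f"only {len(src_pts)} matches above score {cfg.min_score}"
        )
    src = np.array(src_pts)
    dst = np.array(dst_pts)
    sc = np.array(scores)

    # trimmed least-squares consensus against a similarity model
    keep = np.ones(len(src), dtype=bool)
    for _ in range(cfg.consensus_iters):
        if keep.sum() < 3:
            break
        pred = _fit_similarity(src[keep], dst[keep])
        resid = np.full(len(src), np.inf)
        resid[keep] = np.linalg.norm(dst[keep] - pred, axis=1)
        new_keep = resid <= cfg.consensus_threshold_px
        if new_keep.sum() < cfg.min_matches:
            break  # keep the previous (larger) inlier set
        if (new_keep == keep).all():
            break
        keep = new_keep
    if keep.sum() < cfg.min_matches:
        raise InsufficientLandmarksError(
            f"only {int(keep.sum())} consensus inliers (need {cfg.min_matches})"
        )
    return LandmarkMatches(src=src[keep], dst=dst[keep], scores=sc[keep])


def detect_and_match(
    frame_a: np.ndarray, frame_b: np.ndarray, cfg: LandmarkConfig | None = None
) -> LandmarkMatches:
    """Corner landmarks detected on ``frame_a`` and matched into ``frame_b``."""
    cfg = cfg or LandmarkConfig()
    corners = detect_corners(frame_a, cfg)
    return match_landmarks(frame_a, frame_b, corners, cfg)
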