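"""Whole-frame video stabilization by composed TPS warps.

Frames are first temporally decimated to the post-processing rate
(default 7 fps, by nearest-index frame selection so 8-bit values survive
untouched). Landmarks are matched between consecutive retained frames on
the white-light channel, each pair's motion interpolated by a thin-plate
spline, and the warps composed outward from a reference frame (the middle
frame, minimizing accumulated drift). Each NIR frame is then resampled
through the composed warp so every pixel of the output volume follows one
physical tissue point. Pixels that leave the field of view in any frame
are masked invalid (the grey border of the rendered maps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.color import rgb2gray

from ..errors import StabilizationError
from ..reference import POSTPROCESS_FPS
from ..trace_extraction import FrameSequencePair
from ..errors import InsufficientLandmarksError
from .landmarks import LandmarkConfig, detect_corners, match_landmarks
from .tps import fit_tps

__all__ = ["StabilizationConfig", "StabilizedField", "stabilize", "select_frame_indices"]


@dataclass
class StabilizationConfig:
    output_fps: float = POSTPROCESS_FPS
    lam: float = 1.0  # TPS regularization; 0 = exact interpolation
    max_gap: int = 5  # consecutive landmark failures tolerated
    landmarks: LandmarkConfig = field(default_factory=LandmarkConfig)
    keep_warps: bool = False  # retain composed sampling coords per frame


@dataclass
class StabilizedField:
    """Motion-compensated per-pixel intensity volume at the output rate."""

    volume: np.ndarray  # (T', H, W) float32, g.u.
    times: np.ndarray  # (T',) seconds
    valid: np.ndarray  # (H, W) bool; True where observed in every frame
    reference_index: int  # index into the retained frames
    fps: float
    source_indices: np.ndarray  # retained indices into the original stack
    warps: np.ndarray | None = None  # (T', 2, H, W) composed sampling coords

    @property
    def n_frames(self) -> int:
        return self.volume.shape[0]

    def curves(self) -> np.ndarray:
        """(T', n_valid) curves of the valid pixels."""
        return self.volume[:, self.valid]


def select_frame_indices(timestamps: np.ndarray, output_fps: float) -> np.ndarray:
    """Nearest-index decimation of the original stack to ``output_fps``."""
    t0, t1 = timestamps[0], timestamps[-1]
    targets = np.arange(t0, t1 + 1e-9, 1.0 / output_fps)
    idx = np.searchsorted(timestamps, targets)
    idx = np.clip(idx, 0, len(timestamps) - 1)
    left = np.clip(idx - 1, 0, len(timestamps) - 1)
    use_left = np.abs(timestamps[left] - targets) <= np.abs(timestamps[idx] - targets)
    idx = np.where(use_left, left, idx)
    return np.unique(idx)


def stabilize(pair: FrameSequencePair, cfg: StabilizationConfig | None = None) -> StabilizedField:
    """Stabilize the NIR stack against the white-light channel.

    Overlay-only input (no white-light channel) cannot be stabilized; the
    raw decimated stack is returned with full validity.
    """
    cfg = cfg or StabilizationConfig()
    keep = select_frame_indices(pair.timestamps, cfg.output_fps)
    H, W = pair.frame_shape
    n_keep = len(keep)
    ref_pos = n_keep // 2

    nir = pair.nir
    times = pair.timestamps[keep] - pair.timestamps[0]

    if pair.overlay_only:
        vol = nir[keep].astype(np.float32)
        return StabilizedField(
            volume=vol, times=times, valid=np.ones((H, W), dtype=bool),
            reference_index=ref_pos, fps=cfg.output_fps, source_indices=keep,
        )

    grays = [rgb2gray(pair.white[i]).astype(np.float32) for i in keep]
    ref_gray = grays[ref_pos]
    corners = detect_corners(ref_gray, cfg.landmarks)

    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    identity = np.stack([rr.ravel(), cc.ravel()], axis=1)  # (N, 2)

    volume = np.empty((n_keep, H, W), dtype=np.float32)
    valid = np.ones((H, W), dtype=bool)
    volume[ref_pos] = nir[keep[ref_pos]].astype(np.float32)
    warps = None
    if cfg.keep_warps:
        warps = np.empty((n_keep, 2, H, W), dtype=np.float32)
        warps[ref_pos] = identity.T.reshape(2, H, W)

    # each retained frame is matched directly against the reference frame
    # (no warp composition, so sub-pixel matching bias does not accumulate);
    # the previous frame's landmark positions centre the search windows so a
    # small search radius still tolerates large accumulated motion
    for direction in (1, -1):
        sample = np.stack([rr, cc])
        prior = corners.astype(float)
        gap = 0
        pos = ref_pos
        while 0 <= pos + direction < n_keep:
            nxt = pos + direction
            try:
                matches = match_landmarks(
                    ref_gray, grays[nxt], corners, cfg.landmarks, prior_dst=prior
                )
                warp = fit_tps(matches.src, matches.dst, cfg.lam)
                sample = warp.transform(identity).T.reshape(2, H, W)
                prior = warp.transform(corners.astype(float))
                gap = 0
            except InsufficientLandmarksError:
                gap += 1
                if gap > cfg.max_gap:
                    raise StabilizationError(
                        f"landmark matching failed for {gap} consecutive retained "
                        f"frames around index {keep[nxt]}"
                    )
                # reuse the previous frame's warp
            if warps is not None:
                warps[nxt] = sample
            volume[nxt] = map_coordinates(
                nir[keep[nxt]].astype(np.float32), sample, order=1, mode="nearest"
            )
            # half-pixel tolerance so numerical jitter of a near-identity
            # warp does not invalidate the frame edge
            inside = (
                (sample[0] >= -0.5) & (sample[0] <= H - 0.5)
                & (sample[1] >= -0.5) & (sample[1] <= W - 0.5)
            )
            valid &= inside
            pos = nxt

    return StabilizedField(
        volume=volume, times=times, valid=valid, reference_index=ref_pos,
        fps=cfg.output_fps, source_indices=keep, warps=warps,
    )
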