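"""ROI tracking on the white-light channel and NIR trace extraction.

The dual-channel recordings carry a white-light RGB stream (used only for
tracking, since the NIR channel changes appearance as the bolus arrives)
and a synchronized 8-bit NIR greyscale stream holding the ICG signal.
Tracking is translation-only normalized cross-correlation template
matching with periodic template refresh; overlay-only systems (green ICG
overlay burned into the RGB image, no separate white-light output) skip
tracking and use a fixed ROI after green-channel conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.color import rgb2gray
from skimage.draw import polygon as draw_polygon
from skimage.feature import match_template

from .errors import (
    ExtractionError,
    FormatError,
    InvalidParameterError,
    TrackingError,
)
from .reference import ANALYSIS_WINDOW_S, VIDEO_FPS

__all__ = [
    "FrameSequencePair",
    "ROISpec",
    "ROITrack",
    "ROITrace",
    "TrackerConfig",
    "overlay_to_grayscale",
    "track_roi",
    "extract_trace",
]


@dataclass
class FrameSequencePair:
    """Synchronized white-light and NIR stacks.

    white   (T, H, W, 3) uint8, or None for overlay-only recordings
    nir     (T, H, W) uint8 greyscale units
    timestamps  (T,) seconds, strictly increasing
    fps     nominal frame rate
    overlay optional (T, H, W, 3) uint8 green-overlay render (Firefly-style)
    """

    nir: np.ndarray
    timestamps: np.ndarray
    fps: float = VIDEO_FPS
    white: np.ndarray | None = None
    overlay: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nir = np.asarray(self.nir)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.nir.ndim != 3:
            raise FormatError("nir stack must be (T, H, W)")
        if len(self.timestamps) != self.nir.shape[0]:
            raise FormatError("timestamps length must equal frame count")
        if np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.white is not None:
            self.white = np.asarray(self.white)
            if self.white.ndim != 4 or self.white.shape[-1] != 3:
                raise FormatError("white stack must be (T, H, W, 3)")
            if self.white.shape[:3] != self.nir.shape:
                raise FormatError("white and nir stacks must share T, H, W")

    @property
    def n_frames(self) -> int:
        return self.nir.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.nir.shape[1], self.nir.shape[2]

    @property
    def overlay_only(self) -> bool:
        return self.white is None


@dataclass
class ROISpec:
    """A polygonal region of interest annotated with its tissue label.

    Coordinates are 0-based (row, col) pixels in the reference frame.
    """

    polygon: np.ndarray  # (N, 2) float, (row, col)
    label: str
    roi_id: str
    patient_id: str = ""
    frame: int = 0

    def __post_init__(self) -> None:
        self.polygon = np.asarray(self.polygon, dtype=float)
        if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
            raise InvalidParameterError("polygon must be (N>=3, 2) (row, col) vertices")
        shp = _ShapelyPolygon(self.polygon)
        if not shp.is_valid:
            raise InvalidParameterError(f"polygon of roi {self.roi_id!r} is self-intersecting")
        if shp.area < 9.0:
            raise InvalidParameterError(
                f"polygon of roi {self.roi_id!r} has area {shp.area:.1f} < 9 px"
            )

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = draw_polygon(self.polygon[:, 0], self.polygon[:, 1], shape)
        m = np.zeros(shape, dtype=bool)
        m[rr, cc] = True
        return m


@dataclass
class ROITrack:
    """Per-frame integer translation of an ROI plus validity bookkeeping."""

    offsets: np.ndarray  # (T, 2) int, (drow, dcol) relative to reference frame
    valid: np.ndarray  # (T,) bool
    scores: np.ndarray  # (T,) float in [-1, 1]

    @property
    def n_frames(self) -> int:
        return len(self.offsets)


@dataclass
class ROITrace:
    """One region's time-fluorescence curve."""

    times: np.ndarray  # seconds from first frame
    intensities: np.ndarray  # mean g.u. over ROI pixels
    fps: float
    label: str
    roi_id: str
    patient_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise FormatError("times and intensities must have equal length")
        if self.intensities.size and (
            self.intensities.min() < 0 or self.intensities.max() > 255
        ):
            raise FormatError("intensities must lie in [0, 255] g.u.")

    @property
    def n_samples(self) -> int:
        return len(self.times)


@dataclass
class TrackerConfig:
    search_radius: int = 12  # px, per-frame search window half-width
    template_margin: int = 6  # px around the ROI bounding box
    refresh_every: int = 30  # minimum frames between template refreshes
    min_score: float = 0.6  # NCC score below which a frame is invalid
    # refresh only when the match degrades below this score: an unconditional
    # refresh accumulates sub-pixel drift on stable appearance
    refresh_score: float = 0.8


def overlay_to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Green-channel extraction for NIR-overlay (Firefly-style) frames.

    Overlay systems encode the ICG signal in the green channel of the
    composite image; luminance conversion would mix in white-light anatomy.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise FormatError("overlay frame must be (H, W, 3)")
    return frame[..., 1].copy()


def _to_gray(frame_rgb: np.ndarray) -> np.ndarray:
    return rgb2gray(frame_rgb).astype(np.float32)


def track_roi(
    pair: FrameSequencePair, roi: ROISpec, cfg: TrackerConfig | None = None
) -> ROITrack:
    """Track the ROI through the white-light channel.

    Normalized cross-correlation of a template cut around the ROI in the
    reference frame against a search window in every frame; the template is
    refreshed every ``cfg.refresh_every`` frames (from the most recent
    confidently matched frame) to tolerate slow appearance change. Frames
    whose best score falls below ``cfg.min_score`` are flagged invalid and
    carry the last valid offset. Overlay-only input skips tracking.
    """
    cfg = cfg or TrackerConfig()
    T = pair.n_frames
    if not 0 <= roi.frame < T:
        raise InvalidParameterError(f"reference frame {roi.frame} outside [0, {T})")
    if pair.overlay_only:
        return ROITrack(
            offsets=np.zeros((T, 2), dtype=int),
            valid=np.ones(T, dtype=bool),
            scores=np.ones(T),
        )

    H, W = pair.frame_shape
    r0 = max(int(np.floor(roi.polygon[:, 0].min())) - cfg.template_margin, 0)
    r1 = min(int(np.ceil(roi.polygon[:, 0].max())) + cfg.template_margin + 1, H)
    c0 = max(int(np.floor(roi.polygon[:, 1].min())) - cfg.template_margin, 0)
    c1 = min(int(np.ceil(roi.polygon[:, 1].max())) + cfg.template_margin + 1, W)
    if r1 - r0 < 3 or c1 - c0 < 3:
        raise InvalidParameterError("ROI template degenerate after clipping")

    gray_ref = _to_gray(pair.white[roi.frame])
    template = gray_ref[r0:r1, c0:c1]

    offsets = np.zeros((T, 2), dtype=int)
    valid = np.zeros(T, dtype=bool)
    scores = np.full(T, -1.0)
    last_offset = np.zeros(2, dtype=int)
    frames_since_refresh = 0

    order = list(range(roi.frame, T)) + list(range(roi.frame - 1, -1, -1))
    for t in order:
        if t == roi.frame:
            last_offset = np.zeros(2, dtype=int)
            frames_since_refresh = 0
        gray = _to_gray(pair.white[t])
        sr0 = r0 + last_offset[0] - cfg.search_radius
        sc0 = c0 + last_offset[1] - cfg.search_radius
        sr1 = r1 + last_offset[0] + cfg.search_radius
        sc1 = c1 + last_offset[1] + cfg.search_radius
        pr0, pc0 = max(sr0, 0), max(sc0, 0)
        pr1, pc1 = min(sr1, H), min(sc1, W)
        search = gray[pr0:pr1, pc0:pc1]
        if search.shape[0] < template.shape[0] or search.shape[1] < template.shape[1]:
            scores[t] = -1.0
            offsets[t] = last_offset
            continue
        ncc = match_template(search, template)
        idx = np.unravel_index(np.argmax(ncc), ncc.shape)
        score = float(ncc[idx])
        off = np.array([pr0 + idx[0] - r0, pc0 + idx[1] - c0], dtype=int)
        scores[t] = score
        if score >= cfg.min_score:
            offsets[t] = off
            valid[t] = True
            last_offset = off
            frames_since_refresh += 1
            if frames_since_refresh >= cfg.refresh_every and score < cfg.refresh_score:
                tr0, tc0 = r0 + off[0], c0 + off[1]
                if (
                    tr0 >= 0
                    and tc0 >= 0
                    and tr0 + (r1 - r0) <= H
                    and tc0 + (c1 - c0) <= W
                ):
                    template = gray[tr0 : tr0 + (r1 - r0), tc0 : tc0 + (c1 - c0)]
                frames_since_refresh = 0
        else:
            offsets[t] = last_offset
        # entering the backward sweep: restart from the reference state
        if t == order[len(range(roi.frame, T)) - 1] and roi.frame > 0:
            last_offset = np.zeros(2, dtype=int)
            frames_since_refresh = 0
            template = gray_ref[r0:r1, c0:c1]

    if not valid.any():
        raise TrackingError(f"ROI {roi.roi_id!r}: no frame matched above threshold")
    if not valid.all():
        warnings.warn(
            f"ROI {roi.roi_id!r}: {int((~valid).sum())}/{T} frames below match "
            "threshold; carrying last valid offset",
            stacklevel=2,
        )
    return ROITrack(offsets=offsets, valid=valid, scores=scores)


def extract_trace(
    pair: FrameSequencePair,
    track: ROITrack,
    roi: ROISpec,
    window_s: float = ANALYSIS_WINDOW_S,
) -> ROITrace:
    """Mean NIR intensity over the tracked ROI polygon, per frame.

    The trace is truncated to the analysis window [0, window_s) measured
    from the first frame. ROI pixels pushed outside the frame by the offset
    are dropped; a fully clipped ROI raises ExtractionError.
    """
    if track.n_frames != pair.n_frames:
        raise InvalidParameterError("track does not cover all frames")
    H, W = pair.frame_shape
    rr, cc = draw_polygon(roi.polygon[:, 0], roi.polygon[:, 1], (H, W))
    if len(rr) == 0:
        raise ExtractionError(f"ROI {roi.roi_id!r} rasterizes to zero pixels")

    t_rel = pair.timestamps - pair.timestamps[0]
    keep = t_rel < window_s
    nir = pair.nir
    means = np.empty(int(keep.sum()))
    out_i = 0
    for t in np.nonzero(keep)[0]:
        dr, dc = track.offsets[t]
        r = rr + dr
        c = cc + dc
        inside = (r >= 0) & (r < H) & (c >= 0) & (c < W)
        if not inside.any():
            raise ExtractionError(
                f"ROI {roi.roi_id!r} entirely outside frame {t} after offset"
            )
        means[out_i] = nir[t][r[inside], c[inside]].mean()
        out_i += 1
    return ROITrace(
        times=t_rel[keep],
        intensities=means,
        fps=pair.fps,
        label=roi.label,
        roi_id=roi.roi_id,
        patient_id=roi.patient_id,
        meta={"n_pixels": int(len(rr)), "window_s": float(window_s)},
    )
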