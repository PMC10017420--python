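"""Rendering of synthetic dual-channel ICG angiogram videos.

A scene is defined on a padded "world" grid: a tissue class map (healthy
parenchyma, lesion, peri-lesional rim, optional benign cyst, background),
per-class noise-free kinetics, and a smooth per-pixel amplitude field.
Camera motion (global affine random walk) plus a low-spatial-frequency
sinusoidal respiration field displace the sampling grid identically in
both channels; sensor noise and 8-bit quantization are applied last, with
clipping at 255 modelling the saturation ceiling that motivates the low
ICG dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from ..errors import InvalidParameterError
from ..reference import ANALYSIS_WINDOW_S, ICG_DOSE_MG_PER_KG, VIDEO_FPS
from ..trace_extraction import FrameSequencePair
from .kinetics import (
    KineticParams,
    calibrate_kinetics,
    cyst_kinetics,
    perfusion_curve,
    rim_kinetics,
)

__all__ = ["SceneConfig", "TissueClassMap", "GroundTruth", "render_sequence"]

CLASS_IDS = {"background": 0, "healthy": 1, "lesion": 2, "rim": 3, "cyst": 4}


@dataclass
class TissueClassMap:
    """Label image over the frame; values index into CLASS_IDS."""

    labels: np.ndarray  # (H, W) uint8
    legend: dict[str, int] = field(default_factory=lambda: dict(CLASS_IDS))

    def mask(self, name: str) -> np.ndarray:
        return self.labels == self.legend[name]


@dataclass
class SceneConfig:
    """Geometry, kinetics, motion and noise of a synthetic recording.

    Defaults reproduce the study protocol: 30 fps for at least 90 s
    (>= 2698 frames per trace) after a 0.05 mg/kg ICG bolus. Smaller or
    slower configurations are allowed for quick experiments;
    ``meets_study_protocol`` reports whether the protocol holds.
    """

    height: int = 120
    width: int = 160
    fps: float = VIDEO_FPS
    duration_s: float = ANALYSIS_WINDOW_S
    kinetics: dict[str, KineticParams] | None = None  # None -> reference calibration
    lesion_center: tuple[float, float] = (0.45, 0.40)  # fractions of (H, W)
    lesion_radius_frac: float = 0.16
    rim_width_px: float = 4.0
    include_cyst: bool = False
    cyst_center: tuple[float, float] = (0.55, 0.78)
    cyst_radius_frac: float = 0.10
    border_px: int = 4  # background band at the frame edge
    amplitude_jitter_sd: float = 0.06  # per-pixel multiplicative, smooth field
    affine_step_sd_px: float = 0.12  # camera translation random-walk step
    rotation_step_sd_rad: float = 0.0004
    respiration_amplitude_px: float = 2.5
    respiration_period_s: float = 4.0
    noise_sd: float = 2.0  # per-pixel sensor noise, g.u.
    overlay_mode: bool = False
    dose_mg_per_kg: float = ICG_DOSE_MG_PER_KG  # informational

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise InvalidParameterError("scene must be at least 16x16 px")
        if self.fps <= 0 or self.duration_s <= 0:
            raise InvalidParameterError("fps and duration must be positive")
        if self.noise_sd < 0 or self.amplitude_jitter_sd < 0:
            raise InvalidParameterError("noise SDs must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def meets_study_protocol(self) -> bool:
        return self.duration_s >= 90.0 and self.n_frames >= 2698

    def resolved_kinetics(self) -> dict[str, KineticParams]:
        if self.kinetics is not None:
            return dict(self.kinetics)
        cal = calibrate_kinetics()
        healthy = cal["healthy"]
        return {
            "healthy": healthy,
            "lesion": cal["crlm"],
            "rim": rim_kinetics(healthy),
            "cyst": cyst_kinetics(healthy),
            "background": KineticParams(
                baseline=4.0, arrival_delay=1.0, time_to_peak=60.0,
                amplitude=1.0, shape=1.0,
            ),
        }


@dataclass
class GroundTruth:
    """Everything the generator knows: class map, per-class curves, motion."""

    config: SceneConfig
    class_map: TissueClassMap
    kinetics: dict[str, KineticParams]
    amplitude_field: np.ndarray  # (H, W) multiplicative factor on amplitude
    translations: np.ndarray  # (T, 2) camera translation (drow, dcol)
    rotations: np.ndarray  # (T,) camera rotation about the frame centre, rad
    respiration_envelope: np.ndarray  # (H, W) in [0, 1]
    respiration_direction: np.ndarray  # (2,) unit vector
    respiration_phase: float
    timestamps: np.ndarray

    def displacement(self, frame_idx: int) -> np.ndarray:
        """(2, H, W) displacement added to frame coords when sampling the
        world: frame(r, c) = world((r, c) + displacement)."""
        H, W = self.class_map.labels.shape
        rr, cc = np.mgrid[0:H, 0:W].astype(float)
        cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        th = self.rotations[frame_idx]
        # small-angle rotation about the centre plus translation
        dr = (np.cos(th) - 1) * (rr - cy) - np.sin(th) * (cc - cx)
        dc = np.sin(th) * (rr - cy) + (np.cos(th) - 1) * (cc - cx)
        dr = dr + self.translations[frame_idx, 0]
        dc = dc + self.translations[frame_idx, 1]
        t = self.timestamps[frame_idx]
        resp = self.config.respiration_amplitude_px * np.sin(
            2 * np.pi * t / self.config.respiration_period_s + self.respiration_phase
        )
        dr = dr + resp * self.respiration_envelope * self.respiration_direction[0]
        dc = dc + resp * self.respiration_envelope * self.respiration_direction[1]
        return np.stack([dr, dc])

    def noise_free_trace(self, mask: np.ndarray) -> np.ndarray:
        """Mean noise-free, motion-free curve over a pixel mask (world frame)."""
        t = self.timestamps
        out = np.zeros_like(t)
        total = int(mask.sum())
        for name, pid in self.class_map.legend.items():
            sel = mask & (self.class_map.labels == pid)
            n = int(sel.sum())
            if n == 0:
                continue
            p = self.kinetics[name if name != "lesion" else "lesion"]
            curve = perfusion_curve(t, p)
            amp_mean = self.amplitude_field[sel].mean()
            out = out + n * (p.baseline + amp_mean * (curve - p.baseline))
        return out / total


def _build_class_map(cfg: SceneConfig, H: int, W: int) -> np.ndarray:
    labels = np.full((H, W), CLASS_IDS["healthy"], dtype=np.uint8)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    min_dim = min(cfg.height, cfg.width)
    lc = (cfg.lesion_center[0] * H, cfg.lesion_center[1] * W)
    lr = cfg.lesion_radius_frac * min_dim
    d_lesion = np.hypot(rr - lc[0], cc - lc[1])
    labels[d_lesion <= lr + cfg.rim_width_px] = CLASS_IDS["rim"]
    labels[d_lesion <= lr] = CLASS_IDS["lesion"]
    if cfg.include_cyst:
        kc = (cfg.cyst_center[0] * H, cfg.cyst_center[1] * W)
        kr = cfg.cyst_radius_frac * min_dim
        labels[np.hypot(rr - kc[0], cc - kc[1]) <= kr] = CLASS_IDS["cyst"]
    if cfg.border_px > 0:
        b = cfg.border_px
        labels[:b, :] = CLASS_IDS["background"]
        labels[-b:, :] = CLASS_IDS["background"]
        labels[:, :b] = CLASS_IDS["background"]
        labels[:, -b:] = CLASS_IDS["background"]
    return labels


def _white_texture(rng: np.random.Generator, H: int, W: int) -> np.ndarray:
    """Trackable static white-light texture in [0, 1], (H, W)."""
    base = 0.55 + 0.18 * gaussian_filter(rng.standard_normal((H, W)), 8)
    speckle = 0.10 * gaussian_filter(rng.standard_normal((H, W)), 1.0)
    tex = base + speckle
    # scatter small dark vessel-like spots: strong corners for landmarks
    n_spots = max(20, (H * W) // 250)
    rs = rng.uniform(2, H - 3, n_spots)
    cs = rng.uniform(2, W - 3, n_spots)
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    for r, c in zip(rs, cs):
        rad = rng.uniform(1.2, 2.8)
        tex -= 0.35 * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * rad**2))
    return np.clip(tex, 0.02, 0.98)


def render_sequence(
    config: SceneConfig, seed: int
) -> tuple[FrameSequencePair, GroundTruth]:
    """Render a synthetic dual-channel recording; deterministic per seed.

    Returns the frame pair plus the full ground-truth record (class map,
    per-pixel amplitude field, per-frame true motion). The white-light
    channel carries static trackable texture; the NIR channel follows the
    per-class kinetics; both share identical motion.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    H, W = cfg.height, cfg.width
    pad = int(np.ceil(abs(cfg.respiration_amplitude_px) + 3 * cfg.affine_step_sd_px
                      * np.sqrt(max(cfg.n_frames, 1)) + 4))
    Hw, Ww = H + 2 * pad, W + 2 * pad

    kin = cfg.resolved_kinetics()
    labels_world = _build_class_map(cfg, Hw, Ww)
    # smooth unit-SD field scaled to the requested per-pixel jitter
    smooth = gaussian_filter(rng.standard_normal((Hw, Ww)), 6)
    amp_world = 1.0 + cfg.amplitude_jitter_sd * smooth / max(smooth.std(), 1e-12)

    white_world_gray = _white_texture(rng, Hw, Ww)
    tint = np.array([1.0, 0.55, 0.45])
    white_world = np.clip(white_world_gray[..., None] * tint[None, None, :], 0, 1)

    T = cfg.n_frames
    timestamps = np.arange(T) / cfg.fps
    translations = np.cumsum(
        rng.normal(0.0, cfg.affine_step_sd_px, size=(T, 2)), axis=0
    )
    rotations = np.cumsum(rng.normal(0.0, cfg.rotation_step_sd_rad, size=T))
    if cfg.affine_step_sd_px == 0:
        translations[:] = 0.0
    if cfg.rotation_step_sd_rad == 0:
        rotations[:] = 0.0
    env = gaussian_filter(rng.standard_normal((H, W)), max(H, W) / 5.0)
    env = (env - env.min()) / max(env.max() - env.min(), 1e-12)
    direction = np.array([0.8, 0.6])
    phase = rng.uniform(0, 2 * np.pi) if cfg.respiration_amplitude_px else 0.0

    gt = GroundTruth(
        config=cfg,
        class_map=TissueClassMap(labels_world[pad : pad + H, pad : pad + W].copy()),
        kinetics=kin,
        amplitude_field=amp_world[pad : pad + H, pad : pad + W].copy(),
        translations=translations,
        rotations=rotations,
        respiration_envelope=env,
        respiration_direction=direction / np.linalg.norm(direction),
        respiration_phase=phase,
        timestamps=timestamps,
    )

    # per-class scalar curves, evaluated once
    class_curves = {
        name: perfusion_curve(timestamps, p) for name, p in kin.items()
    }
    name_of_id = {v: k for k, v in CLASS_IDS.items()}
    baseline_world = np.zeros((Hw, Ww))
    for cid in np.unique(labels_world):
        name = name_of_id[int(cid)]
        key = "lesion" if name == "lesion" else name
        baseline_world[labels_world == cid] = kin[key].baseline

    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    static_coords = np.stack([rr + pad, cc + pad])
    has_motion = (
        cfg.affine_step_sd_px > 0
        or cfg.rotation_step_sd_rad > 0
        or cfg.respiration_amplitude_px != 0
    )

    nir = np.empty((T, H, W), dtype=np.uint8)
    white = np.empty((T, H, W, 3), dtype=np.uint8)
    overlay = np.empty((T, H, W, 3), dtype=np.uint8) if cfg.overlay_mode else None
    noisy = cfg.noise_sd > 0

    for t in range(T):
        nir_world = baseline_world.copy()
        for cid in np.unique(labels_world):
            name = name_of_id[int(cid)]
            key = "lesion" if name == "lesion" else name
            sel = labels_world == cid
            p = kin[key]
            rise = class_curves[key][t] - p.baseline
            nir_world[sel] += amp_world[sel] * rise
        if has_motion:
            coords = static_coords + gt.displacement(t)
        else:
            coords = static_coords
        frame = map_coordinates(nir_world, coords, order=1, mode="nearest")
        if noisy:
            frame = frame + rng.normal(0.0, cfg.noise_sd, size=(H, W))
        nir[t] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)
        for ch in range(3):
            wch = map_coordinates(white_world[..., ch], coords, order=1, mode="nearest")
            wf = wch * 255.0
            if noisy:
                wf = wf + rng.normal(0.0, 1.0, size=(H, W))
            white[t, ..., ch] = np.clip(np.rint(wf), 0, 255).astype(np.uint8)
        if overlay is not None:
            dimmed = (white[t].mean(axis=-1) * 0.25).astype(np.uint8)
            overlay[t, ..., 0] = dimmed
            overlay[t, ..., 1] = nir[t]
            overlay[t, ..., 2] = dimmed

    pair = FrameSequencePair(
        nir=nir,
        timestamps=timestamps,
        fps=cfg.fps,
        white=None if cfg.overlay_mode else white,
        overlay=overlay,
    )
    return pair, gt
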