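"""Synthetic fresh-frozen microscopy sections with known emission ratios.

A section holds a lesion region embedded in healthy parenchyma. Healthy
liver concentrates ICG and fluoresces strongly; lesion tissue barely at
all. H&E staining plus cover slipping attenuates the fluorescence signal
by a constant factor (default 6.5): the stained rendering is the unstained
rendering divided by the attenuation factor, before pixel texture noise.
Pixel texture is multiplicative lognormal with unit mean so region means
are preserved in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidParameterError
from ..reference import MICROSCOPY_SIGNAL_PER_AREA, STAINING_ATTENUATION

__all__ = ["SectionConfig", "SectionImage", "render_microscopy_section"]


@dataclass
class SectionConfig:
    height: int = 128
    width: int = 160
    healthy_emission: float = MICROSCOPY_SIGNAL_PER_AREA["healthy"][0]
    lesion_emission: float = MICROSCOPY_SIGNAL_PER_AREA["crlm"][0]
    texture_cv: float = 0.25  # per-pixel lognormal texture
    attenuation: float = STAINING_ATTENUATION
    lesion_center: tuple[float, float] = (0.5, 0.42)
    lesion_radius_frac: float = 0.30

    def __post_init__(self) -> None:
        if self.attenuation <= 0:
            raise InvalidParameterError("attenuation factor must be > 0")
        if self.healthy_emission < 0 or self.lesion_emission < 0:
            raise InvalidParameterError("emissions must be >= 0")


@dataclass
class SectionImage:
    """Fluorescence microscopy section with region masks."""

    image: np.ndarray  # (H, W) float, arbitrary units >= 0
    masks: dict[str, np.ndarray] = field(default_factory=dict)  # lesion / healthy
    stained: bool = False
    attenuation: float = STAINING_ATTENUATION


def render_microscopy_section(
    config: SectionConfig | None = None,
    stained: bool = False,
    seed: int = 0,
) -> SectionImage:
    """Render one section; same seed gives identical tissue + texture, so
    the stained image equals the unstained image divided by the
    attenuation factor, pixel for pixel."""
    cfg = config or SectionConfig()
    rng = np.random.default_rng(seed)
    H, W = cfg.height, cfg.width
    rr, cc = np.mgrid[0:H, 0:W].astype(float)
    lc = (cfg.lesion_center[0] * H, cfg.lesion_center[1] * W)
    lr = cfg.lesion_radius_frac * min(H, W)
    lesion = np.hypot(rr - lc[0], cc - lc[1]) <= lr
    healthy = ~lesion
    if not lesion.any() or not healthy.any():
        raise InvalidParameterError("lesion/healthy masks must both be non-empty")

    emission = np.where(lesion, cfg.lesion_emission, cfg.healthy_emission)
    if cfg.texture_cv > 0:
        sigma = np.sqrt(np.log1p(cfg.texture_cv**2))
        texture = np.exp(rng.normal(-sigma**2 / 2, sigma, size=(H, W)))
    else:
        texture = np.ones((H, W))
    image = emission * texture
    if stained:
        image = image / cfg.attenuation
    return SectionImage(
        image=image,
        masks={"lesion": lesion, "healthy": healthy},
        stained=stained,
        attenuation=cfg.attenuation,
    )
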