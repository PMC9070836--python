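"""Synthetic Wiesner-stained stem cross-sections with known ground truth.

A stem section is rendered as concentric annuli on a neutral background:
pith, xylem ring, cortex, epidermis.  Lignin staining is painted as
contiguous angular sectors of the cortex (plus, optionally, the whole
xylem ring).  Default colors are chosen so that, in the a* (green–red)
channel, unstained tissue and stain sit symmetrically around the neutral
background mode — the adaptive histogram-peak threshold then falls at
the half-maximum of blurred stain boundaries, so blob edges are not
systematically inflated or eroded by the blur.

Staining grows from seeded start angles in a fixed angular order, so for
a fixed seed the stained set at a lower ``cortex_stain_fraction`` is a
subset of the set at a higher one (a monotone fixture ladder).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..imaging import RoiSet

# Rendered colors (8-bit sRGB).  a8 values: background 128.0 (neutral),
# tissue ~114, stain ~143 — symmetric about the background mode.
BACKGROUND_RGB = (246, 246, 246)
TISSUE_RGB = (200, 225, 195)
STAIN_RGB = (190, 152, 160)
PITH_RGB = (205, 230, 196)
EPIDERMIS_RGB = (170, 200, 165)


@dataclass
class SectionSpec:
    """Geometry, staining and noise parameters for one rendered section.

    Radii are in pixels from the section center and must be strictly
    nested: pith < xylem inner < xylem outer < cortex inner < cortex
    outer < epidermis.
    """

    image_size: tuple[int, int] = (512, 512)
    radius_pith: float = 70.0
    radius_xylem_inner: float = 80.0
    radius_xylem_outer: float = 120.0
    radius_cortex_inner: float = 135.0
    radius_cortex_outer: float = 190.0
    radius_epidermis: float = 200.0
    cortex_stain_fraction: float = 0.3
    xylem_stained: bool = True
    stain_color: tuple[int, int, int] = STAIN_RGB
    tissue_color: tuple[int, int, int] = TISSUE_RGB
    noise_sd: float = 4.0
    n_blobs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        radii = [
            self.radius_pith,
            self.radius_xylem_inner,
            self.radius_xylem_outer,
            self.radius_cortex_inner,
            self.radius_cortex_outer,
            self.radius_epidermis,
        ]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError(f"section radii must be strictly nested, got {radii}")
        if not 0.0 <= self.cortex_stain_fraction <= 1.0:
            raise ValueError("cortex_stain_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_blobs < 1:
            raise ValueError("n_blobs must be >= 1")


@dataclass
class RenderedSection:
    """A rendered image plus its generative ground truth."""

    image: np.ndarray  # HxWx3 uint8
    lignin_mask: np.ndarray  # true stained pixels (pre-noise, pre-blur)
    rois: RoiSet
    spec: SectionSpec


def _stained_cortex(spec: SectionSpec, cortex: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Select a contiguous-sector subset of cortex pixels covering the target fraction.

    Cortex pixels are ranked by angular distance to the nearest of
    ``n_blobs`` seeded start angles; the stained set is the prefix of
    that ranking reaching ``cortex_stain_fraction`` of the cortex area.
    The ranking depends only on the seed, so stain sets are nested
    across fractions.
    """
    target = int(round(spec.cortex_stain_fraction * cortex.sum()))
    out = np.zeros_like(cortex)
    if target == 0:
        return out
    if spec.cortex_stain_fraction >= 1.0:
        return cortex.copy()
    rng = np.random.default_rng(spec.seed)
    starts = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_blobs)
    th = theta[cortex]
    # circular distance to nearest start angle
    d = np.min(
        np.abs((th[:, None] - starts[None, :] + np.pi) % (2.0 * np.pi) - np.pi), axis=1
    )
    order = np.argsort(d, kind="stable")[:target]
    idx = np.flatnonzero(cortex.ravel())[order]
    out.ravel()[idx] = True
    return out


def render_section(spec: SectionSpec) -> RenderedSection:
    """Render one section; deterministic for a fixed seed."""
    h, w = spec.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx) % (2.0 * np.pi)

    pith = r < spec.radius_pith
    xylem = (r >= spec.radius_xylem_inner) & (r < spec.radius_xylem_outer)
    cortex = (r >= spec.radius_cortex_inner) & (r < spec.radius_cortex_outer)
    section = r < spec.radius_epidermis
    epidermis = (r >= spec.radius_cortex_outer) & section
    gaps = section & ~(pith | xylem | cortex | epidermis)

    stained_cortex = _stained_cortex(spec, cortex, theta)
    lignin = stained_cortex | (xylem if spec.xylem_stained else np.zeros_like(xylem))

    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = BACKGROUND_RGB
    image[pith] = PITH_RGB
    image[gaps] = spec.tissue_color
    image[xylem] = spec.tissue_color
    image[cortex] = spec.tissue_color
    image[epidermis] = EPIDERMIS_RGB
    image[lignin] = spec.stain_color

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng(spec.seed + 1)
        image += noise_rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    rois = RoiSet(xylem_mask=xylem, cortex_mask=cortex, section_mask=section)
    return RenderedSection(image=image, lignin_mask=lignin, rois=rois, spec=spec)
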