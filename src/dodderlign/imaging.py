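"""Lignin quantification in Wiesner-stained stem cross-sections.

Phloroglucinol–HCl stains lignin red against pale tissue.  The procedure
implemented here quantifies the stained area adaptively, per image:

1. Gaussian blur (sigma 2.0 px) to suppress sensor noise.
2. Conversion to CIELAB, with each channel rescaled to the 8-bit range
   (L*: 0..100 -> 0..255; a*, b*: -128..127 -> 0..255).
3. Histogram-peak thresholding: a pixel is called lignin when its
   lightness is at or below the modal L bin AND its green–red value is at
   or above the modal a bin.  The blue–yellow channel is unrestricted.
   Because unstained tissue plus background dominate the histograms, the
   modes track the pale phase and the red stain falls in the selected
   dark/red tails.
4. ROI arithmetic: the xylem (constitutively lignified) area is
   subtracted from the total stained area to isolate the defensive
   cortex lignification, reported as a percentage of the cortex ROI.

The threshold is adaptive: peaks are recomputed for every image.  On a
degenerate constant image every pixel trivially satisfies both
conditions (<= / >= its own peak), so the mask covers the whole frame;
the procedure presupposes that unstained tissue dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2lab


@dataclass
class ImagingParams:
    """Tunable parameters of the stain-segmentation procedure.

    sigma
        Gaussian blur radius in pixels. Default 2.0.
    histogram_bins
        Number of histogram bins; 256 for 8-bit channels.
    """

    sigma: float = 2.0
    histogram_bins: int = 256

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.histogram_bins < 1:
            raise ValueError("histogram_bins must be >= 1")


@dataclass
class RoiSet:
    """Region-of-interest masks for one section.

    All three masks share the image shape; xylem and cortex are disjoint
    subsets of the whole-section mask.
    """

    xylem_mask: np.ndarray
    cortex_mask: np.ndarray
    section_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xylem_mask", "cortex_mask", "section_mask"):
            m = getattr(self, name)
            if m.dtype != bool:
                setattr(self, name, m.astype(bool))
        if not (
            self.xylem_mask.shape == self.cortex_mask.shape == self.section_mask.shape
        ):
            raise ValueError("ROI masks must share one shape")
        if np.any(self.xylem_mask & ~self.section_mask) or np.any(
            self.cortex_mask & ~self.section_mask
        ):
            raise ValueError("xylem/cortex ROIs must lie inside the section ROI")
        if np.any(self.xylem_mask & self.cortex_mask):
            raise ValueError("xylem and cortex ROIs overlap")


@dataclass
class LabImage:
    """CIELAB channels rescaled to [0, 255] (float)."""

    L8: np.ndarray
    a8: np.ndarray
    b8: np.ndarray


@dataclass
class LigninQuant:
    """Pixel bookkeeping for one section.

    cortex_lignin_pct is the stained-cortex area as a percentage of the
    cortex ROI area — the denominator that stays comparable across
    sections of different overall size.
    """

    total_lignin_px: int
    xylem_lignin_px: int
    cortex_lignin_px: int
    cortex_area_px: int
    cortex_lignin_pct: float


def _check_rgb8(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {image.shape}")
    if image.dtype != np.uint8:
        if image.min() < 0 or image.max() > 255:
            raise ValueError("image values must lie in [0, 255]")
        image = image.astype(np.uint8)
    return image


def gaussian_smooth(image: np.ndarray, params: ImagingParams | None = None) -> np.ndarray:
    """Per-channel Gaussian blur with reflective borders, re-quantized to 8-bit."""
    params = params or ImagingParams()
    image = _check_rgb8(image)
    out = np.empty_like(image)
    for c in range(3):
        blurred = gaussian_filter(
            image[:, :, c].astype(np.float64), sigma=params.sigma, mode="reflect"
        )
        out[:, :, c] = np.clip(np.rint(blurred), 0, 255).astype(np.uint8)
    return out


def rgb_to_lab8(image: np.ndarray) -> LabImage:
    """sRGB (D65) -> CIELAB, channels affinely rescaled to the 8-bit range."""
    image = _check_rgb8(image)
    lab = rgb2lab(image)  # L in [0,100], a/b roughly [-128,127]
    return LabImage(
        L8=lab[:, :, 0] * (255.0 / 100.0),
        a8=lab[:, :, 1] + 128.0,
        b8=lab[:, :, 2] + 128.0,
    )


def histogram_peak(channel: np.ndarray, bins: int = 256) -> int:
    """Index of the fullest histogram bin over [0, 256); ties -> lowest index."""
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("cannot take the histogram peak of an empty channel")
    counts, _ = np.histogram(channel, bins=bins, range=(0.0, 256.0))
    return int(np.argmax(counts))  # argmax returns the first maximum


def _bin_width(bins: int) -> float:
    return 256.0 / bins


def lignin_mask(lab: LabImage, bins: int = 256) -> np.ndarray:
    """Adaptive stain mask: (L8 <= peak(L8)) AND (a8 >= peak(a8)).

    Peak comparisons use the upper/lower edge of the modal bin so that
    pixels inside the modal bin satisfy their own condition, matching an
    inclusive 0..peak (lightness) and peak..255 (green–red) filter.
    """
    w = _bin_width(bins)
    l_peak = histogram_peak(lab.L8, bins)
    a_peak = histogram_peak(lab.a8, bins)
    return (lab.L8 < (l_peak + 1) * w) & (lab.a8 >= a_peak * w)


def quantify_cortex_lignin(mask: np.ndarray, rois: RoiSet) -> LigninQuant:
    """ROI arithmetic: cortex lignin = total stained − stained xylem."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != rois.section_mask.shape:
        raise ValueError("mask and ROI shapes differ")
    cortex_area = int(rois.cortex_mask.sum())
    if cortex_area == 0:
        raise ValueError("cortex ROI is empty; percentage undefined")
    total = int((mask & rois.section_mask).sum())
    xylem = int((mask & rois.xylem_mask).sum())
    cortex = total - xylem
    return LigninQuant(
        total_lignin_px=total,
        xylem_lignin_px=xylem,
        cortex_lignin_px=cortex,
        cortex_area_px=cortex_area,
        # boundary false positives outside the cortex ROI can push the raw
        # ratio marginally past 100; the percentage is clipped to [0, 100]
        cortex_lignin_pct=float(np.clip(100.0 * cortex / cortex_area, 0.0, 100.0)),
    )


def quantify_section(
    image: np.ndarray, rois: RoiSet, params: ImagingParams | None = None
) -> LigninQuant:
    """Full procedure on one section: blur -> Lab -> adaptive mask -> ROI arithmetic."""
    params = params or ImagingParams()
    smoothed = gaussian_smooth(image, params)
    lab = rgb_to_lab8(smoothed)
    mask = lignin_mask(lab, params.histogram_bins)
    return quantify_cortex_lignin(mask, rois)


# ---------------------------------------------------------------------------
# file I/O

def read_image(path: str) -> np.ndarray:
    """Read an 8-bit RGB image from PNG/TIFF."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(image: np.ndarray, path: str) -> None:
    from PIL import Image

    Image.fromarray(_check_rgb8(image), mode="RGB").save(path)


def read_mask(path: str) -> np.ndarray:
    """Read a boolean mask from a single-channel PNG (nonzero = True)."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_mask(mask: np.ndarray, path: str) -> None:
    from PIL import Image

    Image.fromarray((np.asarray(mask, bool) * np.uint8(255)), mode="L").save(path)


def write_overlay(image: np.ndarray, mask: np.ndarray, path: str) -> None:
    """Visual QC overlay: detected lignin pixels painted pure red."""
    overlay = _check_rgb8(image).copy()
    overlay[np.asarray(mask, bool)] = (255, 0, 0)
    write_image(overlay, path)
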