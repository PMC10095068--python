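"""HSI colour model, stain thresholding and optical density.

The hue/saturation/intensity (HSI) decomposition used here is the classic
intensity-mean variant:

    I = (R + G + B) / 3                     (normalised to [0, 1])
    S = 1 - min(R, G, B) / I                (0 where I = 0)
    H = angular hue in degrees, 0-360, with H(achromatic) := 0

A stain-positive mask is the conjunction of a hue window (which may wrap
through 360° → 0°), a saturation window and an intensity window.  Optical
density is the Beer–Lambert transform of intensity against a background
reference, OD = −log10(I / I_bg), clamped to [0, OD_MAX].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CalibratedImage

#: Clamp for per-pixel optical density; ~3 OD is the dynamic range of
#: 8-bit brightfield data (I = 1/255 on white background).
OD_MAX = 3.0


@dataclass(frozen=True)
class HSIThresholds:
    """Hue/saturation/intensity windows defining a stain-positive pixel.

    ``hue`` is in degrees and may wrap (lo > hi means the window crosses
    360° → 0°, e.g. (350, 10) accepts 355° and 5°). ``saturation`` and
    ``intensity`` are closed sub-intervals of [0, 1].
    """

    hue: tuple[float, float]
    saturation: tuple[float, float] = (0.0, 1.0)
    intensity: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        h_lo, h_hi = self.hue
        if not (0.0 <= h_lo <= 360.0 and 0.0 <= h_hi <= 360.0):
            raise ValueError(f"hue window must lie in [0, 360], got {self.hue}")
        for name, (lo, hi) in (("saturation", self.saturation), ("intensity", self.intensity)):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} window must be a sub-interval of [0, 1], got {(lo, hi)}")


@dataclass(frozen=True)
class StainMask:
    """Binary raster of stain-positive pixels plus the thresholds used."""

    mask: np.ndarray
    thresholds: HSIThresholds

    @property
    def count(self) -> int:
        return int(self.mask.sum())


def rgb_to_hsi(image: CalibratedImage | np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose an 8-bit RGB raster into (hue°, saturation, intensity).

    Returns three float arrays of the image's spatial shape.  Hue of
    achromatic pixels (R = G = B) is 0 by convention; saturation at pure
    black is 0.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    rgb = px.astype(np.float64)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    s = r + g + b
    intensity = s / (3.0 * 255.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(s > 0, 1.0 - 3.0 * np.minimum(np.minimum(r, g), b) / s, 0.0)

    # angular hue: cos θ = [ (r−g) + (r−b) ] / (2 √((r−g)² + (r−b)(g−b)))
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.where(achromatic, 1.0, num / np.where(achromatic, 1.0, den))
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    hue = np.where(b > g, 360.0 - theta, theta)
    hue = np.where(achromatic, 0.0, hue)
    return hue, sat, intensity


def _hue_in_window(hue: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if lo <= hi:
        return (hue >= lo) & (hue <= hi)
    # wrapping window, e.g. (350, 10)
    return (hue >= lo) | (hue <= hi)


def threshold_hsi(image: CalibratedImage | np.ndarray, thresholds: HSIThresholds) -> StainMask:
    """Binary stain mask: pixels inside all three HSI windows."""
    hue, sat, intensity = rgb_to_hsi(image)
    t = thresholds
    m = _hue_in_window(hue, *t.hue)
    m &= (sat >= t.saturation[0]) & (sat <= t.saturation[1])
    m &= (intensity >= t.intensity[0]) & (intensity <= t.intensity[1])
    return StainMask(mask=m, thresholds=t)


def background_reference(image: CalibratedImage | np.ndarray, percentile: float = 95.0) -> float:
    """Robust background intensity: a high percentile of image intensity.

    Brightfield backgrounds are the brightest extended region of a slide,
    so the 95th percentile tracks illumination without being hijacked by
    a handful of saturated pixels.
    """
    _, _, intensity = rgb_to_hsi(image)
    ref = float(np.percentile(intensity, percentile))
    if ref <= 0:
        raise ValueError("background reference intensity is zero; image is black")
    return ref


def optical_density(
    image: CalibratedImage | np.ndarray,
    mask: StainMask | np.ndarray | None = None,
    background: float | None = None,
) -> np.ndarray:
    """Per-pixel optical density OD = −log10(I / I_bg), clamped to [0, OD_MAX].

    Pixels at or above the background intensity get OD 0.  When ``mask``
    is given, OD outside the mask is zeroed; the mask must match the
    image's spatial shape.  ``background`` defaults to the 95th-percentile
    intensity of the image.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    if background is None:
        background = background_reference(px)
    if background <= 0:
        raise ValueError(f"background reference must be positive, got {background}")
    _, _, intensity = rgb_to_hsi(px)
    with np.errstate(divide="ignore"):
        od = -np.log10(np.maximum(intensity, 1e-12) / background)
    od = np.clip(od, 0.0, OD_MAX)
    if mask is not None:
        m = mask.mask if isinstance(mask, StainMask) else np.asarray(mask, dtype=bool)
        if m.shape != od.shape:
            raise ValueError(f"mask shape {m.shape} does not match image shape {od.shape}")
        od = np.where(m, od, 0.0)
    return od
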