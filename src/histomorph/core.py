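"""Core containers: calibrated images and per-image ground truth.

All measurements in this package are expressed in micrometres; the only
bridge between pixel rasters and physical units is the ``scale`` carried
by :class:`CalibratedImage` (μm per pixel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit RGB raster with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3), dtype uint8
        The image data.
    scale : float
        Pixel size in μm/pixel. Must be positive.
    image_id : str
        Identifier used to key ground truth and manifest rows.
    """

    pixels: np.ndarray
    scale: float
    image_id: str = ""

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be positive μm/pixel, got {self.scale}")
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {px.dtype}")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def height_um(self) -> float:
        return self.pixels.shape[0] * self.scale

    @property
    def width_um(self) -> float:
        return self.pixels.shape[1] * self.scale

    def to_um(self, rc: np.ndarray) -> np.ndarray:
        """Convert (row, col) pixel coordinates to (y, x) μm."""
        return np.asarray(rc, dtype=float) * self.scale

    def save(self, path: str | Path) -> None:
        """Write the raster as an 8-bit RGB TIFF with resolution metadata."""
        ppu = 1.0 / self.scale  # pixels per μm
        tifffile.imwrite(
            str(path),
            self.pixels,
            photometric="rgb",
            resolution=(ppu, ppu),
            resolutionunit="NONE",
        )

    @classmethod
    def load(cls, path: str | Path, scale: float, image_id: str = "") -> "CalibratedImage":
        px = tifffile.imread(str(path))
        if px.dtype != np.uint8:
            px = np.clip(px, 0, 255).astype(np.uint8)
        return cls(pixels=px, scale=scale, image_id=image_id or Path(path).stem)


@dataclass
class GroundTruth:
    """Exact per-image truth emitted alongside every generated image.

    Only populated fields are meaningful for a given image kind: skin
    sections fill layer and nucleus fields, mast-cell fields fill the
    cell list.
    """

    image_id: str = ""
    scale: float = 1.0
    # Skin section truth -------------------------------------------------
    #: per-layer per-column vertical thickness in μm, keyed by layer name
    layer_thickness_profile: dict[str, np.ndarray] = field(default_factory=dict)
    #: (y, x) μm centroids of every rendered nucleus, shape (n, 2)
    nucleus_coords_um: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    #: label raster of nucleus pixels (0 = background, k = nucleus k)
    nucleus_label_raster: np.ndarray | None = None
    #: (y, x, lumen_diameter) μm for every vessel
    vessels_um: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    # Mast-cell field truth ----------------------------------------------
    #: one dict per cell: center_um (y, x), soma_diameter_um,
    #: granule_fraction, label ("resting"/"activated"), stained_px count
    mast_cells: list[dict] = field(default_factory=list)
    #: label raster of stained pixels (0 = background, k = cell k)
    mc_label_raster: np.ndarray | None = None

    @property
    def nucleus_count(self) -> int:
        return int(self.nucleus_coords_um.shape[0])

    def mean_layer_thickness(self, layer: str) -> float:
        """Column-averaged true thickness of one layer, μm."""
        prof = self.layer_thickness_profile[layer]
        return float(np.mean(prof))

    def layer_band(self, layer: str) -> tuple[float, float]:
        """Vertical (top, bottom) μm extent of the layer's truth band."""
        top = self.layer_tops_um[layer]
        thick = self.layer_thickness_profile[layer]
        return float(np.min(top)), float(np.max(top + thick))

    #: per-layer per-column top boundary y in μm (filled by the generator)
    layer_tops_um: dict[str, np.ndarray] = field(default_factory=dict)
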