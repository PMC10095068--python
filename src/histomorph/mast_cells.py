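"""Mast-cell identification and IOD/A activation scoring.

Methylene-blue-stained mast cells are segmented by HSI thresholding;
stain fragments lying within a linking radius of each other are merged
into one cell, because a degranulated cell sheds granules around its
soma.  Per cell we measure the stained area A (μm²), the integrated
optical density IOD (OD·μm², summed over the cell's stained pixels), and
the intensive ratio IOD/A — stain density per unit stained area.

A resting cell packs overlapping granules into a compact soma, so its
per-pixel density is high; dispersal during degranulation thins the
deposit.  Cells with IOD/A at or above a calibrated threshold are
labelled resting, below it activated.  The threshold is calibrated from
labelled training cells by an exhaustive 1-D sweep minimising
misclassification (midpoint of class means when perfectly separable).
Absolute IOD values are in artifact-defined OD units; only ratio
comparisons against the calibrated threshold are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk as _disk

from .color_ops import HSIThresholds, optical_density, threshold_hsi
from .core import CalibratedImage

RESTING = "resting"
ACTIVATED = "activated"


@dataclass(frozen=True)
class CellRegion:
    """One segmented cell: its stained-pixel mask and the image scale."""

    mask: np.ndarray  # boolean, full-image frame
    scale: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MastCellMeasurement:
    """Per-cell morphometry: area, integrated OD, their ratio, label."""

    cell_id: int
    A_um2: float
    IOD: float  # OD · μm²
    ratio: float  # IOD / A, intensive
    centroid_um: tuple[float, float]
    label: str | None = None


@dataclass(frozen=True)
class MCPopulationSummary:
    """Densities per mm² of total / resting / activated cells."""

    total_per_mm2: float
    resting_per_mm2: float
    activated_per_mm2: float
    activated_fraction: float
    n_cells: int
    n_images: int
    surveyed_area_mm2: float


def segment_mast_cells(
    image: CalibratedImage,
    thresholds: HSIThresholds,
    min_area_um2: float = 20.0,
    link_radius_um: float = 10.0,
) -> list[CellRegion]:
    """Segment mast cells, merging granule fragments into whole cells.

    The stain mask is dilated by half the linking radius, so fragments
    separated by gaps up to ``link_radius_um`` join one connected
    component; each cell's region is the set of *original* stained pixels
    under that component.  Merged regions below ``min_area_um2`` are
    discarded as debris.
    """
    scale = image.scale
    mask = threshold_hsi(image, thresholds).mask
    if not mask.any():
        return []
    link_px = max(1, int(round(link_radius_um / 2 / scale)))
    fused = ndimage.binary_dilation(mask, structure=_disk(link_px))
    lab, n = ndimage.label(fused)
    regions: list[CellRegion] = []
    min_px = min_area_um2 / scale**2
    for k in range(1, n + 1):
        cell_mask = mask & (lab == k)
        if cell_mask.sum() < min_px:
            continue
        regions.append(CellRegion(mask=cell_mask, scale=scale))
    return regions


def measure_cell(region: CellRegion, od: np.ndarray) -> MastCellMeasurement:
    """Measure area, IOD and their ratio over one cell region.

    A = stained pixel count × scale²; IOD = Σ OD over those pixels ×
    scale²; ratio = IOD / A equals the mean per-pixel OD.
    """
    if od.shape != region.mask.shape:
        raise ValueError(f"OD raster shape {od.shape} does not match region {region.mask.shape}")
    npx = region.area_px
    if npx == 0:
        raise ValueError("zero-area cell region")
    s2 = region.scale**2
    a = npx * s2
    iod = float(od[region.mask].sum()) * s2
    rr, cc = np.nonzero(region.mask)
    return MastCellMeasurement(
        cell_id=0,
        A_um2=float(a),
        IOD=iod,
        ratio=iod / a,
        centroid_um=(float(rr.mean() * region.scale), float(cc.mean() * region.scale)),
    )


def measure_image(
    image: CalibratedImage,
    thresholds: HSIThresholds,
    min_area_um2: float = 20.0,
    link_radius_um: float = 10.0,
    background: float | None = None,
) -> list[MastCellMeasurement]:
    """Segment and measure every mast cell of one image."""
    regions = segment_mast_cells(image, thresholds, min_area_um2, link_radius_um)
    if not regions:
        return []
    od = optical_density(image, background=background)
    out = []
    for i, reg in enumerate(regions):
        m = measure_cell(reg, od)
        out.append(MastCellMeasurement(cell_id=i, A_um2=m.A_um2, IOD=m.IOD, ratio=m.ratio, centroid_um=m.centroid_um))
    return out


def classify_activation(
    cells: list[MastCellMeasurement],
    ratio_threshold: float,
    surveyed_area_mm2: float = 1.0,
    n_images: int = 1,
    low_ratio_is_activated: bool = True,
) -> tuple[list[MastCellMeasurement], MCPopulationSummary]:
    """Label cells resting/activated by IOD/A and summarise densities.

    With the default direction, ratio ≥ threshold ⇒ resting (compact,
    densely stained) and ratio < threshold ⇒ activated (dispersed,
    thinly stained); the flag flips the rule if a different stain
    behaviour is calibrated.  An empty cell list yields a summary of
    zeros.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    labeled = []
    for c in cells:
        act = (c.ratio < ratio_threshold) if low_ratio_is_activated else (c.ratio >= ratio_threshold)
        labeled.append(
            MastCellMeasurement(
                cell_id=c.cell_id,
                A_um2=c.A_um2,
                IOD=c.IOD,
                ratio=c.ratio,
                centroid_um=c.centroid_um,
                label=ACTIVATED if act else RESTING,
            )
        )
    n = len(labeled)
    n_act = sum(1 for c in labeled if c.label == ACTIVATED)
    n_rest = n - n_act
    summary = MCPopulationSummary(
        total_per_mm2=n / surveyed_area_mm2,
        resting_per_mm2=n_rest / surveyed_area_mm2,
        activated_per_mm2=n_act / surveyed_area_mm2,
        activated_fraction=(n_act / n) if n else 0.0,
        n_cells=n,
        n_images=n_images,
        surveyed_area_mm2=surveyed_area_mm2,
    )
    return labeled, summary


def calibrate_threshold(ratios: np.ndarray, labels: list[str] | np.ndarray) -> float:
    """Calibrate the IOD/A decision threshold from labelled training cells.

    Sweeps every midpoint between adjacent sorted ratios and returns the
    cut minimising misclassification under the rule "ratio < threshold ⇒
    activated"; when the classes are perfectly separable this is the
    midpoint between the closest opposing pair, and for well-separated
    class means it coincides with the midpoint of class means.

    Raises ``ValueError`` if either class is missing or the classes are
    indistinguishable (identical ratio sets).
    """
    ratios = np.asarray(ratios, dtype=float)
    labels = np.asarray(labels)
    if ratios.shape != labels.shape:
        raise ValueError("ratios and labels must align")
    act = ratios[labels == ACTIVATED]
    rest = ratios[labels == RESTING]
    if len(act) == 0 or len(rest) == 0:
        raise ValueError("both classes must be represented in the training cells")
    if np.array_equal(np.sort(act), np.sort(rest)):
        raise ValueError("classes have identical ratio distributions; threshold is undefined")

    if act.max() < rest.min():  # separable: midpoint of class means
        return float((act.mean() + rest.mean()) / 2)

    order = np.sort(np.unique(ratios))
    cuts = (order[:-1] + order[1:]) / 2
    best_t, best_err = None, np.inf
    for t in cuts:
        err = int(np.sum(act >= t)) + int(np.sum(rest < t))
        if err < best_err:
            best_err, best_t = err, float(t)
    if best_t is None:
        raise ValueError("no admissible threshold found")
    return best_t
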