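"""Nucleus detection and infiltration counting in circular ROIs.

Hematoxylin-stained nuclei are segmented by HSI thresholding, clumps are
split by watershed on the distance transform, and candidate objects are
kept only if they satisfy nucleus-like morphometric windows (area,
elongation, solidity).  Counts are then taken inside fixed-diameter
circular ROIs — tiling the hypodermal band, or centred on annotated
blood-vessel lumens for perivascular infiltration.

Membership is centroid-in-closed-disk: a nucleus belongs to a ROI iff its
centroid lies inside or exactly on the circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import segmentation as skseg

from .color_ops import HSIThresholds, threshold_hsi
from .core import CalibratedImage


@dataclass(frozen=True)
class NucleusFilter:
    """Morphometric windows a connected component must satisfy to count
    as a nucleus: area (μm²), major/minor elongation bound, solidity floor."""

    area_um2: tuple[float, float] = (10.0, 80.0)
    elongation_max: float = 3.0
    solidity_min: float = 0.8

    def __post_init__(self) -> None:
        if self.area_um2[0] <= 0 or self.area_um2[1] < self.area_um2[0]:
            raise ValueError(f"area window must be a positive interval, got {self.area_um2}")
        if self.elongation_max < 1:
            raise ValueError("elongation_max must be ≥ 1")


@dataclass(frozen=True)
class Nucleus:
    """One detected nucleus: centroid (y, x) μm plus shape descriptors."""

    centroid_um: tuple[float, float]
    area_um2: float
    elongation: float
    solidity: float


@dataclass(frozen=True)
class InfiltrationReport:
    """Per-ROI nucleus counts with ROI geometry and the per-image mean."""

    counts: tuple[int, ...]
    centers_um: tuple[tuple[float, float], ...]
    diameter_um: float
    context: str  # "whole_hypodermis" or "perivascular"

    @property
    def mean_count(self) -> float:
        return float(np.mean(self.counts))


def detect_nuclei(
    image: CalibratedImage,
    thresholds: HSIThresholds,
    nucleus_filter: NucleusFilter | None = None,
) -> list[Nucleus]:
    """Detect nuclei by HSI thresholding + watershed + shape filtering.

    Components larger than ~1.5× the filter's area ceiling are assumed to
    be clumps and split by watershed seeded at distance-transform maxima;
    smaller components pass through unsplit, which keeps slightly lobed
    single nuclei intact.  Objects failing any filter window (area,
    elongation, solidity) are discarded.  An empty result is valid.
    """
    f = nucleus_filter or NucleusFilter()
    scale = image.scale
    mask = threshold_hsi(image, thresholds).mask
    if not mask.any():
        return []

    lab, n = ndimage.label(mask)
    max_single_px = 1.5 * f.area_um2[1] / scale**2
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    clump_labels = np.flatnonzero(sizes > max_single_px) + 1

    if clump_labels.size:
        clump_mask = np.isin(lab, clump_labels)
        dist = ndimage.distance_transform_edt(clump_mask)
        # seeds: distance maxima at least a typical nucleus radius apart
        min_dist_px = max(2, int(round(np.sqrt(f.area_um2[0] / np.pi) / scale)))
        peaks = skfeature.peak_local_max(
            dist, min_distance=min_dist_px, labels=clump_mask, exclude_border=False
        )
        markers = np.zeros_like(lab)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.any():
            ws = skseg.watershed(-dist, markers=markers, mask=clump_mask)
            lab = np.where(clump_mask, ws + lab.max(), lab)
            # relabel: equal-valued connected runs become distinct objects
            lab = skmeasure.label(lab, background=0)

    nuclei: list[Nucleus] = []
    for rp in skmeasure.regionprops(lab):
        area = rp.area * scale**2
        if not (f.area_um2[0] <= area <= f.area_um2[1]):
            continue
        minor = max(rp.axis_minor_length, 1e-9)
        elong = rp.axis_major_length / minor
        if elong > f.elongation_max:
            continue
        if rp.solidity < f.solidity_min:
            continue
        cy, cx = rp.centroid
        nuclei.append(
            Nucleus(
                centroid_um=(cy * scale, cx * scale),
                area_um2=float(area),
                elongation=float(elong),
                solidity=float(rp.solidity),
            )
        )
    return nuclei


def count_in_rois(
    nuclei: list[Nucleus],
    rois: list[tuple[float, float]],
    diameter_um: float = 75.0,
    context: str = "whole_hypodermis",
) -> InfiltrationReport:
    """Count detected nuclei inside each circular ROI (closed disk).

    ``rois`` are (y, x) centres in μm; the diameter is shared by every
    ROI of a report.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    if diameter_um <= 0:
        raise ValueError("ROI diameter must be positive")
    r = diameter_um / 2
    centers = np.asarray(rois, dtype=float)
    if len(nuclei) == 0:
        counts = [0] * len(rois)
    else:
        pts = np.array([nu.centroid_um for nu in nuclei])
        d = np.hypot(pts[None, :, 0] - centers[:, None, 0], pts[None, :, 1] - centers[:, None, 1])
        counts = (d <= r).sum(axis=1).astype(int).tolist()
    return InfiltrationReport(
        counts=tuple(int(c) for c in counts),
        centers_um=tuple((float(y), float(x)) for y, x in centers),
        diameter_um=float(diameter_um),
        context=context,
    )


def tile_band_rois(
    band_top_um: np.ndarray,
    band_bottom_um: np.ndarray,
    width_um: float,
    diameter_um: float = 75.0,
) -> list[tuple[float, float]]:
    """Hexagonally tile a horizontal tissue band with disjoint circular ROIs.

    ROI centres keep one radius clear of the band boundaries; rows are
    offset by half a spacing (hex packing) so the band is covered evenly.
    """
    r = diameter_um / 2
    spacing = diameter_um
    row_step = spacing * np.sqrt(3) / 2
    centers: list[tuple[float, float]] = []
    top = float(np.max(band_top_um))
    bot = float(np.min(band_bottom_um))
    y = top + r
    row = 0
    while y <= bot - r:
        x0 = r + (spacing / 2 if row % 2 else 0.0)
        x = x0
        while x <= width_um - r:
            centers.append((y, x))
            x += spacing
        y += row_step
        row += 1
    return centers


def perivascular_rois(
    image: CalibratedImage,
    vessel_centers_um: np.ndarray | list[tuple[float, float]],
    diameter_um: float = 75.0,
    dropped: list | None = None,
) -> list[tuple[float, float]]:
    """One ROI of the stated diameter centred on each vessel lumen.

    Vessels close enough to the image edge that the ROI would be clipped
    are dropped; their centres are appended to ``dropped`` when given.
    """
    r = diameter_um / 2
    H_um, W_um = image.height_um, image.width_um
    keep: list[tuple[float, float]] = []
    for v in np.asarray(vessel_centers_um, dtype=float).reshape(-1, 2):
        y, x = float(v[0]), float(v[1])
        if r <= y <= H_um - r and r <= x <= W_um - r:
            keep.append((y, x))
        elif dropped is not None:
            dropped.append((y, x))
    return keep
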