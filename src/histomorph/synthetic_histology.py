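"""Synthetic stained-section generator with exact ground truth.

Two image families are emulated, at the level of detail the downstream
measurements actually consume:

* **H&E-like skin sections** — three horizontally stacked wavy layers
  (epidermis, dermis, hypodermis) of distinct colour, scattered
  hematoxylin-coloured elliptical nuclei, and ring-shaped blood-vessel
  lumens in the hypodermis.  Ground truth records the analytic per-column
  thickness of every layer, every nucleus centroid, and every vessel.

* **Methylene-blue-like mast-cell fields** — isolated cells rendered as
  collections of small stained granules.  A resting cell packs its
  granules densely inside the soma; a degranulated (activated) cell
  scatters fewer granules over a wider halo.  Granule optical densities
  add where granules overlap, so compact cells are darker per stained
  pixel — the physical basis of the IOD/A activation readout.

Cohort simulation composes these generators into a 2×2 antigen ×
resveratrol experiment (groups SV, OV, SR, OR) with per-group effect
multipliers and lognormal mouse-level variability.

Everything is driven by explicit integer seeds; identical (spec, seed)
pairs produce bit-identical images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .core import CalibratedImage, GroundTruth

# ---------------------------------------------------------------------------
# Palette (8-bit RGB).  Chosen so that each object class occupies a distinct
# HSI region; the default thresholds in `palette_thresholds` are calibrated
# against these colours, not against any real stain.
# ---------------------------------------------------------------------------
BACKGROUND_RGB = (245, 245, 245)
BACKGROUND_NOISE_SD = 3.0
EPIDERMIS_RGB = (60, 80, 200)  # blue
DERMIS_RGB = (150, 60, 180)  # purple
HYPODERMIS_RGB = (90, 180, 100)  # green
NUCLEUS_RGB = (70, 40, 120)  # hematoxylin-like dark blue-violet
VESSEL_WALL_RGB = (200, 90, 120)  # eosinophilic pink ring

#: Per-channel Beer–Lambert attenuation weights for the methylene-blue-like
#: granule stain: red/green absorb strongly, blue weakly, so stained pixels
#: read as blue-violet.
MB_CHANNEL_WEIGHTS = np.array([1.4, 1.1, 0.35])

LAYER_NAMES = ("epidermis", "dermis", "hypodermis")
GROUPS = ("SV", "OV", "SR", "OR")


def palette_thresholds() -> dict:
    """Default HSI windows matched to the generator palette."""
    from .color_ops import HSIThresholds

    return {
        "epidermis": HSIThresholds(hue=(215, 248), saturation=(0.25, 1.0), intensity=(0.30, 0.60)),
        "dermis": HSIThresholds(hue=(275, 310), saturation=(0.25, 1.0), intensity=(0.35, 0.65)),
        "hypodermis": HSIThresholds(hue=(95, 160), saturation=(0.25, 1.0), intensity=(0.30, 0.65)),
        "nuclei": HSIThresholds(hue=(248, 278), saturation=(0.25, 1.0), intensity=(0.02, 0.40)),
        "mast_cell": HSIThresholds(hue=(180, 320), saturation=(0.08, 1.0), intensity=(0.0, 0.85)),
    }


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayerSpec:
    """Geometry and colour of one skin layer.

    ``mean_thickness`` is the layer's average vertical extent in μm;
    boundaries undulate as a sinusoid of ``waviness_amplitude`` /
    ``waviness_period`` plus smooth Gaussian noise of ``boundary_noise_sd``.
    """

    name: str
    mean_thickness: float
    waviness_amplitude: float | None = None  # default: 8% of thickness
    waviness_period: float | None = None  # default: 10× thickness
    fill_color: tuple[int, int, int] | None = None
    boundary_noise_sd: float | None = None  # default: 1.5% of thickness

    def __post_init__(self) -> None:
        if self.name not in LAYER_NAMES:
            raise ValueError(f"layer name must be one of {LAYER_NAMES}, got {self.name!r}")
        if self.mean_thickness <= 0:
            raise ValueError(f"mean_thickness must be positive, got {self.mean_thickness}")
        amp = self.amplitude
        if amp >= self.mean_thickness / 2:
            raise ValueError(
                f"waviness_amplitude {amp} must be < mean_thickness/2 "
                f"({self.mean_thickness / 2}) so layers never self-intersect"
            )

    @property
    def amplitude(self) -> float:
        return 0.08 * self.mean_thickness if self.waviness_amplitude is None else self.waviness_amplitude

    @property
    def period(self) -> float:
        # boundary undulation wavelength scales with layer thickness (so
        # slopes stay gentle for thick layers) but is capped: a section a
        # few hundred μm wide should still contain whole cycles, keeping
        # the per-image mean thickness close to nominal
        if self.waviness_period is not None:
            return self.waviness_period
        return min(10.0 * self.mean_thickness, 1000.0)

    @property
    def noise_corr_um(self) -> float:
        return max(20.0, 0.5 * self.mean_thickness)

    @property
    def noise_sd(self) -> float:
        return 0.015 * self.mean_thickness if self.boundary_noise_sd is None else self.boundary_noise_sd

    @property
    def color(self) -> tuple[int, int, int]:
        if self.fill_color is not None:
            return self.fill_color
        return {
            "epidermis": EPIDERMIS_RGB,
            "dermis": DERMIS_RGB,
            "hypodermis": HYPODERMIS_RGB,
        }[self.name]


def default_layers(epidermis: float = 30.0, dermis: float = 250.0, hypodermis: float = 200.0) -> list[LayerSpec]:
    return [
        LayerSpec("epidermis", epidermis),
        LayerSpec("dermis", dermis),
        LayerSpec("hypodermis", hypodermis),
    ]


@dataclass(frozen=True)
class NucleusField:
    """Scattered hematoxylin-like nuclei.

    ``density`` is nuclei per mm² of tissue; axes are (major, minor)
    diameter ranges in μm.  With ``overlap_allowed`` False, centres keep a
    minimum separation of the largest major axis plus 1 μm.
    """

    density: float = 300.0
    major_axis_um: tuple[float, float] = (7.0, 11.0)
    minor_axis_um: tuple[float, float] = (5.0, 8.0)
    color: tuple[int, int, int] = NUCLEUS_RGB
    overlap_allowed: bool = False

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError(f"density must be ≥ 0, got {self.density}")
        if not (self.major_axis_um[0] >= self.minor_axis_um[0] > 0):
            raise ValueError("require major ≥ minor > 0 for nucleus axes")


@dataclass(frozen=True)
class VesselField:
    """Ring-shaped blood-vessel lumens placed in the hypodermis."""

    count: int = 3
    lumen_diameter_um: tuple[float, float] = (20.0, 40.0)
    wall_thickness_um: float = 4.0
    wall_color: tuple[int, int, int] = VESSEL_WALL_RGB


@dataclass(frozen=True)
class MastCellSpec:
    """One mast cell: soma size, granulation and activation truth label.

    ``granule_fraction`` is the expected fraction of soma pixels carrying
    stain.  Activated (degranulated) cells additionally scatter their
    granules up to ``scatter_radius`` μm beyond the soma edge.
    """

    soma_diameter_um: tuple[float, float] = (12.0, 18.0)
    granule_fraction: float = 0.9
    stain_intensity: float = 0.5  # optical density deposited per granule layer
    scatter_radius_um: float = 0.0
    truth_label: str = "resting"

    def __post_init__(self) -> None:
        if not 0.0 <= self.granule_fraction <= 1.0:
            raise ValueError(f"granule_fraction must be in [0, 1], got {self.granule_fraction}")
        if self.truth_label not in ("resting", "activated"):
            raise ValueError(f"truth_label must be 'resting' or 'activated', got {self.truth_label!r}")
        if self.stain_intensity <= 0:
            raise ValueError("stain_intensity must be positive")


def resting_cell(granule_fraction: float = 0.9) -> MastCellSpec:
    return MastCellSpec(granule_fraction=granule_fraction, scatter_radius_um=0.0, truth_label="resting")


def activated_cell(granule_fraction: float = 0.3, scatter_radius_um: float = 6.0) -> MastCellSpec:
    return MastCellSpec(
        granule_fraction=granule_fraction,
        scatter_radius_um=scatter_radius_um,
        truth_label="activated",
    )


# ---------------------------------------------------------------------------
# Internal helpers
# ---------------------------------------------------------------------------


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    base = np.array(BACKGROUND_RGB, dtype=np.float64)
    img = base[None, None, :] + rng.normal(0.0, BACKGROUND_NOISE_SD, size=(*shape, 3))
    return np.clip(img, 0, 255)


def _smooth_noise(n: int, sd: float, smooth_um: float, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth 1-D Gaussian process of marginal sd ``sd`` sampled at n columns."""
    raw = rng.normal(0.0, 1.0, size=n)
    if sd == 0:
        return np.zeros(n)
    sm = ndimage.gaussian_filter1d(raw, sigma=smooth_um / scale, mode="wrap")
    s = sm.std()
    return sm * (sd / s) if s > 0 else np.zeros(n)


def _fill_color(img: np.ndarray, where: np.ndarray, color: tuple[int, int, int], rng: np.random.Generator) -> None:
    n = int(where.sum())
    col = np.array(color, dtype=np.float64)
    img[where] = col[None, :] + rng.normal(0.0, 2.0, size=(n, 3))


def _place_points(
    n: int,
    lo: np.ndarray,
    hi: np.ndarray,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> np.ndarray:
    """Dart-throwing placement of n points in a box with minimum separation.

    Returns the (k, 2) array of points placed (k ≤ n if the box saturates).
    Uses a coarse occupancy grid so placement stays linear in n.
    """
    if n == 0:
        return np.empty((0, 2))
    span = hi - lo
    if min_sep <= 0:
        return lo + rng.random((n, 2)) * span
    cell = min_sep
    grid: dict[tuple[int, int], list[np.ndarray]] = {}
    pts: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(max_tries):
            p = lo + rng.random(2) * span
            ci, cj = int(p[0] // cell), int(p[1] // cell)
            ok = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    for q in grid.get((ci + di, cj + dj), ()):
                        if np.hypot(*(p - q)) < min_sep:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((ci, cj), []).append(p)
                pts.append(p)
                break
    return np.array(pts) if pts else np.empty((0, 2))


# ---------------------------------------------------------------------------
# Skin sections
# ---------------------------------------------------------------------------


def generate_skin_section(
    layers: list[LayerSpec],
    nuclei: NucleusField | None = None,
    vessels: VesselField | None = None,
    scale: float = 1.0,
    seed: int = 0,
    width_um: float = 2000.0,
    margin_um: float = 30.0,
    perivascular_factor: float = 1.0,
    perivascular_radius_um: float = 75.0,
    image_id: str = "",
) -> tuple[CalibratedImage, GroundTruth]:
    """Render a three-layer skin section and its exact ground truth.

    The tissue is a stack of wavy horizontal bands spanning the full image
    width, sitting below a background margin.  Nuclei are Poisson-sampled
    over the tissue area at the requested density (plus an optional
    perivascular enrichment around vessel centres) and drawn as filled
    ellipses; vessels are rings in the hypodermis.

    Returns the calibrated image and a :class:`GroundTruth` holding the
    analytic per-column thickness of each layer, every nucleus centroid,
    and every vessel centre.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive μm/pixel, got {scale}")
    if [l.name for l in layers] != list(LAYER_NAMES[: len(layers)]):
        raise ValueError(f"layers must be ordered {LAYER_NAMES}, got {[l.name for l in layers]}")
    colors = [l.color for l in layers]
    if len({tuple(c) for c in colors}) != len(colors):
        raise ValueError("layer fill colours must be distinct")

    rng = np.random.default_rng(seed)
    total_thickness = sum(l.mean_thickness for l in layers)
    height_um = 2 * margin_um + total_thickness * 1.15
    H = int(round(height_um / scale))
    W = int(round(width_um / scale))
    if H < 4 or W < 4:
        raise ValueError("image too small to contain the requested layers at this scale")
    if total_thickness + 2 * margin_um > H * scale + 1e-9:
        raise ValueError(
            f"layer thicknesses sum to {total_thickness} μm which exceeds the "
            f"{H * scale} μm image height"
        )

    x_um = (np.arange(W) + 0.5) * scale

    # Boundary curves, μm.  The epidermal surface undulates with the
    # epidermis' own waviness; each layer's lower boundary adds the layer's
    # sinusoid + smooth noise to its thickness, so the per-column thickness
    # profile is known analytically before rasterisation.
    surf = layers[0]
    phase0 = rng.uniform(0, 2 * np.pi)
    top = margin_um + surf.amplitude * np.sin(2 * np.pi * x_um / surf.period + phase0)
    top = top + _smooth_noise(W, surf.noise_sd, surf.noise_corr_um, scale, rng)

    boundaries = [top]
    profiles: dict[str, np.ndarray] = {}
    tops: dict[str, np.ndarray] = {}
    for lay in layers:
        phase = rng.uniform(0, 2 * np.pi)
        thick = (
            lay.mean_thickness
            + lay.amplitude * np.sin(2 * np.pi * x_um / lay.period + phase)
            + _smooth_noise(W, lay.noise_sd, lay.noise_corr_um, scale, rng)
        )
        thick = np.maximum(thick, scale)  # layers never vanish
        tops[lay.name] = boundaries[-1].copy()
        profiles[lay.name] = thick
        boundaries.append(boundaries[-1] + thick)
    bounds_px = np.stack(boundaries) / scale  # (n+1, W)

    if np.any(bounds_px[-1] > H - 1):
        raise ValueError("layer stack exceeds image height; increase margins or image size")

    img = _background((H, W), rng)
    rows = np.arange(H)[:, None]
    # counts = number of boundaries at or above each pixel row
    counts = np.zeros((H, W), dtype=np.int8)
    for b in bounds_px:
        counts += (rows >= b[None, :]).astype(np.int8)
    # counts == 0: background above; counts == k in 1..n: inside layer k-1;
    # counts == n+1: background below
    for k, lay in enumerate(layers):
        _fill_color(img, counts == k + 1, lay.color, rng)

    truth = GroundTruth(image_id=image_id, scale=scale)
    truth.layer_thickness_profile = profiles
    truth.layer_tops_um = tops

    tissue_top_um = boundaries[0]
    tissue_bot_um = boundaries[-1]

    # Vessels (drawn before nuclei so perivascular nuclei can overlay walls)
    vessel_list = []
    if vessels is not None and vessels.count > 0 and len(layers) == 3:
        hypo_top = boundaries[2]
        hypo_bot = boundaries[3]
        for _ in range(vessels.count):
            d = rng.uniform(*vessels.lumen_diameter_um)
            r_out = d / 2 + vessels.wall_thickness_um
            for _try in range(50):
                cx = rng.uniform(r_out + 2, width_um - r_out - 2)
                j = min(W - 1, int(cx / scale))
                ylo = hypo_top[j] + r_out + 2
                yhi = hypo_bot[j] - r_out - 2
                if yhi <= ylo:
                    continue
                cy = rng.uniform(ylo, yhi)
                if all(np.hypot(cy - v[0], cx - v[1]) > r_out + v[2] / 2 + vessels.wall_thickness_um + 4 for v in vessel_list):
                    break
            else:
                continue
            rr, cc = skdraw.disk((cy / scale, cx / scale), r_out / scale, shape=(H, W))
            wall = np.zeros((H, W), dtype=bool)
            wall[rr, cc] = True
            rr, cc = skdraw.disk((cy / scale, cx / scale), (d / 2) / scale, shape=(H, W))
            lumen = np.zeros((H, W), dtype=bool)
            lumen[rr, cc] = True
            _fill_color(img, wall & ~lumen, vessels.wall_color, rng)
            _fill_color(img, lumen, BACKGROUND_RGB, rng)
            vessel_list.append((cy, cx, d))
    truth.vessels_um = np.array(vessel_list) if vessel_list else np.empty((0, 3))

    # Nuclei: Poisson count over tissue area, uniform placement inside the
    # tissue band (rejection on the per-column band), optional enrichment
    # around vessels.
    nuc_centers: list[np.ndarray] = []
    nuc_label = np.zeros((H, W), dtype=np.int32)
    if nuclei is not None and nuclei.density > 0:
        tissue_area_mm2 = float(np.sum(tissue_bot_um - tissue_top_um)) * scale / 1e6
        n_expected = nuclei.density * tissue_area_mm2
        n_draw = int(rng.poisson(n_expected))
        min_sep = 0.0 if nuclei.overlap_allowed else nuclei.major_axis_um[1] + 1.0

        # rejection-sample uniform positions within the wavy tissue band
        lo = np.array([float(tissue_top_um.min()), 0.0])
        hi = np.array([float(tissue_bot_um.max()), width_um])
        pts = _place_points(int(n_draw * 1.6) + 8, lo, hi, min_sep, rng)
        inside = []
        for p in pts:
            j = min(W - 1, int(p[1] / scale))
            if tissue_top_um[j] + 3 <= p[0] <= tissue_bot_um[j] - 3:
                inside.append(p)
            if len(inside) == n_draw:
                break
        pts = np.array(inside) if inside else np.empty((0, 2))

        if perivascular_factor > 1.0 and len(vessel_list) > 0:
            extra_rate = nuclei.density * (perivascular_factor - 1.0)
            for (vy, vx, _d) in vessel_list:
                area_mm2 = np.pi * perivascular_radius_um**2 / 1e6
                k = int(rng.poisson(extra_rate * area_mm2))
                placed = 0
                for _try in range(k * 30 + 10):
                    if placed >= k:
                        break
                    ang = rng.uniform(0, 2 * np.pi)
                    rad = perivascular_radius_um * np.sqrt(rng.random())
                    p = np.array([vy + rad * np.sin(ang), vx + rad * np.cos(ang)])
                    j = int(np.clip(p[1] / scale, 0, W - 1))
                    if not (tissue_top_um[j] + 3 <= p[0] <= tissue_bot_um[j] - 3):
                        continue
                    if 0 + 3 <= p[1] <= width_um - 3 and (
                        min_sep == 0
                        or len(pts) == 0
                        or np.min(np.hypot(*(pts - p).T)) >= min_sep
                    ):
                        pts = np.vstack([pts, p]) if len(pts) else p[None, :]
                        placed += 1

        for k, (py, px_) in enumerate(pts, start=1):
            maj = rng.uniform(*nuclei.major_axis_um)
            mnr = rng.uniform(*nuclei.minor_axis_um)
            mnr = min(mnr, maj)
            theta = rng.uniform(0, np.pi)
            rr, cc = skdraw.ellipse(
                py / scale, px_ / scale, (maj / 2) / scale, (mnr / 2) / scale,
                shape=(H, W), rotation=theta,
            )
            if rr.size == 0:
                continue
            col = np.array(nuclei.color, dtype=np.float64)
            img[rr, cc] = col[None, :] + rng.normal(0.0, 2.0, size=(rr.size, 3))
            nuc_label[rr, cc] = k
            nuc_centers.append(np.array([py, px_]))

    truth.nucleus_coords_um = np.array(nuc_centers) if nuc_centers else np.empty((0, 2))
    truth.nucleus_label_raster = nuc_label

    image = CalibratedImage(pixels=np.clip(img, 0, 255).astype(np.uint8), scale=scale, image_id=image_id)
    return image, truth


# ---------------------------------------------------------------------------
# Mast-cell fields
# ---------------------------------------------------------------------------


def generate_mc_field(
    cells: list[MastCellSpec],
    scale: float = 0.25,
    seed: int = 0,
    field_um: tuple[float, float] = (220.0, 220.0),
    min_separation_um: float = 50.0,
    granule_radius_um: float = 1.2,
    image_id: str = "",
) -> tuple[CalibratedImage, GroundTruth]:
    """Render a methylene-blue-like field of isolated mast cells.

    Each cell deposits granules (small disks of optical density
    ``stain_intensity``) at random positions inside its staining region:
    the soma for resting cells, soma + ``scatter_radius`` halo for
    degranulated ones.  The granule count is chosen so the expected
    stained-pixel count equals ``granule_fraction`` × soma area; dense
    packing makes granules overlap, raising per-pixel density in compact
    cells.  Optical density converts to RGB through per-channel
    Beer–Lambert attenuation (blue-violet stain).

    Cells are auto-placed with ``min_separation_um`` between centres;
    a placement that cannot be satisfied raises ``RuntimeError``.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive μm/pixel, got {scale}")
    # independent sub-streams: raster noise consumes draws proportional to
    # the pixel count, so geometry gets its own streams and the same seed
    # renders the same scene at any scale
    noise_rng = np.random.default_rng([seed, 0])
    H = int(round(field_um[0] / scale))
    W = int(round(field_um[1] / scale))
    img = _background((H, W), noise_rng)

    margin = min_separation_um / 2
    lo = np.array([margin, margin])
    hi = np.array([field_um[0] - margin, field_um[1] - margin])
    if len(cells) > 0 and np.any(hi <= lo):
        raise RuntimeError("field too small for the requested minimum separation")
    # dart-throwing can jam near saturation; retry whole placements on
    # fresh deterministic sub-streams before declaring the field too small
    centers = np.empty((0, 2))
    for attempt in range(8):
        place_rng = np.random.default_rng([seed, 1, attempt])
        centers = _place_points(len(cells), lo, hi, min_separation_um, place_rng, max_tries=200)
        if centers.shape[0] == len(cells):
            break
    if centers.shape[0] < len(cells):
        raise RuntimeError(
            f"could only place {centers.shape[0]} of {len(cells)} cells at "
            f"{min_separation_um} μm minimum separation in a {field_um} μm field"
        )

    od = np.zeros((H, W))
    mc_label = np.zeros((H, W), dtype=np.int32)
    cell_truth: list[dict] = []
    g_r_px = max(1.0, granule_radius_um / scale)
    granule_area_px = np.pi * g_r_px**2

    for k, (spec, (cy, cx)) in enumerate(zip(cells, centers), start=1):
        rng = np.random.default_rng([seed, 2, k])  # per-cell stream
        soma_d = rng.uniform(*spec.soma_diameter_um)
        soma_r = soma_d / 2
        region_r = soma_r + spec.scatter_radius_um
        soma_area_px = np.pi * (soma_r / scale) ** 2
        target_px = spec.granule_fraction * soma_area_px
        # deposit granules until the stained footprint reaches the target
        # pixel count: granule_fraction is then met by construction, and
        # dense packing (resting cells) stacks optical density by overlap
        centre_r = max(region_r - granule_radius_um, region_r * 0.5)
        cell_od = np.zeros((H, W))
        max_gran = int(20 * target_px / granule_area_px) + 20
        n_gran = 0
        stained_ct = 0
        while stained_ct < target_px and n_gran < max_gran:
            ang = rng.uniform(0, 2 * np.pi)
            rad = centre_r * np.sqrt(rng.random())
            gy = (cy + rad * np.sin(ang)) / scale
            gx = (cx + rad * np.cos(ang)) / scale
            rr, cc = skdraw.disk((gy, gx), g_r_px, shape=(H, W))
            cell_od[rr, cc] += spec.stain_intensity
            n_gran += 1
            stained_ct = int(np.count_nonzero(cell_od))
        stained = cell_od > 0
        od += cell_od
        mc_label[stained] = k
        cell_truth.append(
            {
                "center_um": (float(cy), float(cx)),
                "soma_diameter_um": float(soma_d),
                "granule_fraction": spec.granule_fraction,
                "scatter_radius_um": spec.scatter_radius_um,
                "label": spec.truth_label,
                "stained_px": int(stained.sum()),
                "soma_px": float(soma_area_px),
            }
        )

    # Beer–Lambert conversion channel by channel
    atten = 10.0 ** (-od[..., None] * MB_CHANNEL_WEIGHTS[None, None, :])
    img = img * atten
    image = CalibratedImage(pixels=np.clip(img, 0, 255).astype(np.uint8), scale=scale, image_id=image_id)

    truth = GroundTruth(image_id=image_id, scale=scale)
    truth.mast_cells = cell_truth
    truth.mc_label_raster = mc_label
    return image, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Effect multipliers mimicking the study's qualitative outcome: antigen (O)
#: doubles epidermal thickness and infiltration and triples mast-cell
#: activation; resveratrol (R) rescues everything except the dermal
#: thickening.
PAPER_LIKE_EFFECTS = {
    "SV": {"epidermis": 1.0, "dermis": 1.0, "nucleus_density": 1.0, "activated_fraction": 1.0, "perivascular": 1.0},
    "OV": {"epidermis": 2.0, "dermis": 1.3, "nucleus_density": 2.0, "activated_fraction": 3.0, "perivascular": 2.0},
    "SR": {"epidermis": 1.0, "dermis": 1.0, "nucleus_density": 1.0, "activated_fraction": 1.0, "perivascular": 1.0},
    "OR": {"epidermis": 1.0, "dermis": 1.3, "nucleus_density": 1.0, "activated_fraction": 1.0, "perivascular": 1.0},
}

NULL_EFFECTS = {g: {k: 1.0 for k in PAPER_LIKE_EFFECTS["SV"]} for g in GROUPS}

EFFECT_KEYS = tuple(PAPER_LIKE_EFFECTS["SV"].keys())


@dataclass(frozen=True)
class CohortDesign:
    """A 2×2 antigen × resveratrol cohort with injectable effects.

    ``effects`` maps each group to multipliers on the baseline epidermal /
    dermal thickness, nucleus density, mast-cell activated fraction and
    perivascular enrichment.  SV is the reference group and must have all
    multipliers 1.  Mouse-level variability is lognormal with the given
    coefficient of variation.
    """

    n_mice_per_group: int = 6
    images_per_mouse: int = 2
    effects: dict = field(default_factory=lambda: {g: dict(v) for g, v in PAPER_LIKE_EFFECTS.items()})
    base_epidermis_um: float = 30.0
    base_dermis_um: float = 250.0
    base_hypodermis_um: float = 200.0
    base_nucleus_density: float = 300.0
    base_activated_fraction: float = 0.2
    mouse_cv: float = 0.15
    rng_seed: int = 0
    cells_per_mc_image: int = 8
    section_width_um: float = 1600.0
    section_scale: float = 1.0
    mc_scale: float = 0.25

    def __post_init__(self) -> None:
        if set(self.effects) != set(GROUPS):
            raise ValueError(f"effects must cover groups {GROUPS}")
        for g, eff in self.effects.items():
            for k, v in eff.items():
                if v <= 0:
                    raise ValueError(f"effect multiplier {g}/{k} must be > 0, got {v}")
        for k, v in self.effects["SV"].items():
            if v != 1.0:
                raise ValueError(f"SV is the reference group; its {k} multiplier must be 1, got {v}")


def draw_mouse_truth(design: CohortDesign, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample per-mouse true parameters for every mouse in the design.

    Each quantity is baseline × group multiplier × an independent lognormal
    mouse factor with mean 1 and coefficient of variation ``mouse_cv``.
    Activated fractions are clipped to [0.02, 0.95].  This is the shared
    source of cohort variability for both image generation and fast
    truth-level statistical simulation.
    """
    if rng is None:
        rng = np.random.default_rng(design.rng_seed)
    sigma = np.sqrt(np.log(1 + design.mouse_cv**2))
    mu = -(sigma**2) / 2  # lognormal mean exactly 1

    rows = []
    for g in GROUPS:
        eff = design.effects[g]
        for m in range(design.n_mice_per_group):
            f = {k: rng.lognormal(mu, sigma) for k in EFFECT_KEYS}
            rows.append(
                {
                    "mouse_id": f"{g}_m{m}",
                    "group": g,
                    "antigen": g[0],
                    "resveratrol": g[1],
                    "epidermis_um": design.base_epidermis_um * eff["epidermis"] * f["epidermis"],
                    "dermis_um": design.base_dermis_um * eff["dermis"] * f["dermis"],
                    "nucleus_density": design.base_nucleus_density * eff["nucleus_density"] * f["nucleus_density"],
                    "activated_fraction": float(
                        np.clip(
                            design.base_activated_fraction * eff["activated_fraction"] * f["activated_fraction"],
                            0.02,
                            0.95,
                        )
                    ),
                    "perivascular_factor": eff["perivascular"],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class Cohort:
    """Generated cohort: images, per-image truth, manifest and mouse truth."""

    design: CohortDesign
    mouse_truth: pd.DataFrame
    images: dict[str, CalibratedImage]
    truths: dict[str, GroundTruth]
    manifest: pd.DataFrame

    def save(self, outdir: str | Path) -> None:
        """Write TIFFs, the manifest CSV and a JSON design sidecar."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for iid, im in self.images.items():
            im.save(out / f"{iid}.tif")
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.mouse_truth.to_csv(out / "mouse_truth.csv", index=False)
        lt_rows = []
        for iid, tr in self.truths.items():
            for layer, prof in tr.layer_thickness_profile.items():
                lt_rows.append(
                    {
                        "image_id": iid,
                        "layer": layer,
                        "top_mean_um": float(np.mean(tr.layer_tops_um[layer])),
                        "thickness_mean_um": float(np.mean(prof)),
                    }
                )
        if lt_rows:
            pd.DataFrame(lt_rows).to_csv(out / "layer_truth.csv", index=False)
        design_dict = {
            k: (v if not isinstance(v, dict) else v)
            for k, v in self.design.__dict__.items()
        }
        (out / "design.json").write_text(json.dumps(design_dict, indent=2, sort_keys=True))


def simulate_cohort(design: CohortDesign, warn: list | None = None) -> Cohort:
    """Generate every image of a 2×2 cohort, with manifest and truth.

    Per mouse: ``images_per_mouse`` skin sections (H&E-like) and the same
    number of mast-cell fields (MB-like).  Per-image sub-seeds derive
    deterministically from (rng_seed, mouse index, image index), so the
    whole cohort is reproducible from the design alone.
    """
    if design.n_mice_per_group < 2:
        msg = "n_mice_per_group < 2: downstream group statistics will be degenerate"
        if warn is not None:
            warn.append(msg)
        else:
            import warnings

            warnings.warn(msg, stacklevel=2)

    truth_rng = np.random.default_rng(design.rng_seed)
    mouse_truth = draw_mouse_truth(design, truth_rng)

    images: dict[str, CalibratedImage] = {}
    truths: dict[str, GroundTruth] = {}
    rows = []
    for mi, mouse in mouse_truth.iterrows():
        for k in range(design.images_per_mouse):
            sub = int(np.random.default_rng([design.rng_seed, int(mi), k]).integers(0, 2**31 - 1))
            layers = default_layers(
                epidermis=float(mouse.epidermis_um),
                dermis=float(mouse.dermis_um),
                hypodermis=design.base_hypodermis_um,
            )
            iid = f"{mouse.mouse_id}_he{k}"
            im, tr = generate_skin_section(
                layers,
                nuclei=NucleusField(density=float(mouse.nucleus_density)),
                vessels=VesselField(),
                scale=design.section_scale,
                seed=sub,
                width_um=design.section_width_um,
                perivascular_factor=float(mouse.perivascular_factor),
                image_id=iid,
            )
            images[iid] = im
            truths[iid] = tr
            rows.append({"image_id": iid, "mouse_id": mouse.mouse_id, "group": mouse.group, "kind": "he"})

            cell_rng = np.random.default_rng([design.rng_seed, int(mi), k, 1])
            n_act = int(cell_rng.binomial(design.cells_per_mc_image, mouse.activated_fraction))
            cells = [resting_cell() for _ in range(design.cells_per_mc_image - n_act)] + [
                activated_cell() for _ in range(n_act)
            ]
            iid2 = f"{mouse.mouse_id}_mb{k}"
            im2, tr2 = generate_mc_field(cells, scale=design.mc_scale, seed=sub + 1, image_id=iid2)
            images[iid2] = im2
            truths[iid2] = tr2
            rows.append({"image_id": iid2, "mouse_id": mouse.mouse_id, "group": mouse.group, "kind": "mb"})

    manifest = pd.DataFrame(rows)
    return Cohort(design=design, mouse_truth=mouse_truth, images=images, truths=truths, manifest=manifest)
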