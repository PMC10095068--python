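import numpy as np
import pytest

import histomorph as hm
from histomorph.infiltration import (
    NucleusFilter,
    count_in_rois,
    detect_nuclei,
    perivascular_rois,
    tile_band_rois,
)
from histomorph.synthetic_histology import NUCLEUS_RGB, LayerSpec


def _full_field_layers():
    return [
        LayerSpec("epidermis", 100.0),
        LayerSpec("dermis", 500.0),
        LayerSpec("hypodermis", 400.0),
    ]


class TestDetectNuclei:
    def test_forty_nuclei_detected_exactly_with_accurate_centroids(self, thresholds):
        img, tr = hm.generate_skin_section(
            _full_field_layers(),
            nuclei=hm.NucleusField(density=80.0),  # ≈ 40 over 0.5 mm²
            seed=13,
            width_um=500,
        )
        det = detect_nuclei(img, thresholds["nuclei"])
        assert len(det) == tr.nucleus_count
        truth = tr.nucleus_coords_um
        for n in det:
            d = np.hypot(truth[:, 0] - n.centroid_um[0], truth[:, 1] - n.centroid_um[1])
            assert d.min() <= 2.0

    def test_blank_image_gives_zero(self, thresholds):
        img = hm.CalibratedImage(np.full((50, 50, 3), 245, dtype=np.uint8), scale=1.0)
        assert detect_nuclei(img, thresholds["nuclei"]) == []

    def test_oversized_blob_is_filtered_out(self, thresholds):
        img = np.full((120, 120, 3), 245, dtype=np.uint8)
        img[20:90, 20:90] = NUCLEUS_RGB  # ~4900 μm², far above the window
        cal = hm.CalibratedImage(img, scale=1.0)
        assert detect_nuclei(cal, thresholds["nuclei"]) == []

    @pytest.mark.parametrize("density", [50.0, 500.0, 2000.0])
    def test_recovery_across_densities_within_2_percent(self, thresholds, density):
        img, tr = hm.generate_skin_section(
            _full_field_layers(), nuclei=hm.NucleusField(density=density), seed=int(density),
            width_um=1000,
        )
        det = detect_nuclei(img, thresholds["nuclei"])
        assert abs(len(det) - tr.nucleus_count) <= max(1, 0.02 * tr.nucleus_count)

    def test_widening_area_window_never_loses_detections(self, nucleus_section, thresholds):
        img, _ = nucleus_section
        narrow = detect_nuclei(img, thresholds["nuclei"], NucleusFilter(area_um2=(20.0, 60.0)))
        wide = detect_nuclei(img, thresholds["nuclei"], NucleusFilter(area_um2=(10.0, 80.0)))
        assert len(wide) >= len(narrow)


class TestCountInRois:
    def _nuclei_at(self, pts):
        return [
            hm.Nucleus(centroid_um=(y, x), area_um2=30.0, elongation=1.2, solidity=0.95)
            for y, x in pts
        ]

    def test_five_in_one_roi_none_elsewhere(self):
        nuclei = self._nuclei_at([(100, 100), (110, 105), (95, 98), (102, 110), (90, 90)])
        rep = count_in_rois(nuclei, [(100, 100), (400, 400)], diameter_um=75.0)
        assert rep.counts == (5, 0)
        assert rep.mean_count == 2.5

    def test_boundary_centroid_counts_as_inside(self):
        nuclei = self._nuclei_at([(100.0, 137.5)])  # exactly on the circle
        rep = count_in_rois(nuclei, [(100.0, 100.0)], diameter_um=75.0)
        assert rep.counts == (1,)

    def test_counts_add_over_disjoint_rois(self, nucleus_section, thresholds):
        img, _ = nucleus_section
        nuclei = detect_nuclei(img, thresholds["nuclei"])
        rois = [(200.0, 200.0), (200.0, 400.0), (500.0, 300.0)]
        rep = count_in_rois(nuclei, rois)
        # disjoint circles: sum of per-ROI counts equals count over the union
        r = rep.diameter_um / 2
        pts = np.array([n.centroid_um for n in nuclei])
        in_union = np.zeros(len(pts), dtype=bool)
        for cy, cx in rois:
            in_union |= np.hypot(pts[:, 0] - cy, pts[:, 1] - cx) <= r
        assert sum(rep.counts) == int(in_union.sum())

    def test_mean_count_matches_density_times_roi_area(self, thresholds):
        density = 800.0
        img, tr = hm.generate_skin_section(
            _full_field_layers(), nuclei=hm.NucleusField(density=density), seed=21, width_um=1000,
        )
        nuclei = detect_nuclei(img, thresholds["nuclei"])
        band_top = tr.layer_tops_um["dermis"]
        band_bot = band_top + tr.layer_thickness_profile["dermis"]
        rois = tile_band_rois(band_top, band_bot, img.width_um)
        rep = count_in_rois(nuclei, rois)
        expected = density * np.pi * 37.5**2 / 1e6  # ≈ 3.53 per ROI
        # sampling error of the mean over n ROIs
        tol = 4 * np.sqrt(expected / len(rois))
        assert rep.mean_count == pytest.approx(expected, abs=tol)

    def test_zero_rois_rejected(self):
        with pytest.raises(ValueError):
            count_in_rois([], [], diameter_um=75.0)

    def test_doubling_density_doubles_mean_count(self, thresholds):
        means = []
        for density, seed in ((400.0, 31), (800.0, 32)):
            img, tr = hm.generate_skin_section(
                _full_field_layers(), nuclei=hm.NucleusField(density=density), seed=seed,
                width_um=1000,
            )
            nuclei = detect_nuclei(img, thresholds["nuclei"])
            band_top = tr.layer_tops_um["hypodermis"]
            band_bot = band_top + tr.layer_thickness_profile["hypodermis"]
            rep = count_in_rois(nuclei, tile_band_rois(band_top, band_bot, img.width_um))
            means.append(rep.mean_count)
        assert means[1] / means[0] == pytest.approx(2.0, abs=0.35)


class TestPerivascularRois:
    def test_one_roi_per_annotated_vessel(self):
        img = hm.CalibratedImage(np.full((400, 400, 3), 245, dtype=np.uint8), scale=1.0)
        centers = [(100.0, 100.0), (200.0, 250.0), (300.0, 300.0)]
        rois = perivascular_rois(img, centers, diameter_um=75.0)
        assert rois == centers

    def test_edge_vessel_dropped_and_logged(self):
        img = hm.CalibratedImage(np.full((400, 400, 3), 245, dtype=np.uint8), scale=1.0)
        dropped: list = []
        rois = perivascular_rois(img, [(10.0, 200.0), (200.0, 200.0)], diameter_um=75.0, dropped=dropped)
        assert rois == [(200.0, 200.0)]
        assert dropped == [(10.0, 200.0)]

    def test_perivascular_enrichment_is_visible(self, thresholds):
        # generator places extra nuclei within 75 μm of vessels when
        # perivascular_factor > 1: perivascular ROI means exceed band means
        img, tr = hm.generate_skin_section(
            hm.default_layers(50.0, 250.0, 300.0),
            nuclei=hm.NucleusField(density=300.0),
            vessels=hm.VesselField(count=4),
            seed=17,
            width_um=1500,
            perivascular_factor=4.0,
        )
        nuclei = detect_nuclei(img, thresholds["nuclei"])
        vrois = perivascular_rois(img, tr.vessels_um[:, :2])
        assert len(vrois) >= 2
        peri = count_in_rois(nuclei, vrois, context="perivascular")
        band_top = tr.layer_tops_um["hypodermis"]
        band_bot = band_top + tr.layer_thickness_profile["hypodermis"]
        whole = count_in_rois(nuclei, tile_band_rois(band_top, band_bot, img.width_um))
        assert peri.mean_count > whole.mean_count
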