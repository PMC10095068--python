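import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

import histomorph as hm
from histomorph.color_ops import threshold_hsi
from histomorph.synthetic_histology import (
    GROUPS,
    NULL_EFFECTS,
    CohortDesign,
    LayerSpec,
    draw_mouse_truth,
    simulate_cohort,
)


class TestSkinSection:
    def test_zero_density_gives_stated_thickness_and_no_nuclei(self):
        layers = hm.default_layers(50.0, 300.0, 200.0)
        img, tr = hm.generate_skin_section(
            layers, nuclei=hm.NucleusField(density=0), seed=7, width_um=1600
        )
        assert tr.nucleus_count == 0
        assert tr.mean_layer_thickness("epidermis") == pytest.approx(50.0, rel=0.05)
        assert tr.mean_layer_thickness("dermis") == pytest.approx(300.0, rel=0.05)

    def test_same_seed_bit_identical(self):
        layers = hm.default_layers()
        a, _ = hm.generate_skin_section(layers, seed=5, width_um=600)
        b, _ = hm.generate_skin_section(layers, seed=5, width_um=600)
        assert np.array_equal(a.pixels, b.pixels)

    def test_different_seed_differs(self):
        layers = hm.default_layers()
        a, _ = hm.generate_skin_section(layers, seed=5, width_um=600)
        b, _ = hm.generate_skin_section(layers, seed=6, width_um=600)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_nucleus_count_within_poisson_of_expectation(self):
        # layers fill the 2 mm × 1 mm field, so expected = density × field
        # area = 500 × 2 = 1000, and the draw is Poisson(1000)
        layers = [
            LayerSpec("epidermis", 100.0),
            LayerSpec("dermis", 500.0),
            LayerSpec("hypodermis", 400.0),
        ]
        img, tr = hm.generate_skin_section(
            layers, nuclei=hm.NucleusField(density=500.0), seed=1, width_um=2000, margin_um=30
        )
        expected = 500.0 * (tr.layer_thickness_profile["epidermis"]
                            + tr.layer_thickness_profile["dermis"]
                            + tr.layer_thickness_profile["hypodermis"]).sum() * img.scale / 1e6
        assert expected == pytest.approx(1000, rel=0.1)
        assert abs(tr.nucleus_count - expected) < 4 * np.sqrt(expected)

    def test_truth_raster_matches_threshold_mask(self, nucleus_section, thresholds):
        # every rendered nucleus appears in truth and vice versa: the truth
        # label raster and the HSI stain mask agree pixel-for-pixel ≥ 99%
        img, tr = nucleus_section
        mask = threshold_hsi(img, thresholds["nuclei"]).mask
        truth_mask = tr.nucleus_label_raster > 0
        agree = (mask == truth_mask).mean()
        assert agree >= 0.99
        inter = (mask & truth_mask).sum()
        union = (mask | truth_mask).sum()
        assert inter / union >= 0.95

    def test_calibration_round_trip(self):
        # a structure specified w μm wide occupies w/scale px within ±1 px
        layers = hm.default_layers(60.0, 200.0, 150.0)
        for scale in (0.5, 1.0, 2.0):
            img, tr = hm.generate_skin_section(
                layers, nuclei=hm.NucleusField(density=0), seed=2, scale=scale, width_um=800
            )
            mask = threshold_hsi(img, hm.palette_thresholds()["epidermis"]).mask
            col = mask[:, mask.shape[1] // 2]
            w_px = int(col.sum())
            true_um = tr.layer_thickness_profile["epidermis"][mask.shape[1] // 2]
            assert abs(w_px - true_um / scale) <= 1.5

    def test_impossible_geometry_rejected(self):
        layers = hm.default_layers(50.0, 300.0, 200.0)
        with pytest.raises(ValueError):
            hm.generate_skin_section(layers, scale=-1.0)
        with pytest.raises(ValueError):
            LayerSpec("epidermis", mean_thickness=-5.0)
        with pytest.raises(ValueError):
            LayerSpec("epidermis", 20.0, waviness_amplitude=15.0)  # ≥ thickness/2


class TestMastCellField:
    def test_zero_cells_blank_truth(self):
        img, tr = hm.generate_mc_field([], seed=1, field_um=(60.0, 60.0))
        assert tr.mast_cells == []
        assert not (tr.mc_label_raster > 0).any()

    def test_determinism_of_cells_and_truth(self):
        cells = [hm.resting_cell() for _ in range(10)] + [hm.activated_cell() for _ in range(10)]
        a_img, a_tr = hm.generate_mc_field(cells, seed=3, field_um=(520.0, 520.0))
        b_img, b_tr = hm.generate_mc_field(cells, seed=3, field_um=(520.0, 520.0))
        assert np.array_equal(a_img.pixels, b_img.pixels)
        assert [c["center_um"] for c in a_tr.mast_cells] == [c["center_um"] for c in b_tr.mast_cells]
        assert [c["label"] for c in a_tr.mast_cells] == [c["label"] for c in b_tr.mast_cells]

    def test_stained_fraction_ratio_tracks_granule_fractions(self, mc_training_field):
        # resting 0.9 vs activated 0.3 at equal soma size → stained-pixel
        # fraction ratio ≈ 3, measured on the generator's own truth masks
        _, tr = mc_training_field
        sf = {"resting": [], "activated": []}
        for c in tr.mast_cells:
            sf[c["label"]].append(c["stained_px"] / c["soma_px"])
        ratio = np.mean(sf["resting"]) / np.mean(sf["activated"])
        assert ratio == pytest.approx(3.0, rel=0.15)

    def test_truth_raster_covers_every_cell_once(self, mc_training_field):
        _, tr = mc_training_field
        labels = np.unique(tr.mc_label_raster)
        labels = labels[labels > 0]
        assert len(labels) == len(tr.mast_cells)
        for k, c in enumerate(tr.mast_cells, start=1):
            assert (tr.mc_label_raster == k).sum() == c["stained_px"]

    def test_unplaceable_request_fails_with_named_constraint(self):
        cells = [hm.resting_cell() for _ in range(40)]
        with pytest.raises(RuntimeError, match="separation"):
            hm.generate_mc_field(cells, seed=0, field_um=(80.0, 80.0))


class TestCohort:
    def test_null_design_groups_exchangeable(self):
        # all multipliers 1 → permuting group labels leaves truth means
        # indistinguishable: one-way ANOVA p on truth epidermis is non-tiny
        design = CohortDesign(
            n_mice_per_group=6, effects={g: dict(v) for g, v in NULL_EFFECTS.items()}, rng_seed=0
        )
        pvals = []
        for rep in range(20):
            mt = draw_mouse_truth(
                CohortDesign(n_mice_per_group=6,
                             effects={g: dict(v) for g, v in NULL_EFFECTS.items()},
                             rng_seed=rep)
            )
            groups = [mt.loc[mt.group == g, "epidermis_um"].to_numpy() for g in GROUPS]
            pvals.append(spstats.f_oneway(*groups).pvalue)
        # under the null, p-values are ~uniform: KS not rejected at 1%
        assert spstats.kstest(pvals, "uniform").pvalue > 0.01

    def test_effect_multiplier_scales_truth(self):
        effects = {g: dict(v) for g, v in NULL_EFFECTS.items()}
        effects["OV"]["epidermis"] = 2.0
        design = CohortDesign(n_mice_per_group=40, effects=effects, rng_seed=1)
        mt = draw_mouse_truth(design)
        ov = mt.loc[mt.group == "OV", "epidermis_um"].mean()
        sv = mt.loc[mt.group == "SV", "epidermis_um"].mean()
        assert ov / sv == pytest.approx(2.0, rel=0.1)

    def test_manifest_and_images_deterministic(self):
        design = CohortDesign(n_mice_per_group=2, images_per_mouse=1, rng_seed=4,
                              section_width_um=800)
        a = simulate_cohort(design)
        b = simulate_cohort(design)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for iid in a.images:
            assert np.array_equal(a.images[iid].pixels, b.images[iid].pixels)

    def test_reference_group_must_be_unit(self):
        effects = {g: dict(v) for g, v in NULL_EFFECTS.items()}
        effects["SV"]["epidermis"] = 1.5
        with pytest.raises(ValueError, match="reference"):
            CohortDesign(effects=effects)

    def test_single_mouse_design_warns(self):
        design = CohortDesign(n_mice_per_group=1, images_per_mouse=1, section_width_um=800)
        warnings_log: list = []
        simulate_cohort(design, warn=warnings_log)
        assert warnings_log and "degenerate" in warnings_log[0]
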