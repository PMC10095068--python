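"""Group statistics, 2×2 ANOVA with Bonferroni pairs, ΔΔCt, and the
end-to-end pipeline.

The experimental design is a 2×2 factorial: antigen (saline S vs
ovalbumin O) × resveratrol (vehicle V vs resveratrol R), giving groups
SV, OV, SR, OR.  The mouse is the experimental unit: per-ROI and
per-image measurements are averaged within mouse before any group
statistic, avoiding pseudoreplication.  The ANOVA uses type-II sums of
squares; the pairwise family is the four biologically meaningful
contrasts {SV–OV, OV–OR, SV–SR, SV–OR}, Bonferroni-adjusted (adjusted
p = min(1, 4·raw p)), tested on the pooled residual variance of the full
factorial model.

Relative mRNA expression follows the 2^−ΔΔCt method with two reference
genes: ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2); ΔΔCt subtracts the
control-group (SV) mean ΔCt, so the control group's geometric-mean fold
change is exactly 1.  Amplification efficiency is fixed at 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .synthetic_histology import GROUPS

PAIR_FAMILY = (("SV", "OV"), ("OV", "OR"), ("SV", "SR"), ("SV", "OR"))


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sem: float | None
    measurement: str
    units: str = ""


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    t: float
    p_raw: float
    p_adjusted: float  # Bonferroni: min(1, k · p_raw)
    significant: bool  # p_adjusted < alpha


@dataclass(frozen=True)
class AnovaResult:
    """Factor F/p values plus Bonferroni-adjusted pairwise comparisons."""

    measurement: str
    f_antigen: float
    p_antigen: float
    f_resveratrol: float
    p_resveratrol: float
    f_interaction: float
    p_interaction: float
    pairwise: tuple[PairwiseComparison, ...]
    alpha: float = 0.05


def summarize_groups(per_mouse: pd.DataFrame, measurement: str, units: str = "") -> list[GroupSummary]:
    """Mean ± SEM of one per-mouse measurement, by group.

    ``per_mouse`` needs columns ``group`` and ``value`` (one row per
    mouse).  SEM is sd/√n and absent for single-mouse groups.  Rows with
    a group outside the 2×2 design are rejected by name.
    """
    bad = set(per_mouse["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"measurements mapped to unknown groups: {sorted(bad)}")
    out = []
    for g in GROUPS:
        vals = per_mouse.loc[per_mouse["group"] == g, "value"].to_numpy(dtype=float)
        if vals.size == 0:
            continue
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else None
        out.append(GroupSummary(group=g, n=int(vals.size), mean=float(vals.mean()), sem=sem, measurement=measurement, units=units))
    return out


def two_way_anova(per_mouse: pd.DataFrame, measurement: str = "", alpha: float = 0.05) -> AnovaResult:
    """Two-way ANOVA (antigen × resveratrol) with Bonferroni pairs.

    ``per_mouse`` needs columns ``group`` and ``value``; antigen and
    resveratrol factors are decoded from the group label's two letters.
    Type-II sums of squares handle unbalanced cells.  Each pair of the
    4-contrast family is tested with a t statistic on the pooled residual
    mean square of the full model; Bonferroni multiplies raw p by 4.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = per_mouse.copy()
    bad = set(df["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups: {sorted(bad)}")
    counts = df["group"].value_counts()
    missing = [g for g in GROUPS if counts.get(g, 0) == 0]
    if missing:
        raise ValueError(f"empty design cells: {missing}")
    df["antigen"] = df["group"].str[0]
    df["resveratrol"] = df["group"].str[1]

    model = smf.ols("value ~ C(antigen) * C(resveratrol)", data=df).fit()
    if model.ssr < 1e-12 * max(1.0, float(np.abs(df["value"]).max()) ** 2):
        # degenerate: zero residual variance (e.g. identical values per cell
        # pattern with no noise) — report F = 0, p = 1 when effects are zero
        tbl = None
    else:
        tbl = sm.stats.anova_lm(model, typ=2)

    def _fp(name: str) -> tuple[float, float]:
        if tbl is None:
            # all-identical data: no effects, no error
            return 0.0, 1.0
        row = tbl.loc[name]
        f = float(row["F"]) if np.isfinite(row["F"]) else 0.0
        p = float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else 1.0
        return f, p

    f_a, p_a = _fp("C(antigen)")
    f_r, p_r = _fp("C(resveratrol)")
    f_i, p_i = _fp("C(antigen):C(resveratrol)")

    mse = model.ssr / model.df_resid if model.df_resid > 0 else 0.0
    k = len(PAIR_FAMILY)
    pairs = []
    for g1, g2 in PAIR_FAMILY:
        v1 = df.loc[df["group"] == g1, "value"].to_numpy(dtype=float)
        v2 = df.loc[df["group"] == g2, "value"].to_numpy(dtype=float)
        diff = v1.mean() - v2.mean()
        se = np.sqrt(mse * (1 / v1.size + 1 / v2.size))
        if se == 0:
            t, p = 0.0, 1.0
        else:
            t = diff / se
            p = float(2 * spstats.t.sf(abs(t), model.df_resid))
        p_adj = min(1.0, k * p)
        pairs.append(PairwiseComparison(pair=(g1, g2), t=float(t), p_raw=float(p), p_adjusted=p_adj, significant=p_adj < alpha))

    return AnovaResult(
        measurement=measurement,
        f_antigen=f_a,
        p_antigen=p_a,
        f_resveratrol=f_r,
        p_resveratrol=p_r,
        f_interaction=f_i,
        p_interaction=p_i,
        pairwise=tuple(pairs),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Relative expression (2^−ΔΔCt with two reference genes)
# ---------------------------------------------------------------------------


def relative_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: tuple[str, str] = ("B2M", "ACTB"),
    control_group: str = "SV",
) -> pd.DataFrame:
    """Per-sample fold change of a target gene by the 2^−ΔΔCt method.

    ``ct_table`` columns: sample, group, gene, replicate, Ct.  Duplicate
    determinations are averaged; a sample with a single determination for
    some gene is used as-is and flagged in the output's ``flagged``
    column.  Samples missing either reference gene are rejected.

    Returns a frame with sample, group, delta_ct, ddct and fold_change.
    The control group's geometric-mean fold change is exactly 1.
    """
    need = {"sample", "group", "gene", "Ct"}
    if not need.issubset(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(need)}")
    mean_ct = ct_table.groupby(["sample", "group", "gene"], as_index=False).agg(
        Ct=("Ct", "mean"), n_rep=("Ct", "size")
    )
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="Ct")
    reps = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="n_rep")
    for gene in (target_gene, *reference_genes):
        if gene not in wide.columns or wide[gene].isna().any():
            missing = wide.index[wide[gene].isna()].tolist() if gene in wide.columns else "all samples"
            raise ValueError(f"gene {gene!r} missing for {missing}")
    ref_ct = wide[list(reference_genes)].mean(axis=1)
    delta_ct = wide[target_gene] - ref_ct
    ctrl = delta_ct[wide.index.get_level_values("group") == control_group]
    if ctrl.empty:
        raise ValueError(f"control group {control_group!r} absent from ct_table")
    ddct = delta_ct - ctrl.mean()
    out = delta_ct.reset_index().rename(columns={0: "delta_ct"})
    out.columns = ["sample", "group", "delta_ct"]
    out["ddct"] = ddct.to_numpy()
    out["fold_change"] = 2.0 ** (-out["ddct"])
    out["target_gene"] = target_gene
    out["flagged"] = (reps[[target_gene, *reference_genes]] < 2).any(axis=1).to_numpy()
    return out


def simulate_ct_table(
    fold_by_group: dict[str, float],
    n_per_group: int = 6,
    ct_noise_sd: float = 0.2,
    sample_effect_sd: float = 0.5,
    base_ct: float = 25.0,
    ref_cts: tuple[float, float] = (20.0, 22.0),
    target_gene: str = "CCL2",
    reference_genes: tuple[str, str] = ("B2M", "ACTB"),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic duplicate-well Ct table with injected group fold changes.

    Each sample carries a shared loading offset (affecting every gene
    alike, which ΔCt cancels); a true fold change f in a group lowers the
    target Ct by log2 f; every well adds independent Gaussian noise of
    ``ct_noise_sd`` cycles.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in GROUPS:
        fold = fold_by_group.get(g, 1.0)
        for i in range(n_per_group):
            sample = f"{g}_s{i}"
            loading = rng.normal(0.0, sample_effect_sd)
            truth = {
                target_gene: base_ct + loading - np.log2(fold),
                reference_genes[0]: ref_cts[0] + loading,
                reference_genes[1]: ref_cts[1] + loading,
            }
            for gene, ct in truth.items():
                for rep in (1, 2):
                    rows.append(
                        {"sample": sample, "group": g, "gene": gene, "replicate": rep,
                         "Ct": ct + rng.normal(0.0, ct_noise_sd)}
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full synthetic-cohort analysis run."""

    seed: int = 0
    n_mice_per_group: int = 4
    images_per_mouse: int = 2
    effects: dict | None = None  # None → paper-mimicking defaults
    mouse_cv: float = 0.15
    section_width_um: float = 1600.0
    rois_per_layer: int = 3
    alpha: float = 0.05
    n_calibration_cells: int = 12  # per class, for the IOD/A threshold


def _quantify_cohort(cohort, cfg: PipelineConfig) -> pd.DataFrame:
    """Measure every image of a cohort; return per-mouse measurement table."""
    from .infiltration import count_in_rois, detect_nuclei, tile_band_rois
    from .layer_morphometry import survey_layer
    from .mast_cells import calibrate_threshold, classify_activation, measure_image
    from .synthetic_histology import activated_cell, generate_mc_field, palette_thresholds, resting_cell

    thr = palette_thresholds()

    # Calibrate the IOD/A threshold once, on a dedicated labelled field
    # generated with the same rendering parameters as the cohort.
    calib_cells = [resting_cell() for _ in range(cfg.n_calibration_cells)] + [
        activated_cell() for _ in range(cfg.n_calibration_cells)
    ]
    calib_img, calib_truth = generate_mc_field(
        calib_cells, seed=cfg.seed + 10_000, field_um=(420.0, 420.0), image_id="calibration"
    )
    calib_m = measure_image(calib_img, thr["mast_cell"])
    truth_by_pos = calib_truth.mast_cells
    labels = []
    for m in calib_m:
        d = [np.hypot(m.centroid_um[0] - t["center_um"][0], m.centroid_um[1] - t["center_um"][1]) for t in truth_by_pos]
        labels.append(truth_by_pos[int(np.argmin(d))]["label"])
    ratio_threshold = calibrate_threshold(np.array([m.ratio for m in calib_m]), labels)

    rows = []
    for ridx, (_, rec) in enumerate(cohort.manifest.iterrows()):
        img = cohort.images[rec.image_id]
        tru = cohort.truths[rec.image_id]
        if rec.kind == "he":
            meas = {}
            for li, layer in enumerate(("epidermis", "dermis")):
                sv = survey_layer(
                    img, layer, tru, thr[layer], n_rois=cfg.rois_per_layer,
                    seed=(cfg.seed * 1_000_003 + ridx * 7 + li) % 2**31,
                )
                meas[f"{layer}_um"] = sv.mean
            nuclei = detect_nuclei(img, thr["nuclei"])
            band_top = tru.layer_tops_um["hypodermis"]
            band_bot = band_top + tru.layer_thickness_profile["hypodermis"]
            rois = tile_band_rois(band_top, band_bot, img.width_um)
            if rois:
                rep = count_in_rois(nuclei, rois)
                meas["infiltration_per_roi"] = rep.mean_count
            for name, value in meas.items():
                rows.append({"image_id": rec.image_id, "mouse_id": rec.mouse_id, "group": rec.group,
                             "measurement": name, "value": value})
        else:  # mb
            cells = measure_image(img, thr["mast_cell"])
            labeled, _ = classify_activation(cells, ratio_threshold)
            if labeled:
                frac = sum(1 for c in labeled if c.label == "activated") / len(labeled)
                rows.append({"image_id": rec.image_id, "mouse_id": rec.mouse_id, "group": rec.group,
                             "measurement": "mc_activated_fraction", "value": frac})
    return pd.DataFrame(rows)


MEASUREMENT_UNITS = {
    "epidermis_um": "μm",
    "dermis_um": "μm",
    "infiltration_per_roi": "nuclei/ROI",
    "mc_activated_fraction": "fraction",
}


def run_full_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Generate a synthetic cohort, quantify it, and run the statistics.

    Executes generate → quantify (layer thickness, infiltration, mast-cell
    activation) → per-mouse averaging → group summaries → two-way ANOVA
    with Bonferroni pairs.  Returns (and optionally writes) a report dict
    fully determined by the configuration and seed.
    """
    from .synthetic_histology import CohortDesign, simulate_cohort

    design = CohortDesign(
        n_mice_per_group=cfg.n_mice_per_group,
        images_per_mouse=cfg.images_per_mouse,
        **({"effects": cfg.effects} if cfg.effects is not None else {}),
        mouse_cv=cfg.mouse_cv,
        rng_seed=cfg.seed,
        section_width_um=cfg.section_width_um,
    )
    cohort = simulate_cohort(design)
    per_image = _quantify_cohort(cohort, cfg)

    per_mouse = (
        per_image.groupby(["measurement", "mouse_id", "group"], as_index=False)["value"].mean()
    )

    report: dict = {"config": {k: v for k, v in cfg.__dict__.items()}, "measurements": {}}
    for name, sub in per_mouse.groupby("measurement"):
        summaries = summarize_groups(sub, name, MEASUREMENT_UNITS.get(name, ""))
        anova = two_way_anova(sub, measurement=name, alpha=cfg.alpha)
        report["measurements"][name] = {
            "groups": [s.__dict__ for s in summaries],
            "anova": {
                "f_antigen": anova.f_antigen, "p_antigen": anova.p_antigen,
                "f_resveratrol": anova.f_resveratrol, "p_resveratrol": anova.p_resveratrol,
                "f_interaction": anova.f_interaction, "p_interaction": anova.p_interaction,
            },
            "pairwise": [
                {"pair": list(pc.pair), "t": pc.t, "p_raw": pc.p_raw,
                 "p_adjusted": pc.p_adjusted, "significant": pc.significant}
                for pc in anova.pairwise
            ],
        }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        per_mouse.to_csv(out / "per_mouse.csv", index=False)
        tbl_rows = []
        for name, block in sorted(report["measurements"].items()):
            for s in block["groups"]:
                sig = {tuple(p["pair"]): p["significant"] for p in block["pairwise"]}
                tbl_rows.append({"measurement": name, **s,
                                 "sig_SV_OV": sig[("SV", "OV")], "sig_OV_OR": sig[("OV", "OR")],
                                 "sig_SV_SR": sig[("SV", "SR")], "sig_SV_OR": sig[("SV", "OR")]})
        pd.DataFrame(tbl_rows).to_csv(out / "group_table.csv", index=False)
    return report
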