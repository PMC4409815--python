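"""Synthetic feature-table and cohort generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from funcvar import gating
from funcvar.synthdata import (CellNoiseModel, CohortConfig, ExperimentDesign,
                               SampleRole, SampleSpec, Setting, VariantEffect,
                               VariantSpec, design_with_variants,
                               disruptive_effect, generate_cell_features,
                               generate_cohort)

QUIET = CellNoiseModel(replicate_sigma=1e-9, batch_sigma=1e-9)


def test_design_requires_setting_controls():
    with pytest.raises(ValueError):
        ExperimentDesign(setting=Setting.OVEREXPRESSION,
                         samples=[SampleSpec(SampleRole.WILDTYPE)])
    with pytest.raises(ValueError):
        # complementation requires the siRNA controls as well
        design_with_variants(Setting.OVEREXPRESSION, ["v1"]).samples \
            and ExperimentDesign(
                setting=Setting.COMPLEMENTATION,
                samples=[SampleSpec(SampleRole.TRANSFECTION_CONTROL),
                         SampleSpec(SampleRole.GFP_CONTROL),
                         SampleSpec(SampleRole.WILDTYPE)])
    with pytest.raises(ValueError):
        design_with_variants(Setting.OVEREXPRESSION, ["v1"],
                             cells_per_image=0)


def test_variant_effect_validation():
    with pytest.raises(ValueError):
        VariantEffect(variant_id="x", ldl_multiplier=0.0)
    eff = disruptive_effect("x", 0.16)
    assert eff.seg_number_multiplier == pytest.approx(0.4)
    assert eff.concentration_multiplier == pytest.approx(0.4)


def test_missing_effect_raises():
    design = design_with_variants(Setting.OVEREXPRESSION, ["v1"],
                                  images_per_replicate=1, cells_per_image=5)
    with pytest.raises(KeyError):
        generate_cell_features(design, {}, seed=0)


def test_same_seed_identical_different_seed_distinct():
    design = design_with_variants(Setting.OVEREXPRESSION, ["v1"],
                                  replicates_per_sample=2,
                                  images_per_replicate=3, cells_per_image=20)
    effects = {"v1": disruptive_effect("v1", 0.2)}
    t1 = generate_cell_features(design, effects, seed=42)
    t2 = generate_cell_features(design, effects, seed=42)
    t3 = generate_cell_features(design, effects, seed=43)
    pd.testing.assert_frame_equal(t1, t2)
    assert not t1["gfp"].equals(t3["gfp"])


def test_identity_effect_matches_wildtype_distribution():
    """A variant with all multipliers 1 is indistinguishable from
    wildtype in the GFP-expressing subpopulation."""
    design = design_with_variants(Setting.OVEREXPRESSION, ["v1"],
                                  replicates_per_sample=1,
                                  images_per_replicate=10,
                                  cells_per_image=1000)
    cells = generate_cell_features(design, {"v1": VariantEffect("v1")},
                                   noise=QUIET, seed=0)
    cut = 2 * np.percentile(
        cells.loc[cells["role"] == "transfection_control", "gfp"], 97)
    pos = cells[cells["gfp"] >= cut]
    wt = pos.loc[pos["role"] == "wildtype", "total_ldl"]
    var = pos.loc[pos["role"] == "variant", "total_ldl"]
    assert min(len(wt), len(var)) > 2000
    assert stats.ks_2samp(wt, var).pvalue > 1e-3


def test_gated_ratio_recovers_ldl_multiplier():
    """Gating + replicate summarization recovers a 0.1x LDL effect as a
    GFP+/GFP- ratio near 0.1x the wildtype ratio."""
    design = design_with_variants(Setting.OVEREXPRESSION, ["v1"],
                                  replicates_per_sample=4,
                                  images_per_replicate=30,
                                  cells_per_image=60)
    cells = generate_cell_features(
        design, {"v1": disruptive_effect("v1", 0.1)}, seed=5)
    gated = gating.gate_experiments(cells, Setting.OVEREXPRESSION)
    summ = gating.summarize_replicates(gated)
    wt = summ[(summ["sample_id"] == "wildtype") & summ["valid"]]
    var = summ[(summ["sample_id"] == "variant:v1") & summ["valid"]]
    rel = var["ratio_total_ldl"].mean() / wt["ratio_total_ldl"].mean()
    assert rel == pytest.approx(0.1, rel=0.2)


def test_group_means_converge_to_configured_expectations():
    """Law of large numbers: GFP-negative total LDL mean approaches the
    configured log-normal mean within 3 SE."""
    design = design_with_variants(Setting.OVEREXPRESSION, [],
                                  replicates_per_sample=1,
                                  images_per_replicate=40,
                                  cells_per_image=2500)
    noise = QUIET
    cells = generate_cell_features(design, {}, noise=noise, seed=9)
    neg = cells.loc[(cells["role"] == "transfection_control")
                    & (cells["seg_number"] > 0), "total_ldl"]
    # total = baseline * u * residual with u, residual log-normal
    expected = noise.baseline_total_median * np.exp(
        (noise.cell_shared_sigma ** 2 + noise.total_sigma ** 2) / 2)
    se = neg.std() / np.sqrt(len(neg))
    assert len(neg) > 50_000
    assert abs(neg.mean() - expected) < 3 * se


def test_cohort_reproducible_and_shaped():
    spectrum = [VariantSpec("v1", "disruptive_missense", 0.01)]
    cfg = CohortConfig(n_cases=300, n_controls=300, variant_spectrum=spectrum,
                       class_mi_rr={"disruptive_missense": 5.0},
                       ldl_missing_rate=0.0, seed=3)
    c1, a1 = generate_cohort(cfg)
    c2, _ = generate_cohort(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    assert (c1["mi_status"] == "case").sum() == 300
    assert len(c1) == 600
    assert list(a1.columns) == ["variant_id", "class_label", "carrier_freq"]


def test_cohort_carrier_enrichment_matches_closed_form():
    """P(carrier | case) in a large simulated cohort matches
    f*RR / (1 + f*(RR-1))."""
    f, rr = 0.014, 5.0
    spectrum = [VariantSpec("v1", "dm", f)]
    cfg = CohortConfig(n_cases=30000, n_controls=5000,
                       variant_spectrum=spectrum, class_mi_rr={"dm": rr},
                       prevalence=0.05, ldl_missing_rate=0.0, seed=8)
    cohort, _ = generate_cohort(cfg)
    p_case = f * rr / (1 + f * (rr - 1))
    hat = cohort.loc[cohort["mi_status"] == "case", "v1"].mean()
    se = np.sqrt(p_case * (1 - p_case) / 30000)
    assert abs(hat - p_case) < 3.5 * se


def test_cohort_null_model_centred_on_zero():
    spectrum = [VariantSpec("v1", "neutral", 0.02)]
    cfg = CohortConfig(n_cases=4000, n_controls=4000,
                       variant_spectrum=spectrum, class_mi_rr={"neutral": 1.0},
                       class_ldl_shift={"neutral": 0.0},
                       ldl_missing_rate=0.0, seed=10)
    cohort, _ = generate_cohort(cfg)
    f_case = cohort.loc[cohort["mi_status"] == "case", "v1"].mean()
    f_ctrl = cohort.loc[cohort["mi_status"] == "control", "v1"].mean()
    se = np.sqrt(2 * 0.02 * 0.98 / 4000)
    assert abs(f_case - f_ctrl) < 3.5 * se


def test_cohort_class_ldl_shifts_recovered():
    """Configured class means (221 / 154 / 275 mg/dl over a 135 mg/dl
    baseline) are recovered within sampling error."""
    spectrum = ([VariantSpec(f"d{i}", "disruptive_missense", 0.004)
                 for i in range(6)]
                + [VariantSpec(f"n{i}", "non_disruptive", 0.006)
                   for i in range(6)]
                + [VariantSpec(f"l{i}", "lof", 0.003) for i in range(6)])
    shifts = {"disruptive_missense": 86.0, "non_disruptive": 19.0,
              "lof": 140.0}
    cfg = CohortConfig(n_cases=1716, n_controls=1519,
                       variant_spectrum=spectrum, class_ldl_shift=shifts,
                       class_mi_rr={"disruptive_missense": 5.0,
                                    "non_disruptive": 1.2, "lof": 5.0},
                       ldl_missing_rate=0.0, seed=12)
    cohort, ann = generate_cohort(cfg)
    for label, shift in shifts.items():
        vids = ann.loc[ann["class_label"] == label, "variant_id"]
        mask = cohort[list(vids)].any(axis=1)
        # exclude carriers of a larger-shift class (shift rule takes max)
        larger = ann.loc[ann["class_label"].map(
            lambda l: shifts.get(l, 0) > shift), "variant_id"]
        if len(larger):
            mask &= ~cohort[list(larger)].any(axis=1)
        vals = cohort.loc[mask, "ldl_c"]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - (135.0 + shift)) < 3.5 * se, label


def test_cohort_impossible_parameters_rejected():
    spectrum = [VariantSpec("v1", "dm", 0.01)]
    with pytest.raises(ValueError):
        generate_cohort(CohortConfig(
            n_cases=10, n_controls=10, variant_spectrum=spectrum,
            class_mi_rr={"dm": 5.0}, prevalence=0.5))
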