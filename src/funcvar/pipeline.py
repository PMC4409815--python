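"""End-to-end orchestration: simulate or load inputs, gate, profile,
classify, run burden association and power curves, and write a run
directory with a provenance report."""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__, gating, phenotyping, powersim, rvas, synthdata
from .synthdata import (CellNoiseModel, CohortConfig, Setting, VariantSpec,
                        design_with_variants, disruptive_effect,
                        VariantEffect, WILDTYPE_EFFECT)


def default_demo_config() -> dict:
    """A small fully-synthetic demonstration configuration: a screen of
    six variants (two programmed disruptive), a cohort with three variant
    classes, and two power scenarios."""
    variants = {
        "V1": 0.15, "V2": 0.25,          # programmed disruptive
        "V3": 1.0, "V4": 1.0, "V5": 1.0, "V6": 1.0,
    }
    spectrum = [
        {"variant_id": "V1", "class_label": "disruptive_missense",
         "carrier_freq": 0.004},
        {"variant_id": "V2", "class_label": "disruptive_missense",
         "carrier_freq": 0.004},
        {"variant_id": "V3", "class_label": "non_disruptive",
         "carrier_freq": 0.01},
        {"variant_id": "V4", "class_label": "non_disruptive",
         "carrier_freq": 0.01},
        {"variant_id": "L1", "class_label": "lof", "carrier_freq": 0.003},
    ]
    return {
        "screen": {
            "variants": variants,
            "replicates_per_sample": 4,
            "images_per_replicate": 10,
            "cells_per_image": 40,
        },
        "cohort": {
            "n_cases": 800,
            "n_controls": 800,
            "variant_spectrum": spectrum,
            "class_ldl_shift": {"disruptive_missense": 86.0,
                                "non_disruptive": 19.0, "lof": 140.0},
            "class_mi_rr": {"disruptive_missense": 5.0,
                            "non_disruptive": 1.2, "lof": 5.0},
            "ldl_missing_rate": 0.0,
        },
        "power": {
            "scenarios": [
                {"label": "disruptive+LoF", "carrier_freq": 0.014},
                {"label": "all missense", "carrier_freq": 0.055,
                 "relative_risk": 2.0},
            ],
            "n_sims": 200,
            "grid": [400, 800, 1200, 1600, 2000, 3000, 4000],
        },
    }


def _effects_from_config(variants: Mapping[str, float]) -> dict:
    effects = {}
    for vid, mult in variants.items():
        if mult == 1.0:
            effects[vid] = VariantEffect(variant_id=vid)
        else:
            effects[vid] = disruptive_effect(vid, ldl_multiplier=float(mult))
    return effects


def run_screen(config: Mapping, seed: int, out_dir: Optional[Path] = None
               ) -> dict:
    """Simulate both settings of the screen, gate, summarize and
    classify.  Returns dict with cells, summaries and profiles."""
    variants = config["variants"]
    effects = _effects_from_config(variants)
    kwargs = {k: config[k] for k in ("replicates_per_sample",
                                     "images_per_replicate",
                                     "cells_per_image") if k in config}
    results = {}
    summaries = {}
    for i, setting in enumerate((Setting.OVEREXPRESSION,
                                 Setting.COMPLEMENTATION)):
        design = design_with_variants(setting, list(variants), **kwargs)
        cells = synthdata.generate_cell_features(
            design, effects, CellNoiseModel(), seed=int(seed) + i)
        gated = gating.gate_experiments(cells, setting)
        summaries[setting] = gating.summarize_replicates(gated)
        results[f"cells_{setting.value}"] = cells
    ox = phenotyping.profile_setting(summaries[Setting.OVEREXPRESSION])
    comp = phenotyping.profile_setting(summaries[Setting.COMPLEMENTATION])
    profiles = phenotyping.build_profiles(ox, comp)
    results["summaries"] = summaries
    results["profiles"] = profiles
    if out_dir is not None:
        for setting, summ in summaries.items():
            summ.to_csv(out_dir / f"summaries_{setting.value}.tsv",
                        sep="\t", index=False)
        profiles.to_csv(out_dir / "variant_profiles.tsv", sep="\t",
                        index=False)
    return results


def run_cohort(config: Mapping, seed: int,
               inferred_classes: Optional[Mapping[str, list[str]]] = None,
               out_dir: Optional[Path] = None) -> dict:
    """Simulate the cohort and run the stratified burden tests.

    ``inferred_classes`` (e.g. from the screen's classification) defines
    the tested variant sets; without it the simulated annotation's true
    classes are used.
    """
    cfg = dict(config)
    spectrum = [VariantSpec(**v) for v in cfg.pop("variant_spectrum")]
    cohort_cfg = CohortConfig(variant_spectrum=spectrum, seed=int(seed),
                              **cfg)
    cohort, annotation = synthdata.generate_cohort(cohort_cfg)
    classes = inferred_classes
    if classes is None:
        classes = {label: grp["variant_id"].tolist()
                   for label, grp in annotation.groupby("class_label")}
    results = {}
    for kind in ("LDL", "MI"):
        res = rvas.burden_test(cohort, classes, rvas.PhenotypeDef(
            kind=kind, ldl_case_threshold=cohort_cfg.ldl_case_threshold))
        results[kind] = rvas.burden_table(res)
    if out_dir is not None:
        cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
        annotation.to_csv(out_dir / "variant_annotation.tsv", sep="\t",
                          index=False)
        for kind, table in results.items():
            table.to_csv(out_dir / f"burden_{kind.lower()}.tsv", sep="\t",
                         index=False)
    return {"cohort": cohort, "annotation": annotation, "burden": results}


def run_power(config: Mapping, seed: int,
              out_dir: Optional[Path] = None) -> pd.DataFrame:
    shared = {k: v for k, v in config.items() if k != "scenarios"}
    curves = []
    for i, scenario in enumerate(config.get("scenarios", [])):
        cfg = powersim.PowerSimConfig(**{**shared, **scenario})
        curves.append(powersim.simulate_power_curve(cfg, seed=int(seed) + i))
    out = (pd.concat(curves, ignore_index=True) if curves
           else pd.DataFrame())
    if out_dir is not None and len(out):
        out.to_csv(out_dir / "power_curves.tsv", sep="\t", index=False)
    return out


def run_pipeline(config: Mapping, out_dir: Path, seed: int = 0) -> dict:
    """Run every configured stage and write outputs plus a provenance
    report to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "funcvar_version": __version__,
        "python": sys.version.split()[0],
        "seed": int(seed),
        "stages": [],
    }
    results: dict = {}
    inferred = None
    if "screen" in config:
        results["screen"] = run_screen(config["screen"], seed, out_dir)
        profiles = results["screen"]["profiles"]
        inferred_set = profiles.loc[
            profiles["class"] == phenotyping.DISRUPTIVE,
            "variant_id"].tolist()
        report["stages"].append("screen")
        report["classified_disruptive"] = inferred_set
        if "cohort" in config:
            spectrum = config["cohort"]["variant_spectrum"]
            lof = [v["variant_id"] for v in spectrum
                   if v["class_label"] == "lof"]
            screened = [v["variant_id"] for v in spectrum
                        if v["variant_id"] in set(profiles["variant_id"])]
            inferred = {
                "disruptive_missense": inferred_set or ["__none__"],
                "disruptive_missense+lof": (inferred_set + lof) or ["__none__"],
                "all_missense": screened,
            }
            inferred = {k: v for k, v in inferred.items()
                        if v and v != ["__none__"]}
    if "cohort" in config:
        results["cohort"] = run_cohort(config["cohort"], seed,
                                       inferred_classes=inferred,
                                       out_dir=out_dir)
        report["stages"].append("cohort")
    if "power" in config:
        results["power"] = run_power(config["power"], seed, out_dir)
        report["stages"].append("power")
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=2))
    results["report"] = report
    return results


def load_config(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
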