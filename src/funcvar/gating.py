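"""Cell gating and replicate aggregation.

Cells are classified from their GFP intensity against thresholds derived
from the transfection-control sample of the same experiment: the
GFP-negative cutoff is the 97th percentile of the control GFP, the
GFP-positive cutoff is twice that, and cells in between belong to
neither group.  Under the complementation (rescue) setting, GFP-positive
cells whose total LDL signal indicates over-compensation are excluded
via two caps: 1.25x the mean total LDL signal of the transfection
control, or 5x that of siRNA-treated cells; by default a cell is kept if
it passes either cap.

Replicate summaries average per-image means (never cells pooled across
images) and require at least 25 GFP-positive cells for a replicate to be
valid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthdata import Setting

#: the five phenotypic parameters quantified per cell
PARAMETERS = ("total_ldl", "ldl_concentration", "seg_number", "seg_area", "gfp")

GFP_NEGATIVE = "gfp_negative"
GFP_POSITIVE = "gfp_positive"
INTERMEDIATE_EXCLUDED = "intermediate_excluded"
RESCUE_EXCLUDED = "rescue_excluded"

MIN_GFP_POSITIVE = 25


@dataclass(frozen=True)
class GatingThresholds:
    gfp_negative_cutoff: float
    gfp_positive_cutoff: float
    rescue_cap_transfection: Optional[float] = None
    rescue_cap_sirna: Optional[float] = None

    def __post_init__(self):
        if self.gfp_negative_cutoff <= 0:
            raise ValueError("GFP cutoffs must be positive")
        for cap in (self.rescue_cap_transfection, self.rescue_cap_sirna):
            if cap is not None and cap <= 0:
                raise ValueError("rescue caps must be positive")


def derive_thresholds(transfection_control_gfp,
                      setting: Setting | str,
                      transfection_control_total_ldl=None,
                      sirna_control_total_ldl=None,
                      percentile: float = 97.0,
                      positive_factor: float = 2.0,
                      cap_transfection_factor: float = 1.25,
                      cap_sirna_factor: float = 5.0) -> GatingThresholds:
    """Thresholds for one experiment from its own control samples.

    The percentile uses linear interpolation between closest ranks.  For
    the complementation setting the siRNA cap baseline may come from the
    siRNA-only sample or from the siRNA + GFP-control sample; pass
    whichever the analysis uses.
    """
    setting = Setting(setting)
    gfp = np.asarray(transfection_control_gfp, dtype=float)
    if gfp.size == 0:
        raise ValueError("transfection-control sample is empty")
    neg = float(np.percentile(gfp, percentile, method="linear"))
    thresholds = dict(gfp_negative_cutoff=neg,
                      gfp_positive_cutoff=positive_factor * neg)
    if setting is Setting.COMPLEMENTATION:
        if transfection_control_total_ldl is None or sirna_control_total_ldl is None:
            raise ValueError("complementation gating needs total LDL signal "
                             "of the transfection control and an siRNA control")
        thresholds["rescue_cap_transfection"] = (
            cap_transfection_factor
            * float(np.mean(np.asarray(transfection_control_total_ldl, float))))
        thresholds["rescue_cap_sirna"] = (
            cap_sirna_factor
            * float(np.mean(np.asarray(sirna_control_total_ldl, float))))
    return GatingThresholds(**thresholds)


def gate_cells(cells: pd.DataFrame, thresholds: GatingThresholds,
               setting: Setting | str,
               rescue_combine: str = "or") -> pd.DataFrame:
    """Label every cell with exactly one gate.

    Labels: gfp_negative (below the negative cutoff), gfp_positive (at
    or above the positive cutoff and, under complementation, within the
    rescue caps), intermediate_excluded (between the cutoffs) or
    rescue_excluded.  ``rescue_combine`` selects whether passing one cap
    suffices ("or", default) or both are required ("and").
    """
    setting = Setting(setting)
    if setting is Setting.COMPLEMENTATION and (
            thresholds.rescue_cap_transfection is None
            or thresholds.rescue_cap_sirna is None):
        raise ValueError("complementation gating requires rescue caps")
    if rescue_combine not in ("or", "and"):
        raise ValueError("rescue_combine must be 'or' or 'and'")
    out = cells.copy()
    gfp = out["gfp"].to_numpy(dtype=float)
    gate = np.full(len(out), INTERMEDIATE_EXCLUDED, dtype=object)
    gate[gfp < thresholds.gfp_negative_cutoff] = GFP_NEGATIVE
    positive = gfp >= thresholds.gfp_positive_cutoff
    gate[positive] = GFP_POSITIVE
    if setting is Setting.COMPLEMENTATION:
        total = out["total_ldl"].to_numpy(dtype=float)
        pass_tc = total < thresholds.rescue_cap_transfection
        pass_si = total < thresholds.rescue_cap_sirna
        retained = (pass_tc | pass_si) if rescue_combine == "or" \
            else (pass_tc & pass_si)
        gate[positive & ~retained] = RESCUE_EXCLUDED
    out["gate"] = gate
    return out


def gate_experiments(cells: pd.DataFrame, setting: Setting | str,
                     sirna_baseline_role: str = "sirna_only",
                     rescue_combine: str = "or") -> pd.DataFrame:
    """Gate a full feature table, deriving thresholds per experiment.

    Each replicate index is one experiment carrying its own transfection
    control, from which that experiment's thresholds are derived.
    """
    setting = Setting(setting)
    gated = []
    for rep, block in cells.groupby("replicate", sort=True):
        control = block[block["role"] == "transfection_control"]
        if control.empty:
            raise ValueError(f"experiment {rep} has no transfection control")
        kwargs = {}
        if setting is Setting.COMPLEMENTATION:
            sirna = block[block["role"] == sirna_baseline_role]
            if sirna.empty:
                raise ValueError(
                    f"experiment {rep} has no {sirna_baseline_role} sample")
            kwargs = dict(
                transfection_control_total_ldl=control["total_ldl"],
                sirna_control_total_ldl=sirna["total_ldl"])
        thr = derive_thresholds(control["gfp"], setting, **kwargs)
        gated.append(gate_cells(block, thr, setting,
                                rescue_combine=rescue_combine))
    return pd.concat(gated, ignore_index=True)


def summarize_replicates(gated: pd.DataFrame,
                         parameters: Sequence[str] = PARAMETERS,
                         min_gfp_positive: int = MIN_GFP_POSITIVE) -> pd.DataFrame:
    """Per-sample, per-replicate summary of gated cells.

    Means are computed per image within each GFP group and then averaged
    across the images of the replicate (images lacking a group do not
    contribute to that group's average).  The ratio per parameter is the
    GFP-positive over the GFP-negative replicate mean.  A replicate is
    valid only with at least ``min_gfp_positive`` GFP-positive cells and
    defined ratios.
    """
    rows = []
    for (sample, rep), block in gated.groupby(["sample_id", "replicate"],
                                              sort=True):
        row: dict = {
            "sample_id": sample,
            "role": block["role"].iloc[0],
            "variant_id": block["variant_id"].iloc[0],
            "replicate": rep,
        }
        pos = block[block["gate"] == GFP_POSITIVE]
        neg = block[block["gate"] == GFP_NEGATIVE]
        row["n_gfp_positive"] = int(len(pos))
        row["n_gfp_negative"] = int(len(neg))
        ratios_ok = True
        for param in parameters:
            pos_mean = (pos.groupby("image_id")[param].mean().mean()
                        if len(pos) else np.nan)
            neg_mean = (neg.groupby("image_id")[param].mean().mean()
                        if len(neg) else np.nan)
            row[f"pos_{param}"] = pos_mean
            row[f"neg_{param}"] = neg_mean
            if np.isnan(pos_mean) or not neg_mean > 0:
                row[f"ratio_{param}"] = np.nan
                ratios_ok = False
            else:
                row[f"ratio_{param}"] = pos_mean / neg_mean
        row["valid"] = bool(row["n_gfp_positive"] >= min_gfp_positive
                            and ratios_ok)
        rows.append(row)
    return pd.DataFrame(rows)
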