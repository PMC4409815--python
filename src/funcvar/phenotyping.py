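"""Per-variant statistics and the disruptive / non-disruptive /
unclear classification.

A variant's replicate ratios (GFP-positive over GFP-negative means) are
compared with the wildtype ratios of the same experiments by a paired,
two-tailed t-test.  For the parameter total LDL signal a significance
call additionally requires a deviation value above 1, where the
deviation is a z-score-like effect measure: the absolute difference of
the variant and wildtype mean ratios in units of the wildtype ratio's
replicate SD.  Classification:

* disruptive_missense — overexpression total LDL signal plus at least
  two other DiI parameters significant, validated by a significant
  complementation total LDL signal where complementation data exist;
* non_disruptive — none of the eight DiI parameters (four per setting)
  significant;
* unclear — anything else.

GFP expression is reported but never enters the rule.  No
multiple-testing correction is applied across parameters or variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import Setting

#: the four DiI-LDL parameters entering the classification rule
DII_PARAMETERS = ("total_ldl", "ldl_concentration", "seg_number", "seg_area")

DISRUPTIVE = "disruptive_missense"
NON_DISRUPTIVE = "non_disruptive"
UNCLEAR = "unclear"


@dataclass(frozen=True)
class SignificanceConfig:
    alpha: float = 0.05
    deviation_threshold: float = 1.0
    #: parameters for which the deviation criterion applies on top of p
    deviation_parameters: tuple[str, ...] = ("total_ldl",)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.deviation_threshold <= 0:
            raise ValueError("deviation threshold must be positive")


@dataclass(frozen=True)
class ParameterTest:
    p: float
    deviation: float
    significant: Optional[bool]  # None: undeterminable (< 2 paired replicates)
    n_pairs: int
    mean_relative: float  # variant mean ratio / wildtype mean ratio


def test_parameter(variant_ratios, wildtype_ratios,
                   config: SignificanceConfig = SignificanceConfig(),
                   parameter: str = "total_ldl") -> ParameterTest:
    """Paired two-tailed t-test of variant against wildtype replicate
    ratios, plus the deviation value.

    Pairing is positional: element i of both arrays comes from the same
    experiment.  Pairs with a missing member are dropped; fewer than two
    remaining pairs make the call undeterminable (``significant=None``).
    """
    v = np.asarray(variant_ratios, dtype=float)
    w = np.asarray(wildtype_ratios, dtype=float)
    if v.shape != w.shape:
        raise ValueError("variant and wildtype ratios must be paired")
    keep = ~(np.isnan(v) | np.isnan(w))
    v, w = v[keep], w[keep]
    n = len(v)
    mean_rel = float(v.mean() / w.mean()) if n and w.mean() != 0 else np.nan
    if n < 2:
        return ParameterTest(np.nan, np.nan, None, n, mean_rel)

    diff = v - w
    if np.allclose(diff.std(ddof=1), 0.0):
        p = np.nan  # degenerate paired differences: no test possible
    else:
        p = float(stats.ttest_rel(v, w).pvalue)

    sd_w = float(w.std(ddof=1))
    gap = abs(float(v.mean() - w.mean()))
    if sd_w == 0.0:
        deviation = np.inf if gap > 0 else 0.0
    else:
        deviation = gap / sd_w

    significant = bool(p < config.alpha) if not np.isnan(p) else False
    if parameter in config.deviation_parameters:
        significant = significant and deviation > config.deviation_threshold
    return ParameterTest(p, deviation, significant, n, mean_rel)


def _ratio_frame(summaries: pd.DataFrame, sample_id: str,
                 parameters: Sequence[str]) -> pd.DataFrame:
    sub = summaries[(summaries["sample_id"] == sample_id)
                    & summaries["valid"]]
    cols = {p: sub[f"ratio_{p}"].to_numpy(dtype=float) for p in parameters}
    return pd.DataFrame(cols, index=sub["replicate"].to_numpy())


def profile_setting(summaries: pd.DataFrame,
                    config: SignificanceConfig = SignificanceConfig(),
                    parameters: Sequence[str] = DII_PARAMETERS + ("gfp",),
                    wildtype_sample: str = "wildtype") -> pd.DataFrame:
    """Per-variant parameter tests for one experimental setting.

    ``summaries`` is the output of
    :func:`funcvar.gating.summarize_replicates`.  Variant replicates are
    paired with the wildtype replicates of the same experiments; invalid
    replicates are excluded on either side.
    """
    wt = _ratio_frame(summaries, wildtype_sample, parameters)
    rows = []
    variant_samples = summaries.loc[
        summaries["role"] == "variant", "sample_id"].unique()
    for sample in variant_samples:
        var = _ratio_frame(summaries, sample, parameters)
        common = var.index.intersection(wt.index)
        variant_id = summaries.loc[
            summaries["sample_id"] == sample, "variant_id"].iloc[0]
        row: dict = {"variant_id": variant_id,
                     "n_valid_replicates": int(len(common))}
        for param in parameters:
            t = test_parameter(var.loc[common, param], wt.loc[common, param],
                               config, parameter=param)
            row[f"p_{param}"] = t.p
            row[f"deviation_{param}"] = t.deviation
            row[f"significant_{param}"] = t.significant
            row[f"rel_{param}"] = t.mean_relative
        rows.append(row)
    return pd.DataFrame(rows)


def classify_variant(overexpression: Mapping[str, Optional[bool]],
                     complementation: Optional[Mapping[str, Optional[bool]]],
                     parameters: Sequence[str] = DII_PARAMETERS
                     ) -> tuple[str, bool]:
    """Apply the classification rule to per-parameter significance flags.

    ``overexpression`` maps each DiI parameter to True / False / None
    (None: undeterminable); ``complementation`` likewise, or None when no
    complementation data exist.  Returns (class label, validated): when
    complementation data are missing a disruptive call is made on
    overexpression alone and flagged as not validated.
    """
    if overexpression is None:
        raise ValueError("overexpression results are required")
    ox_total = overexpression.get("total_ldl")
    ox_other = sum(bool(overexpression.get(p)) for p in parameters
                   if p != "total_ldl")
    disruptive_ox = bool(ox_total) and ox_other >= 2

    flags = [overexpression.get(p) for p in parameters]
    has_comp = complementation is not None
    if has_comp:
        flags += [complementation.get(p) for p in parameters]
    any_significant = any(bool(f) for f in flags)

    if disruptive_ox:
        if has_comp:
            if bool(complementation.get("total_ldl")):
                return DISRUPTIVE, True
            return UNCLEAR, False  # failed complementation validation
        return DISRUPTIVE, False
    if not any_significant:
        return NON_DISRUPTIVE, has_comp
    return UNCLEAR, has_comp


def build_profiles(ox_profile: pd.DataFrame,
                   comp_profile: Optional[pd.DataFrame] = None,
                   parameters: Sequence[str] = DII_PARAMETERS) -> pd.DataFrame:
    """Join per-setting profiles and attach the final class label."""
    merged = ox_profile.add_prefix("ox_").rename(
        columns={"ox_variant_id": "variant_id"})
    if comp_profile is not None:
        comp = comp_profile.add_prefix("comp_").rename(
            columns={"comp_variant_id": "variant_id"})
        merged = merged.merge(comp, on="variant_id", how="left")
    labels, validated = [], []
    for _, row in merged.iterrows():
        ox = {p: row[f"ox_significant_{p}"] for p in parameters}
        comp_flags = None
        if comp_profile is not None and f"comp_significant_{parameters[0]}" in row:
            vals = {p: row[f"comp_significant_{p}"] for p in parameters}
            if not all(pd.isna(v) for v in vals.values()):
                comp_flags = {p: (None if pd.isna(v) else bool(v))
                              for p, v in vals.items()}
        ox = {p: (None if pd.isna(v) else bool(v)) for p, v in ox.items()}
        label, ok = classify_variant(ox, comp_flags, parameters)
        labels.append(label)
        validated.append(ok)
    merged["class"] = labels
    merged["validated"] = validated
    return merged


def fc_validation(variant_fc_ratios, wildtype_fc_ratios,
                  config: SignificanceConfig = SignificanceConfig()
                  ) -> ParameterTest:
    """Free-cholesterol validation of a disruptive call: identical
    significance criteria as the total LDL signal (paired t-test plus
    deviation), on GFP-positive / GFP-negative filipin ratios."""
    return test_parameter(variant_fc_ratios, wildtype_fc_ratios, config,
                          parameter="total_ldl")


def setting_concordance(ox_means, comp_means) -> tuple[float, float]:
    """Pearson r and r^2 between per-variant overexpression and
    complementation means for one parameter."""
    x = np.asarray(ox_means, dtype=float)
    y = np.asarray(comp_means, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("concordance needs at least 3 variants")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one setting's means")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, r * r


def concordance_table(profiles: pd.DataFrame,
                      parameters: Sequence[str] = DII_PARAMETERS
                      ) -> pd.DataFrame:
    rows = []
    for param in parameters:
        r, r2 = setting_concordance(profiles[f"ox_rel_{param}"],
                                    profiles[f"comp_rel_{param}"])
        rows.append({"parameter": param, "pearson_r": r, "r_squared": r2})
    return pd.DataFrame(rows)
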