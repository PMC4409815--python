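"""Functionally-stratified rare-variant burden association.

A cohort table carries one row per subject (id, MI status, LDL-C in
mg/dl, sex, age) plus one boolean carrier column per rare variant.  A
burden test collapses the carriers of a declared variant class into a
2x2 table against a binary phenotype (hypercholesterolemia, defined as
LDL-C above a threshold, or MI case/control status) and applies the
exact conditional analysis from :mod:`funcvar.exact`.

Conventions deliberately follow the source study design:

* allele frequency is reported per *subject* (allele count divided by
  the number of subjects analyzed), not per chromosome;
* subjects with missing LDL-C are excluded from LDL analyses only and
  retained for MI;
* no multiple-testing correction is applied across burden classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import exact

#: columns of a cohort table that are not variant carrier flags
FIXED_COLUMNS = ("subject_id", "mi_status", "ldl_c", "sex", "age")

DEFAULT_LDL_THRESHOLD = 190.0


@dataclass(frozen=True)
class PhenotypeDef:
    """Binary phenotype for burden testing: 'LDL' dichotomizes LDL-C at
    ``ldl_case_threshold`` mg/dl; 'MI' uses the recorded case status."""

    kind: str = "MI"
    ldl_case_threshold: float = DEFAULT_LDL_THRESHOLD

    def __post_init__(self):
        if self.kind not in ("LDL", "MI"):
            raise ValueError("phenotype kind must be 'LDL' or 'MI'")
        if self.ldl_case_threshold <= 0:
            raise ValueError("ldl_case_threshold must be positive")


@dataclass(frozen=True)
class BurdenResult:
    class_label: str
    variant_count: int
    allele_count: int
    allele_freq: float
    n_subjects: int
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    p_two_sided: float
    or_cmle: float
    or_sample: float
    ci95: tuple[float, float] = field(default=(np.nan, np.nan))

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "class_label", "variant_count", "allele_count", "allele_freq",
            "n_subjects", "a", "b", "c", "d", "p_two_sided", "or_cmle",
            "or_sample")}
        out["ci95_low"], out["ci95_high"] = self.ci95
        return out


def variant_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c not in FIXED_COLUMNS]


def _phenotype_split(cohort: pd.DataFrame, phenotype: PhenotypeDef):
    if phenotype.kind == "LDL":
        sub = cohort.dropna(subset=["ldl_c"])
        is_case = sub["ldl_c"] > phenotype.ldl_case_threshold
    else:
        sub = cohort
        is_case = sub["mi_status"] == "case"
    return sub, np.asarray(is_case, dtype=bool)


def build_contingency(cohort: pd.DataFrame, variants: Iterable[str],
                      phenotype: PhenotypeDef) -> dict:
    """Carrier-by-phenotype counts plus allele statistics for one class.

    Returns a dict with keys a, b, c, d (case carriers, case
    non-carriers, control carriers, control non-carriers),
    variant_count (variants of the class observed in the analyzed
    subjects), allele_count (summed carrier flags; a subject carrying
    variants of more than one site contributes each allele) and
    allele_freq = allele_count / n_subjects.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("variant class is empty")
    missing = [v for v in variants if v not in cohort.columns]
    if missing:
        raise KeyError(f"variants absent from cohort table: {missing}")
    sub, is_case = _phenotype_split(cohort, phenotype)
    if len(sub) == 0 or is_case.sum() == 0 or (~is_case).sum() == 0:
        raise ValueError("phenotype does not split subjects into two groups")
    flags = sub[variants].to_numpy(dtype=bool)
    carrier = flags.any(axis=1)
    a = int((carrier & is_case).sum())
    c = int((carrier & ~is_case).sum())
    return {
        "a": a,
        "b": int(is_case.sum()) - a,
        "c": c,
        "d": int((~is_case).sum()) - c,
        "variant_count": int((flags.sum(axis=0) > 0).sum()),
        "allele_count": int(flags.sum()),
        "allele_freq": float(flags.sum() / len(sub)),
        "n_subjects": int(len(sub)),
    }


def exact_association(a: int, b: int, c: int, d: int) -> dict:
    """Two-sided exact p, conditional-MLE OR with exact 95% CI, and the
    sample cross-product OR for a 2x2 table."""
    return {
        "p_two_sided": exact.fisher_exact_two_sided(a, b, c, d),
        "or_cmle": exact.cmle_odds_ratio(a, b, c, d),
        "or_sample": exact.sample_odds_ratio(a, b, c, d),
        "ci95": exact.exact_or_ci(a, b, c, d),
    }


def burden_test(cohort: pd.DataFrame, classes: Mapping[str, Sequence[str]],
                phenotype: PhenotypeDef) -> list[BurdenResult]:
    """Run the burden association for every variant class."""
    results = []
    for label, variants in classes.items():
        counts = build_contingency(cohort, variants, phenotype)
        stats = exact_association(counts["a"], counts["b"],
                                  counts["c"], counts["d"])
        results.append(BurdenResult(
            class_label=label,
            variant_count=counts["variant_count"],
            allele_count=counts["allele_count"],
            allele_freq=counts["allele_freq"],
            n_subjects=counts["n_subjects"],
            a=counts["a"], b=counts["b"], c=counts["c"], d=counts["d"],
            p_two_sided=stats["p_two_sided"],
            or_cmle=stats["or_cmle"],
            or_sample=stats["or_sample"],
            ci95=stats["ci95"],
        ))
    return results


def burden_table(results: Iterable[BurdenResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


def effect_size_regression(cohort: pd.DataFrame,
                           variants: Iterable[str]) -> tuple[float, float]:
    """OLS effect of carrier status on LDL-C (mg/dl), adjusted for sex
    and age.  Returns (beta, standard error) for carrier status."""
    variants = list(variants)
    sub = cohort.dropna(subset=["ldl_c"]).copy()
    carrier = sub[variants].to_numpy(dtype=bool).any(axis=1).astype(float)
    if carrier.min() == carrier.max():
        raise ValueError("no variation in carrier status among subjects "
                         "with LDL-C")
    X = pd.DataFrame({
        "carrier": carrier,
        "sex": pd.to_numeric(sub["sex"]).to_numpy(dtype=float),
        "age": sub["age"].to_numpy(dtype=float),
    })
    X = sm.add_constant(X)
    fit = sm.OLS(sub["ldl_c"].to_numpy(dtype=float), X).fit()
    return float(fit.params["carrier"]), float(fit.bse["carrier"])


def prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Polygenic risk score: weighted sum of effect-allele dosages.

    ``dosages`` is subjects x variants (0/1/2 or fractional); ``weights``
    has columns variant_id and weight (mg/dl per allele).  Every weight
    must match a dosage column.
    """
    w = weights.set_index("variant_id")["weight"]
    missing = [v for v in w.index if v not in dosages.columns]
    if missing:
        raise KeyError(f"dosages missing for variants: {missing}")
    mat = dosages[list(w.index)].to_numpy(dtype=float)
    return pd.Series(mat @ w.to_numpy(dtype=float), index=dosages.index,
                     name="prs")
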