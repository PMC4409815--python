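"""Synthetic inputs with known, recoverable parameters.

Two generators live here:

* :func:`generate_cell_features` emulates the per-cell feature tables of
  a high-content LDL-uptake screen.  An experiment (one biological
  replicate) contains a panel of samples — controls plus
  variant-expressing wells — imaged at several positions.  Fluorescence
  intensities are log-normal (strictly positive and right-skewed, as in
  practice); a variant acts multiplicatively on the expected readouts of
  the GFP-positive subpopulation.

* :func:`generate_cohort` emulates a case-control cohort with rare
  carriers, class-specific LDL-C shifts and a relative-risk disease
  model, sampled under case-control ascertainment (carrier status first,
  then Bernoulli disease status with penetrances solved from RR and
  prevalence, then rejection sampling to the requested arm sizes).

Image rendering for the segmentation stage is in :mod:`funcvar.render`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class Setting(str, enum.Enum):
    OVEREXPRESSION = "overexpression"
    COMPLEMENTATION = "complementation"


class SampleRole(str, enum.Enum):
    TRANSFECTION_CONTROL = "transfection_control"
    GFP_CONTROL = "gfp_control"
    WILDTYPE = "wildtype"
    VARIANT = "variant"
    SIRNA_ONLY = "sirna_only"
    SIRNA_PLUS_GFP = "sirna_plus_gfp"
    CONTROL_SIRNA = "control_sirna"


#: roles whose cells may express a GFP construct
_EXPRESSING_ROLES = {SampleRole.GFP_CONTROL, SampleRole.WILDTYPE,
                     SampleRole.VARIANT, SampleRole.SIRNA_PLUS_GFP}
#: roles carrying a functional (wildtype or variant) receptor construct
_RECEPTOR_ROLES = {SampleRole.WILDTYPE, SampleRole.VARIANT}
#: roles treated with LDLR siRNA in a complementation experiment
_SILENCED_ROLES = {SampleRole.WILDTYPE, SampleRole.VARIANT,
                   SampleRole.SIRNA_ONLY, SampleRole.SIRNA_PLUS_GFP}

_REQUIRED_CONTROLS = {
    Setting.OVEREXPRESSION: {SampleRole.TRANSFECTION_CONTROL,
                             SampleRole.GFP_CONTROL, SampleRole.WILDTYPE},
    Setting.COMPLEMENTATION: {SampleRole.TRANSFECTION_CONTROL,
                              SampleRole.GFP_CONTROL, SampleRole.WILDTYPE,
                              SampleRole.SIRNA_ONLY, SampleRole.SIRNA_PLUS_GFP,
                              SampleRole.CONTROL_SIRNA},
}


@dataclass(frozen=True)
class SampleSpec:
    role: SampleRole
    variant_id: Optional[str] = None

    @property
    def sample_id(self) -> str:
        if self.role is SampleRole.VARIANT:
            return f"variant:{self.variant_id}"
        return self.role.value

    def __post_init__(self):
        if self.role is SampleRole.VARIANT and not self.variant_id:
            raise ValueError("variant samples need a variant_id")


@dataclass
class ExperimentDesign:
    setting: Setting
    samples: Sequence[SampleSpec]
    replicates_per_sample: int = 4
    images_per_replicate: int = 30
    cells_per_image: float = 80.0

    def __post_init__(self):
        self.setting = Setting(self.setting)
        roles = {s.role for s in self.samples}
        missing = _REQUIRED_CONTROLS[self.setting] - roles
        if missing:
            raise ValueError(
                f"{self.setting.value} design lacks required controls: "
                f"{sorted(r.value for r in missing)}")
        if (self.replicates_per_sample < 1 or self.images_per_replicate < 1
                or self.cells_per_image <= 0):
            raise ValueError("replicate, image and cell counts must be positive")
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in design")

    @property
    def variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.samples
                if s.role is SampleRole.VARIANT]


def design_with_variants(setting: Setting | str, variant_ids: Sequence[str],
                         **kwargs) -> ExperimentDesign:
    """Standard design: the controls the setting requires plus one
    sample per variant."""
    setting = Setting(setting)
    controls = [SampleSpec(r) for r in sorted(_REQUIRED_CONTROLS[setting],
                                              key=lambda r: r.value)]
    samples = controls + [SampleSpec(SampleRole.VARIANT, v)
                          for v in variant_ids]
    return ExperimentDesign(setting=setting, samples=samples, **kwargs)


@dataclass(frozen=True)
class VariantEffect:
    """Multiplicative effect of a variant on the GFP-positive readouts.

    ``ldl_multiplier`` scales the expected total LDL signal relative to
    the wildtype GFP-positive expectation; segment number and area have
    their own multipliers and LDL concentration is implied as
    total / area.  ``gfp_multiplier`` scales construct expression.
    """

    variant_id: str
    ldl_multiplier: float = 1.0
    seg_number_multiplier: float = 1.0
    seg_area_multiplier: float = 1.0
    gfp_multiplier: float = 1.0

    def __post_init__(self):
        for name in ("ldl_multiplier", "seg_number_multiplier",
                     "seg_area_multiplier", "gfp_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def concentration_multiplier(self) -> float:
        return self.ldl_multiplier / self.seg_area_multiplier


WILDTYPE_EFFECT = VariantEffect(variant_id="wildtype")


def disruptive_effect(variant_id: str, ldl_multiplier: float = 0.2,
                      gfp_multiplier: float = 1.0) -> VariantEffect:
    """Preset for a disruptive variant: LDL uptake reduced to
    ``ldl_multiplier`` of wildtype with proportionally fewer and smaller
    endosome-like segments (square-root allocation across count and
    area)."""
    s = float(np.sqrt(ldl_multiplier))
    return VariantEffect(variant_id=variant_id, ldl_multiplier=ldl_multiplier,
                         seg_number_multiplier=s, seg_area_multiplier=s,
                         gfp_multiplier=gfp_multiplier)


@dataclass
class CellNoiseModel:
    """Distributional parameters of the simulated screen (a.u.).

    GFP and DiI intensities are log-normal; ``*_median`` values are the
    distribution medians and ``*_sigma`` the log-scale SDs.  The four
    DiI parameters of a cell share the per-sample-per-replicate jitter
    ``replicate_sigma`` (biological replicate variability of the
    GFP-positive uptake level) and the per-experiment factor
    ``batch_sigma`` shared by every sample of the experiment, which is
    what pairing variant and wildtype within an experiment cancels.
    """

    gfp_background_median: float = 100.0
    gfp_background_sigma: float = 0.35
    gfp_expressing_median: float = 2000.0
    gfp_expressing_sigma: float = 0.6
    transfection_efficiency: float = 0.3

    baseline_total_median: float = 500.0
    cell_shared_sigma: float = 0.45  # per-cell uptake factor, all DiI readouts
    total_sigma: float = 0.15       # residual cell-level noise, total signal
    uptake_boost: float = 5.0       # GFP+ wildtype over baseline, overexpression
    rescue_level: float = 0.7       # GFP+ wildtype over baseline, complementation
    knockdown_factor: float = 0.25  # residual uptake after LDLR siRNA

    seg_number_mean: float = 14.0   # baseline Poisson mean of segment count
    seg_area_median: float = 70.0   # baseline summed segment area, px
    seg_area_sigma: float = 0.15    # residual cell-level noise, summed area

    replicate_sigma: float = 0.15
    batch_sigma: float = 0.15

    def __post_init__(self):
        if not 0 < self.transfection_efficiency < 1:
            raise ValueError("transfection_efficiency must be in (0, 1)")


def _state_factor(role: SampleRole, setting: Setting, expressing, noise):
    """Per-cell uptake state relative to the endogenous baseline,
    before variant multipliers and jitter."""
    n = len(expressing)
    if setting is Setting.OVEREXPRESSION:
        s = np.ones(n)
        if role in _RECEPTOR_ROLES:
            s[expressing] = noise.uptake_boost
        return s
    # complementation: siRNA-treated wells start from the knocked-down level
    if role in _SILENCED_ROLES:
        s = np.full(n, noise.knockdown_factor)
        if role in _RECEPTOR_ROLES:
            s[expressing] = noise.rescue_level
        return s
    return np.ones(n)


def generate_cell_features(design: ExperimentDesign,
                           effects: Mapping[str, VariantEffect],
                           noise: Optional[CellNoiseModel] = None,
                           seed: int = 0) -> pd.DataFrame:
    """Simulate the per-cell five-parameter feature table for a design.

    Returns one row per cell with columns: sample_id, role, variant_id,
    replicate, image_id, gfp, total_ldl, ldl_concentration, seg_number,
    seg_area.  The GFP-positive subpopulation of a variant sample has
    expected total LDL signal equal to ldl_multiplier times the wildtype
    GFP-positive expectation of the same setting.
    """
    noise = noise or CellNoiseModel()
    missing = [v for v in design.variant_ids if v not in effects]
    if missing:
        raise KeyError(f"no VariantEffect supplied for: {missing}")
    rng = np.random.default_rng(seed)
    blocks = []
    for rep in range(1, design.replicates_per_sample + 1):
        batch = float(np.exp(rng.normal(0.0, noise.batch_sigma)))
        for spec in design.samples:
            eff = (effects[spec.variant_id]
                   if spec.role is SampleRole.VARIANT else WILDTYPE_EFFECT)
            rep_eff = float(np.exp(rng.normal(0.0, noise.replicate_sigma)))
            counts = rng.poisson(design.cells_per_image,
                                 design.images_per_replicate)
            counts = np.maximum(counts, 1)
            n = int(counts.sum())
            image_id = np.repeat(np.arange(1, design.images_per_replicate + 1),
                                 counts)

            if spec.role in _EXPRESSING_ROLES:
                expressing = rng.random(n) < noise.transfection_efficiency
            else:
                expressing = np.zeros(n, dtype=bool)

            gfp = np.exp(rng.normal(np.log(noise.gfp_background_median),
                                    noise.gfp_background_sigma, n))
            if expressing.any():
                gfp[expressing] = np.exp(rng.normal(
                    np.log(noise.gfp_expressing_median * eff.gfp_multiplier),
                    noise.gfp_expressing_sigma, int(expressing.sum())))

            state = _state_factor(spec.role, design.setting, expressing, noise)
            # variant multipliers and replicate jitter act on the
            # GFP-positive receptor-expressing subpopulation only
            m_ldl = np.ones(n)
            m_num = np.ones(n)
            m_area = np.ones(n)
            if spec.role in _RECEPTOR_ROLES:
                # the replicate-level uptake jitter loads on every DiI
                # readout (count, area and intensity of endosome-like
                # segments co-vary with the uptake level); the summed
                # area responds sub-linearly so that the per-segment
                # concentration (total / area) also tracks the jitter
                m_ldl[expressing] = eff.ldl_multiplier * rep_eff
                m_num[expressing] = eff.seg_number_multiplier * rep_eff
                m_area[expressing] = eff.seg_area_multiplier * np.sqrt(rep_eff)

            # per-cell uptake factor shared by the DiI readouts: a cell
            # internalizing more LDL shows more, larger and brighter
            # endosome-like segments (loading u / u / sqrt(u))
            u = np.exp(rng.normal(0.0, noise.cell_shared_sigma, n))
            seg_number = rng.poisson(noise.seg_number_mean
                                     * np.sqrt(state) * m_num * u)
            total = np.exp(rng.normal(
                np.log(noise.baseline_total_median * state * m_ldl * batch
                       * u),
                noise.total_sigma))
            seg_area = np.exp(rng.normal(
                np.log(noise.seg_area_median * np.sqrt(state) * m_area
                       * np.sqrt(u)),
                noise.seg_area_sigma))
            empty = seg_number == 0
            total[empty] = 0.0
            seg_area[empty] = 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                conc = np.where(seg_area > 0, total / seg_area, 0.0)

            blocks.append(pd.DataFrame({
                "sample_id": spec.sample_id,
                "role": spec.role.value,
                "variant_id": spec.variant_id or "",
                "replicate": rep,
                "image_id": image_id,
                "gfp": gfp,
                "total_ldl": total,
                "ldl_concentration": conc,
                "seg_number": seg_number,
                "seg_area": seg_area,
            }))
    out = pd.concat(blocks, ignore_index=True)
    out.insert(0, "cell_id", np.arange(1, len(out) + 1))
    return out


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class VariantSpec:
    variant_id: str
    class_label: str
    carrier_freq: float

    def __post_init__(self):
        if not 0 < self.carrier_freq < 1:
            raise ValueError("carrier frequency must be in (0, 1)")


@dataclass
class CohortConfig:
    n_cases: int = 1716
    n_controls: int = 1519
    variant_spectrum: Sequence[VariantSpec] = field(default_factory=list)
    ldl_baseline_mean: float = 135.0
    ldl_baseline_sd: float = 30.0
    class_ldl_shift: Mapping[str, float] = field(default_factory=dict)
    class_mi_rr: Mapping[str, float] = field(default_factory=dict)
    prevalence: float = 0.05
    ldl_case_threshold: float = 190.0
    ldl_missing_rate: float = 0.335
    age_mean: float = 42.0
    age_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("arm sizes must be positive")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.ldl_case_threshold <= 0:
            raise ValueError("ldl_case_threshold must be positive")
        if not 0 <= self.ldl_missing_rate < 1:
            raise ValueError("ldl_missing_rate must be in [0, 1)")
        labels = {v.class_label for v in self.variant_spectrum}
        for label in labels:
            if self.class_mi_rr.get(label, 1.0) <= 0:
                raise ValueError("relative risks must be positive")


def _class_rr(config: CohortConfig, label: str) -> float:
    return float(config.class_mi_rr.get(label, 1.0))


def _baseline_penetrance(config: CohortConfig) -> float:
    """Non-carrier disease probability K0 matching the marginal
    prevalence: K = K0 * E[RR(subject)], where a subject's RR is that of
    the highest-risk class it carries."""
    labels = sorted({v.class_label for v in config.variant_spectrum},
                    key=lambda l: -_class_rr(config, l))
    p_class = {}
    for label in labels:
        freqs = [v.carrier_freq for v in config.variant_spectrum
                 if v.class_label == label]
        p_class[label] = 1.0 - float(np.prod([1.0 - f for f in freqs]))
    mean_rr = 0.0
    p_no_higher = 1.0
    for label in labels:
        mean_rr += p_no_higher * p_class[label] * _class_rr(config, label)
        p_no_higher *= 1.0 - p_class[label]
    mean_rr += p_no_higher * 1.0
    k0 = config.prevalence / mean_rr
    max_rr = max([_class_rr(config, l) for l in labels], default=1.0)
    if k0 * max_rr > 1.0:
        raise ValueError("RR and prevalence imply a carrier penetrance > 1")
    return k0


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a case-control cohort under the relative-risk model.

    Returns the cohort table (subject_id, mi_status, ldl_c, sex, age,
    plus one boolean column per variant) and the variant annotation
    table (variant_id, class_label, carrier_freq).  LDL-C is baseline
    plus the shift of the subject's largest-shift carried class plus
    Gaussian noise, with a configurable missingness rate.
    """
    if not config.variant_spectrum:
        raise ValueError("variant spectrum is empty")
    rng = np.random.default_rng(config.seed)
    k0 = _baseline_penetrance(config)
    freqs = np.array([v.carrier_freq for v in config.variant_spectrum])
    rrs = np.array([_class_rr(config, v.class_label)
                    for v in config.variant_spectrum])
    shifts = np.array([float(config.class_ldl_shift.get(v.class_label, 0.0))
                       for v in config.variant_spectrum])

    cases, controls = [], []
    n_case_needed, n_ctrl_needed = config.n_cases, config.n_controls
    # expected fraction of cases ~ prevalence; size batches accordingly
    batch = max(int(max(n_case_needed / config.prevalence,
                        n_ctrl_needed / (1 - config.prevalence)) * 0.25),
                10_000)
    guard = 0
    while n_case_needed > 0 or n_ctrl_needed > 0:
        guard += 1
        if guard > 400:
            raise RuntimeError("cohort rejection sampling did not converge")
        flags = rng.random((batch, len(freqs))) < freqs
        subj_rr = np.where(flags.any(axis=1),
                           np.where(flags, rrs, 1.0).max(axis=1), 1.0)
        is_case = rng.random(batch) < k0 * subj_rr
        subj_shift = np.where(flags.any(axis=1),
                              np.where(flags, shifts, 0.0).max(axis=1), 0.0)
        ldl = (config.ldl_baseline_mean + subj_shift
               + rng.normal(0.0, config.ldl_baseline_sd, batch))
        sex = rng.integers(0, 2, batch)
        age = rng.normal(config.age_mean, config.age_sd, batch)
        df = pd.DataFrame(flags, columns=[v.variant_id
                                          for v in config.variant_spectrum])
        df.insert(0, "age", age)
        df.insert(0, "sex", sex)
        df.insert(0, "ldl_c", ldl)
        df.insert(0, "mi_status", np.where(is_case, "case", "control"))
        take_case = df[is_case].head(n_case_needed)
        take_ctrl = df[~is_case].head(n_ctrl_needed)
        cases.append(take_case)
        controls.append(take_ctrl)
        n_case_needed -= len(take_case)
        n_ctrl_needed -= len(take_ctrl)

    cohort = pd.concat(cases + controls, ignore_index=True)
    if config.ldl_missing_rate > 0:
        drop = rng.random(len(cohort)) < config.ldl_missing_rate
        cohort.loc[drop, "ldl_c"] = np.nan
    cohort.insert(0, "subject_id",
                  [f"S{i:06d}" for i in range(1, len(cohort) + 1)])
    annotation = pd.DataFrame(
        [{"variant_id": v.variant_id, "class_label": v.class_label,
          "carrier_freq": v.carrier_freq} for v in config.variant_spectrum])
    return cohort, annotation


def spectrum_from_frame(frame: pd.DataFrame) -> list[VariantSpec]:
    """Variant spectrum from a table with columns variant_id,
    class_label, carrier_freq."""
    return [VariantSpec(r.variant_id, r.class_label, float(r.carrier_freq))
            for r in frame.itertuples()]
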