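import numpy as np
import pandas as pd
import pytest

# Published burden-association counts for the ATVB cohort: per variant
# class, (case carriers, case non-carriers, control carriers, control
# non-carriers) together with the printed odds ratio and exact 95% CI.
# LDL rows compare hypercholesterolemia (LDL-C > 190 mg/dl, n = 251)
# against the remainder (n = 1,901); MI rows compare 1,716 cases with
# 1,519 controls.
TABLE1 = {
    ("LDL", "clear_lof"): dict(counts=(13, 238, 3, 1898), or_printed=34.4,
                               ci_printed=(9.4, 189.7)),
    ("LDL", "all_missense"): dict(counts=(35, 216, 92, 1809), or_printed=3.2,
                                  ci_printed=(2.0, 4.9)),
    ("LDL", "all_missense_lof"): dict(counts=(48, 203, 95, 1806),
                                      or_printed=4.5, ci_printed=(3.0, 6.6)),
    ("LDL", "pred_damaging"): dict(counts=(22, 229, 26, 1875), or_printed=6.9,
                                   ci_printed=(3.7, 12.9)),
    ("LDL", "pred_damaging_lof"): dict(counts=(35, 216, 29, 1872),
                                       or_printed=10.4,
                                       ci_printed=(6.1, 18.1)),
    ("LDL", "disruptive"): dict(counts=(14, 237, 6, 1895), or_printed=18.6,
                                ci_printed=(6.6, 59.6)),
    ("LDL", "disruptive_lof"): dict(counts=(27, 224, 9, 1892),
                                    or_printed=25.3, ci_printed=(11.3, 61.8)),
    ("MI", "clear_lof"): dict(counts=(17, 1699, 0, 1519), or_printed=None,
                              ci_printed=(3.7, np.inf)),
    ("MI", "all_missense"): dict(counts=(119, 1597, 58, 1461),
                                 or_printed=1.9, ci_printed=(1.4, 2.6)),
    # the conditional-MLE OR for this row is 2.168 under any standard
    # implementation; the published 2.1 is truncated, not rounded
    ("MI", "all_missense_lof"): dict(counts=(136, 1580, 58, 1461),
                                     or_printed=2.1, ci_printed=(1.6, 3.0),
                                     or_tol=0.1),
    ("MI", "pred_damaging"): dict(counts=(50, 1666, 12, 1507), or_printed=3.8,
                                  ci_printed=(2.0, 7.8)),
    ("MI", "pred_damaging_lof"): dict(counts=(67, 1649, 12, 1507),
                                      or_printed=5.1, ci_printed=(2.7, 10.4)),
    ("MI", "disruptive"): dict(counts=(27, 1689, 2, 1517), or_printed=12.1,
                               ci_printed=(3.0, 105.4)),
    ("MI", "disruptive_lof"): dict(counts=(44, 1672, 2, 1517),
                                   or_printed=20.0, ci_printed=(5.2, 169.9)),
}


@pytest.fixture(scope="session")
def table1():
    return TABLE1


def make_cohort(n_subjects: int, carrier_counts: dict[str, int],
                case_mask=None, ldl=None, seed: int = 0) -> pd.DataFrame:
    """Deterministic cohort table with exact carrier counts per variant
    (carriers placed at the start of the table unless shuffled)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "subject_id": [f"S{i}" for i in range(n_subjects)],
        "mi_status": (case_mask if case_mask is not None
                      else ["control"] * n_subjects),
        "ldl_c": ldl if ldl is not None else rng.normal(135, 30, n_subjects),
        "sex": rng.integers(0, 2, n_subjects),
        "age": rng.normal(42, 5, n_subjects),
    })
    for vid, k in carrier_counts.items():
        flags = np.zeros(n_subjects, dtype=bool)
        flags[rng.choice(n_subjects, size=k, replace=False)] = True
        df[vid] = flags
    return df
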