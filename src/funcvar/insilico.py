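"""Composite in-silico deleteriousness score from four prediction tools.

Each tool's categorical call is mapped to -1 / 0 / +1 and the four values
are summed; the sum is binned into likely_benign / unclear / likely_FH.
Sums of exactly -1 or +1 (reachable because PolyPhen-2 can contribute 0)
fall between the published cutpoints and are binned as unclear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

TOOL_VALUES: dict[str, dict[str, int]] = {
    "polyphen2": {"probably_damaging": -1, "possibly_damaging": 0, "benign": 1},
    "sift": {"damaging": -1, "tolerated": 1},
    "mutation_assessor": {"high": -1, "medium": -1, "low": 1, "neutral": 1},
    "mutation_taster": {"disease_causing": -1, "polymorphism": 1},
}

TOOLS = tuple(TOOL_VALUES)

LIKELY_BENIGN = "likely_benign"
UNCLEAR = "unclear"
LIKELY_FH = "likely_FH"


@dataclass(frozen=True)
class CompositeScore:
    score: int
    category: str
    n_tools: int


def categorize(score: int) -> str:
    if score > 1:
        return LIKELY_BENIGN
    if score < -1:
        return LIKELY_FH
    return UNCLEAR


def composite_score(calls: Mapping[str, Optional[str]]) -> CompositeScore:
    """Sum the mapped tool values and bin the total.

    ``calls`` maps tool name to its categorical call; a missing tool may
    be omitted or set to None and contributes 0.  At least one call must
    be present.
    """
    unknown = set(calls) - set(TOOL_VALUES)
    if unknown:
        raise ValueError(f"unknown prediction tools: {sorted(unknown)}")
    score = 0
    n_tools = 0
    for tool, call in calls.items():
        if call is None:
            continue
        mapping = TOOL_VALUES[tool]
        if call not in mapping:
            raise ValueError(f"unknown category {call!r} for tool {tool}")
        score += mapping[call]
        n_tools += 1
    if n_tools == 0:
        raise ValueError("no prediction-tool calls present")
    return CompositeScore(score=score, category=categorize(score), n_tools=n_tools)


def score_table(calls: pd.DataFrame) -> pd.DataFrame:
    """Score a per-variant table with columns variant_id + tool names."""
    rows = []
    for _, row in calls.iterrows():
        present = {t: row[t] for t in TOOLS
                   if t in calls.columns and pd.notna(row[t])}
        cs = composite_score(present)
        rows.append({"variant_id": row["variant_id"], "score": cs.score,
                     "category": cs.category, "n_tools": cs.n_tools})
    return pd.DataFrame(rows)
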