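"""Subjective-value scoring, intelligibility, composites, and exclusions.

The indifference point from each staircase is normalized into a subjective
value (SV) on [0, 2].  When the participant initially chose the low-effort
option (the hard task was discounted), SV = ip / base in [0, 1].  When they
initially chose the hard task (the easy task was discounted), SV =
1 + (base - ip) / base in [1, 2].  Values above 1 indicate a preference for
the harder task at equal pay; the two formulas agree (SV = 1) at ip = base.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .task_engine import HIGH, LOW, TitrationSeries

__all__ = [
    "SubjectiveValueRecord",
    "CompositeScores",
    "ExclusionReport",
    "indifference_to_sv",
    "score_series",
    "mean_sv",
    "keyword_intelligibility",
    "build_composites",
    "apply_exclusions",
]

N_CELLS_PER_DOMAIN = 9  # 3 loads x 3 amounts

SPAN_COLUMNS = ("lspan", "ospan", "symspan")
REWARD_COLUMNS = ("bas_total", "grapes_reward", "spsrq_reward")


@dataclass(frozen=True)
class SubjectiveValueRecord:
    participant_id: str
    domain: str
    load: int
    base_amount: float
    sv: float
    initial_choice: str

    def __post_init__(self):
        if not 0.0 <= self.sv <= 2.0:
            raise ValueError(f"sv out of [0, 2]: {self.sv}")
        if self.initial_choice not in (LOW, HIGH):
            raise ValueError("initial_choice must be 'low' or 'high'")


@dataclass(frozen=True)
class CompositeScores:
    """Per-participant summed z-score composites."""

    wm_capacity: pd.Series
    reward_sensitivity: pd.Series


@dataclass(frozen=True)
class ExclusionReport:
    flags: pd.DataFrame  # index participant_id; bool columns per flag
    counts: dict[str, int]
    retained_ids: tuple[str, ...]
    dropped: dict[str, tuple[str, ...]]  # id -> reasons

    @property
    def n_retained(self) -> int:
        return len(self.retained_ids)


def indifference_to_sv(
    indifference_point: float | Fraction,
    base_amount: float | Fraction,
    initial_choice: str,
) -> float:
    """Map a staircase endpoint to a subjective value on [0, 2]."""
    ip = float(indifference_point)
    base = float(base_amount)
    if base <= 0:
        raise ValueError("base_amount must be positive")
    if not 0.0 <= ip <= base:
        raise ValueError(
            f"indifference point {ip} outside [0, {base}]"
        )
    if initial_choice == LOW:
        return ip / base
    if initial_choice == HIGH:
        return 1.0 + (base - ip) / base
    raise ValueError("initial_choice must be 'low' or 'high'")


def score_series(series: TitrationSeries, participant_id: str) -> SubjectiveValueRecord:
    """Score one completed staircase into a subjective-value record."""
    cell = series.cell
    sv = indifference_to_sv(
        series.indifference_point, cell.base_amount, series.initial_choice
    )
    return SubjectiveValueRecord(
        participant_id=participant_id,
        domain=cell.domain,
        load=cell.load,
        base_amount=float(cell.base_amount),
        sv=sv,
        initial_choice=series.initial_choice,
    )


def mean_sv(records: pd.DataFrame | list[SubjectiveValueRecord]) -> float:
    """Average SV over the 9 load x amount cells of one participant x domain.

    Requires exactly one record per cell; missing or duplicate cells raise
    rather than silently imputing.
    """
    if isinstance(records, list):
        df = pd.DataFrame(
            {
                "load": [r.load for r in records],
                "base_amount": [r.base_amount for r in records],
                "sv": [r.sv for r in records],
            }
        )
    else:
        df = records
    cells = list(zip(df["load"], df["base_amount"]))
    if len(cells) != N_CELLS_PER_DOMAIN or len(set(cells)) != N_CELLS_PER_DOMAIN:
        raise ValueError(
            f"expected exactly {N_CELLS_PER_DOMAIN} unique load x amount "
            f"cells, got {len(cells)} rows ({len(set(cells))} unique)"
        )
    return float(df["sv"].mean())


_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


def _tokens(text: str) -> list[str]:
    return [
        t.translate(_PUNCT_TABLE)
        for t in re.split(r"\s+", text.lower().strip())
        if t.translate(_PUNCT_TABLE)
    ]


def keyword_intelligibility(typed_response: str, keywords: list[str]) -> float:
    """Proportion of the sentence's 4 key words typed correctly.

    Matching is case-insensitive, punctuation-stripped, order-free token
    equality; each keyword is credited at most once (a response token is
    consumed when it matches).
    """
    if not keywords:
        raise ValueError("keyword list is empty")
    if len(keywords) != 4:
        raise ValueError(f"expected exactly 4 keywords, got {len(keywords)}")
    response_tokens = _tokens(typed_response)
    hits = 0
    for kw in keywords:
        kw_norm = kw.lower().translate(_PUNCT_TABLE)
        if kw_norm in response_tokens:
            response_tokens.remove(kw_norm)
            hits += 1
    return hits / len(keywords)


def build_composites(participants: pd.DataFrame) -> CompositeScores:
    """Sum-of-z-score composites for WM capacity and reward sensitivity.

    z-scores use the mean/SD of the supplied (analyzed) sample, so run this
    after exclusions.  A zero-variance component is an error naming the
    offending column.
    """
    def z_sum(cols) -> pd.Series:
        total = pd.Series(0.0, index=participants.index)
        for col in cols:
            if col not in participants:
                raise KeyError(f"missing component column {col!r}")
            v = participants[col].astype(float)
            if v.isna().any():
                raise ValueError(f"missing values in component {col!r}")
            sd = v.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                raise ValueError(f"zero variance in component {col!r}")
            total = total + (v - v.mean()) / sd
        return total

    return CompositeScores(
        wm_capacity=z_sum(SPAN_COLUMNS),
        reward_sensitivity=z_sum(REWARD_COLUMNS),
    )


def apply_exclusions(
    participants: pd.DataFrame,
    mean_sv_by_participant: pd.Series | None = None,
    sensitivity_mode: str = "primary",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the study's exclusion rules.

    ``primary`` drops participants who reported not using headphones or who
    did not complete both discounting tasks.  ``drop_effort_seekers``
    additionally drops participants whose grand-mean SV across both domains
    exceeds 1 (a sensitivity re-analysis, never a default).
    """
    if sensitivity_mode not in ("primary", "drop_effort_seekers"):
        raise ValueError(f"unknown sensitivity_mode {sensitivity_mode!r}")
    df = participants.set_index("participant_id") if "participant_id" in participants else participants
    flags = pd.DataFrame(index=df.index)
    flags["no_headphones"] = df["no_headphones"].astype(bool)
    flags["incomplete_discounting"] = df["incomplete_discounting"].astype(bool)
    if mean_sv_by_participant is not None:
        grand = mean_sv_by_participant.reindex(df.index)
        flags["effort_seeker_mean_sv_gt_1"] = (grand > 1.0).fillna(False)
    else:
        flags["effort_seeker_mean_sv_gt_1"] = False

    drop = flags["no_headphones"] | flags["incomplete_discounting"]
    if sensitivity_mode == "drop_effort_seekers":
        drop = drop | flags["effort_seeker_mean_sv_gt_1"]

    dropped = {}
    for pid in df.index[drop]:
        reasons = tuple(c for c in flags.columns if flags.loc[pid, c])
        dropped[str(pid)] = reasons
    retained = df.loc[~drop].reset_index()
    report = ExclusionReport(
        flags=flags,
        counts={c: int(flags[c].sum()) for c in flags.columns},
        retained_ids=tuple(str(i) for i in df.index[~drop]),
        dropped=dropped,
    )
    assert report.n_retained + len(dropped) == len(df)
    return retained, report
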