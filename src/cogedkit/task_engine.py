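"""COG-ED decision phase: trial scheduling and the titration staircase.

A decision cell pairs a high-effort task level (index 1-3, i.e. 2/3/4-back
or -4/-8/-12 dB SNR) with a base monetary amount ($2/$3/$4).  On the first
trial both options pay the base amount; the option chosen there becomes the
*titrated* side.  Its offer is then adjusted with successively halved steps
(base/2, base/4, ...): down after each choice of the titrated option, up
otherwise, while the other side stays fixed at the base amount.  The
titrated offer after the final adjustment is the indifference point.

Offers are kept as exact :class:`fractions.Fraction` values so the staircase
arithmetic is free of float drift; they are rounded to cents only in the
CSV log layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "LOW",
    "HIGH",
    "DOMAINS",
    "OfferCell",
    "Trial",
    "TitrationSeries",
    "ReplayError",
    "schedule_trials",
    "run_titration",
    "replay_titration",
    "threshold_chooser",
]

LOW = "low"
HIGH = "high"
DOMAINS = ("working_memory", "speech")

#: SNR (dB) of the speech high-effort levels, indexed by load 1..3; baseline 0 dB
SNR_BY_LOAD = {1: -4, 2: -8, 3: -12}
#: N-back level of the working-memory high-effort levels; baseline 1-back
NBACK_BY_LOAD = {1: 2, 2: 3, 3: 4}

DEFAULT_AMOUNTS = (2, 3, 4)
DEFAULT_LOADS = (1, 2, 3)
DEFAULT_N_TRIALS = 5


@dataclass(frozen=True)
class OfferCell:
    """One load x amount decision cell in one domain."""

    domain: str
    load: int
    base_amount: Fraction

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.load not in (1, 2, 3):
            raise ValueError(f"load must be 1, 2 or 3, got {self.load}")
        base = Fraction(self.base_amount)
        if base <= 0:
            raise ValueError("base_amount must be positive")
        object.__setattr__(self, "base_amount", base)


@dataclass(frozen=True)
class Trial:
    offer_low: Fraction
    offer_high: Fraction
    choice: str  # LOW or HIGH

    def __post_init__(self):
        if self.choice not in (LOW, HIGH):
            raise ValueError(f"choice must be {LOW!r} or {HIGH!r}")
        if self.offer_low < 0 or self.offer_high < 0:
            raise ValueError("offers must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """A completed staircase for one cell."""

    cell: OfferCell
    trials: tuple[Trial, ...]
    titrated_side: str
    indifference_point: Fraction

    @property
    def initial_choice(self) -> str:
        return self.trials[0].choice


class ReplayError(ValueError):
    """A logged choice series violates the staircase schedule."""


def schedule_trials(
    loads: Sequence[int] = DEFAULT_LOADS,
    amounts: Sequence[int] = DEFAULT_AMOUNTS,
    rng: np.random.Generator | None = None,
    domain: str = "working_memory",
) -> list[OfferCell]:
    """Randomly interleave the load x amount cells of one domain.

    Each cell appears exactly once; with the default 3 loads x 3 amounts and
    5 choices per cell this yields the task's 45 decision trials per domain.
    """
    cells = [
        OfferCell(domain=domain, load=load, base_amount=Fraction(a))
        for load in loads
        for a in amounts
    ]
    keys = [(c.load, c.base_amount) for c in cells]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate load x amount cells in schedule")
    rng = rng or np.random.default_rng()
    order = rng.permutation(len(cells))
    return [cells[i] for i in order]


def run_titration(
    cell: OfferCell,
    chooser: Callable[[Fraction, Fraction], str],
    n_trials_per_cell: int = DEFAULT_N_TRIALS,
) -> TitrationSeries:
    """Run the staircase for one cell against a chooser callable.

    ``chooser(offer_low, offer_high)`` must return ``"low"`` or ``"high"``
    for any offer pair.  Trial 1 presents equal offers at the base amount;
    its choice fixes the titrated side.  Adjustment k (k = 1..n-1) has step
    ``base/2**k`` and is applied after the choice on trial k: the titrated
    offer moves down if the titrated option was just chosen, up otherwise.
    The last trial's choice is recorded (it is the trial used for incentive
    selection) but triggers no further adjustment.
    """
    if n_trials_per_cell < 2:
        raise ValueError("need at least 2 trials per cell")
    base = cell.base_amount
    trials: list[Trial] = []

    offer_low = offer_high = base
    try:
        first = chooser(offer_low, offer_high)
    except Exception as exc:  # give the caller the failing cell
        raise RuntimeError(f"chooser failed on {cell}") from exc
    trials.append(Trial(offer_low, offer_high, first))
    titrated = first

    titrated_offer = base
    for k in range(1, n_trials_per_cell):
        step = base / 2**k
        last_choice = trials[-1].choice
        if last_choice == titrated:
            titrated_offer -= step
        else:
            titrated_offer += step
        if titrated == LOW:
            offer_low, offer_high = titrated_offer, base
        else:
            offer_low, offer_high = base, titrated_offer
        # the choice on the final trial is recorded (it can be selected for
        # the incentive payout) but triggers no further adjustment
        try:
            choice = chooser(offer_low, offer_high)
        except Exception as exc:
            raise RuntimeError(f"chooser failed on {cell}") from exc
        trials.append(Trial(offer_low, offer_high, choice))

    assert 0 <= titrated_offer <= 2 * base
    return TitrationSeries(
        cell=cell,
        trials=tuple(trials),
        titrated_side=titrated,
        indifference_point=titrated_offer,
    )


def replay_titration(
    cell: OfferCell,
    logged_trials: Iterable[tuple[Fraction, Fraction, str]],
    n_trials_per_cell: int = DEFAULT_N_TRIALS,
) -> TitrationSeries:
    """Re-score a logged choice series, validating it against the schedule.

    The log must contain ``(offer_low, offer_high, choice)`` rows exactly as
    the staircase would have produced them for those choices; any deviation
    raises :class:`ReplayError` naming the offending trial (1-based).
    """
    logged = [
        (Fraction(lo), Fraction(hi), choice) for lo, hi, choice in logged_trials
    ]
    if not logged:
        raise ReplayError("no trials in log")
    if len(logged) != n_trials_per_cell:
        raise ReplayError(
            f"expected {n_trials_per_cell} trials, got {len(logged)}"
        )
    it = iter([choice for _, _, choice in logged])
    series = run_titration(cell, lambda lo, hi: next(it), n_trials_per_cell)
    for idx, (expected, got) in enumerate(zip(series.trials, logged), start=1):
        if (expected.offer_low, expected.offer_high) != (got[0], got[1]):
            raise ReplayError(
                f"trial {idx}: offers {float(got[0])}/{float(got[1])} violate "
                f"the step schedule (expected "
                f"{float(expected.offer_low)}/{float(expected.offer_high)})"
            )
    return series


def threshold_chooser(sv_true: float) -> Callable[[Fraction, Fraction], str]:
    """Deterministic agent valuing the hard option at ``sv_true * offer_high``.

    Picks the option with the larger subjective payoff; exact ties go to the
    low-effort option (conservative: never overstates effort seeking).
    """

    def choose(offer_low: Fraction, offer_high: Fraction) -> str:
        return HIGH if sv_true * float(offer_high) > float(offer_low) else LOW

    return choose
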