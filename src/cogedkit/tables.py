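"""CSV/JSON schemas shared by the synthetic generator and the pipeline.

Plain CSV with a versioned ``# schema:`` comment line; currency offers are
serialized as fixed-point decimal strings with enough digits to round-trip
the staircase's dyadic arithmetic exactly (base/2**k needs up to six
decimals for the configurable 6-trial staircase).
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import pandas as pd

from .synthetic_cohort import Cohort, TLX_SCALES
from .task_engine import DEFAULT_LOADS, DOMAINS

__all__ = [
    "SCHEMAS",
    "cohort_to_tables",
    "write_table",
    "read_table",
    "validate_tables",
    "format_offer",
    "parse_offer",
]

SCHEMA_VERSION = 1

SCHEMAS = {
    "participants": [
        "participant_id",
        "no_headphones",
        "incomplete_discounting",
        "lspan",
        "ospan",
        "symspan",
        "bas_total",
        "grapes_reward",
        "spsrq_reward",
        "ncs",
    ]
    + [f"hit_rate_{l}" for l in DEFAULT_LOADS]
    + [f"cr_rate_{l}" for l in DEFAULT_LOADS]
    + [f"mean_rt_{l}" for l in DEFAULT_LOADS]
    + [f"intelligibility_{l}" for l in DEFAULT_LOADS],
    "choices": [
        "participant_id",
        "domain",
        "load",
        "base_amount",
        "trial_index",
        "offer_low",
        "offer_high",
        "choice",
    ],
    "ratings": ["participant_id", "domain", "level"] + list(TLX_SCALES),
    "truth": [
        "participant_id",
        "domain",
        "load",
        "base_amount",
        "sv_true",
        "g",
        "u_wm",
        "u_speech",
        "capacity",
        "reward_sens",
        "effort_seeker",
    ],
    "sv_scores": [
        "participant_id",
        "domain",
        "load",
        "base_amount",
        "sv",
        "initial_choice",
    ],
}


def format_offer(x) -> str:
    return f"{float(x):.6f}"


def parse_offer(s) -> Fraction:
    return Fraction(str(s))


def cohort_to_tables(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Flatten a cohort into the pipeline's table schemas."""
    part_rows, choice_rows, rating_rows, truth_rows = [], [], [], []
    for p in cohort.participants:
        row = {
            "participant_id": p.participant_id,
            "no_headphones": p.no_headphones,
            "incomplete_discounting": p.incomplete_discounting,
            **p.spans,
            **p.questionnaires,
        }
        for _, perf in p.performance.iterrows():
            l = int(perf["load"])
            row[f"hit_rate_{l}"] = perf["hit_rate"]
            row[f"cr_rate_{l}"] = perf["cr_rate"]
            row[f"mean_rt_{l}"] = perf["mean_rt"]
            row[f"intelligibility_{l}"] = perf["intelligibility"]
        part_rows.append(row)

        for series in p.titrations:
            for t_idx, trial in enumerate(series.trials, start=1):
                choice_rows.append(
                    {
                        "participant_id": p.participant_id,
                        "domain": series.cell.domain,
                        "load": series.cell.load,
                        "base_amount": int(series.cell.base_amount),
                        "trial_index": t_idx,
                        "offer_low": format_offer(trial.offer_low),
                        "offer_high": format_offer(trial.offer_high),
                        "choice": trial.choice,
                    }
                )

        for _, r in p.ratings.iterrows():
            rating_rows.append(
                {
                    "participant_id": p.participant_id,
                    "domain": r["domain"],
                    "level": int(r["level"]),
                    **{s: r[s] for s in TLX_SCALES},
                }
            )

        for (domain, load, amount), sv in sorted(p.true_sv.values.items()):
            truth_rows.append(
                {
                    "participant_id": p.participant_id,
                    "domain": domain,
                    "load": load,
                    "base_amount": amount,
                    "sv_true": sv,
                    "g": p.latent.g,
                    "u_wm": p.latent.u_wm,
                    "u_speech": p.latent.u_speech,
                    "capacity": p.latent.capacity,
                    "reward_sens": p.latent.reward_sens,
                    "effort_seeker": p.latent.effort_seeker,
                }
            )

    return {
        "participants": pd.DataFrame(part_rows)[SCHEMAS["participants"]],
        "choices": pd.DataFrame(choice_rows)[SCHEMAS["choices"]],
        "ratings": pd.DataFrame(rating_rows)[SCHEMAS["ratings"]],
        "truth": pd.DataFrame(truth_rows)[SCHEMAS["truth"]],
    }


def write_table(df: pd.DataFrame, name: str, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: cogedkit/{name} v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, name: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"participant_id": str})
    if name is not None:
        missing = [c for c in SCHEMAS[name] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns for {name!r}: {missing}")
    return df


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _check_range(df, col, lo, hi, fname, violations):
    bad = df.index[(df[col] < lo) | (df[col] > hi)]
    for idx in bad:
        violations.append(
            f"{fname}: row {idx}: column {col!r} value {df.loc[idx, col]} "
            f"outside [{lo}, {hi}]"
        )


def validate_tables(tables: dict[str, pd.DataFrame]) -> list[str]:
    """Collect schema/range/consistency violations (non-fatal, aggregated)."""
    violations: list[str] = []
    for name, df in tables.items():
        if name not in SCHEMAS:
            violations.append(f"unknown table {name!r}")
            continue
        missing = [c for c in SCHEMAS[name] if c not in df.columns]
        if missing:
            violations.append(f"{name}.csv: missing columns {missing}")

    parts = tables.get("participants")
    choices = tables.get("choices")
    ratings = tables.get("ratings")
    scores = tables.get("sv_scores")

    if choices is not None and not choices.empty:
        _check_range(choices, "load", 1, 3, "choices.csv", violations)
        bad = choices.index[~choices["base_amount"].isin([2, 3, 4])]
        for idx in bad:
            violations.append(
                f"choices.csv: row {idx}: base_amount "
                f"{choices.loc[idx, 'base_amount']} not in {{2, 3, 4}}"
            )
        bad = choices.index[~choices["domain"].isin(DOMAINS)]
        for idx in bad:
            violations.append(
                f"choices.csv: row {idx}: unknown domain "
                f"{choices.loc[idx, 'domain']!r}"
            )
        bad = choices.index[~choices["choice"].isin(["low", "high"])]
        for idx in bad:
            violations.append(f"choices.csv: row {idx}: invalid choice value")
    if ratings is not None and not ratings.empty:
        for scale in TLX_SCALES:
            if scale in ratings:
                _check_range(ratings, scale, 1, 21, "ratings.csv", violations)
        _check_range(ratings, "level", 0, 3, "ratings.csv", violations)
    if scores is not None and not scores.empty:
        _check_range(scores, "sv", 0.0, 2.0, "sv_scores.csv", violations)
    if parts is not None:
        for col in [f"hit_rate_{l}" for l in DEFAULT_LOADS] + [
            f"intelligibility_{l}" for l in DEFAULT_LOADS
        ]:
            if col in parts:
                _check_range(parts, col, 0.0, 1.0, "participants.csv", violations)
        known = set(parts["participant_id"])
        for name, df in (("choices", choices), ("ratings", ratings)):
            if df is not None and not df.empty:
                unknown = sorted(set(df["participant_id"]) - known)
                for pid in unknown:
                    violations.append(
                        f"{name}.csv: participant {pid!r} missing from "
                        "participants.csv"
                    )
    return violations
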