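"""End-to-end analysis pipeline.

Stages: simulate (or ingest) -> score staircases into subjective values ->
exclusions -> pooled load x domain mixed model -> three-stage correlation
test of domain-general cognitive motivation (zero-order; residualized for
load and performance; partial, additionally controlling capacity and
reward-sensitivity composites) -> per-load domain contrasts -> workload-
rating models -> exploratory trait-questionnaire correlations.  Both the
primary sample and the effort-seeker sensitivity sample are always
analyzed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables as tbl
from .effort_models import (
    SPEECH_COVARIATES,
    WM_COVARIATES,
    ModelSpec,
    fit_mixed,
    fit_ratings_models,
    residualize_domain,
)
from .inference import (
    CorrelationPrior,
    CorrelationResult,
    bayes_correlation,
    bayes_partial_correlation,
    paired_t_bf,
)
from .scoring import apply_exclusions, build_composites, mean_sv
from .synthetic_cohort import CohortConfig, generate_cohort
from .task_engine import DEFAULT_LOADS, DOMAINS, OfferCell, replay_titration
from .scoring import score_series

__all__ = ["PipelineConfig", "run_pipeline", "score_choices"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``input_dir`` (directory with participants/choices/
    ratings CSVs) or ``cohort_config`` (simulate) must be provided.
    """

    cohort_config: CohortConfig | None = None
    input_dir: str | None = None
    output_dir: str | None = None
    prior: CorrelationPrior = field(default_factory=CorrelationPrior)
    subtract_random_intercept: bool = False
    run_design: bool = False
    seed: int = 0

    def __post_init__(self):
        if (self.cohort_config is None) == (self.input_dir is None):
            raise ValueError(
                "provide exactly one of cohort_config (simulate) or "
                "input_dir (ingest)"
            )

    def to_dict(self) -> dict:
        # note: output_dir is an execution detail, not analysis configuration,
        # so it is excluded to keep reports byte-identical across locations
        d = {
            "input_dir": self.input_dir,
            "prior": self.prior.describe(),
            "subtract_random_intercept": self.subtract_random_intercept,
            "run_design": self.run_design,
            "seed": self.seed,
        }
        if self.cohort_config is not None:
            cc = dataclasses.asdict(self.cohort_config)
            d["cohort_config"] = {
                k: v for k, v in cc.items() if not k.startswith("_")
            }
        return d


def score_choices(choices: pd.DataFrame, n_trials_per_cell: int = 5) -> pd.DataFrame:
    """Replay every logged staircase and score it into an SV table.

    Each (participant, domain, load, base_amount) cell is validated
    against the staircase schedule during replay; tampered logs raise.
    """
    rows = []
    grouped = choices.groupby(
        ["participant_id", "domain", "load", "base_amount"], sort=True
    )
    for (pid, domain, load, base), g in grouped:
        g = g.sort_values("trial_index")
        series = replay_titration(
            OfferCell(domain=domain, load=int(load), base_amount=int(base)),
            [
                (tbl.parse_offer(r.offer_low), tbl.parse_offer(r.offer_high), r.choice)
                for r in g.itertuples()
            ],
            n_trials_per_cell=n_trials_per_cell,
        )
        rec = score_series(series, pid)
        rows.append(
            {
                "participant_id": pid,
                "domain": domain,
                "load": int(load),
                "base_amount": float(base),
                "sv": rec.sv,
                "initial_choice": rec.initial_choice,
            }
        )
    return pd.DataFrame(rows)


def _mean_sv_table(sv_scores: pd.DataFrame) -> pd.DataFrame:
    """Per participant x domain mean SV (requires complete 9-cell grids)."""
    rows = []
    for (pid, domain), g in sv_scores.groupby(["participant_id", "domain"]):
        rows.append(
            {
                "participant_id": pid,
                "domain": domain,
                "mean_sv": mean_sv(g[["load", "base_amount", "sv"]]),
            }
        )
    return pd.DataFrame(rows)


def _performance_long(participants: pd.DataFrame) -> pd.DataFrame:
    """Wide per-load performance columns -> long (participant, load) rows."""
    rows = []
    for r in participants.itertuples():
        for load in DEFAULT_LOADS:
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "load": load,
                    "hit_rate": getattr(r, f"hit_rate_{load}"),
                    "cr_rate": getattr(r, f"cr_rate_{load}"),
                    "mean_rt": getattr(r, f"mean_rt_{load}"),
                    "intelligibility": getattr(r, f"intelligibility_{load}"),
                }
            )
    return pd.DataFrame(rows)


def _corr_dict(res: CorrelationResult) -> dict:
    return {
        "r_median": round(res.r_median, 6),
        "ci95": [round(res.ci95[0], 6), round(res.ci95[1], 6)],
        "bf10": round(res.bf10, 6),
        "n": res.n_effective,
        "r_observed": round(res.r_observed, 6),
        "prior": res.prior,
    }


def _fit_dict(fit) -> dict:
    return {
        "fixed_effects": {
            name: {
                "estimate": round(fe.estimate, 6),
                "sd": round(fe.sd, 6),
                "ci95": [round(fe.ci95[0], 6), round(fe.ci95[1], 6)],
            }
            for name, fe in fit.fixed_effects.items()
        },
        "random_intercept_var": round(fit.random_intercept_var, 6),
        "residual_var": round(fit.residual_var, 6),
        "r2": round(fit.r2, 6),
    }


def _three_stage(
    merged: pd.DataFrame,
    sv_scores: pd.DataFrame,
    participants: pd.DataFrame,
    perf_long: pd.DataFrame,
    prior: CorrelationPrior,
    subtract_random_intercept: bool,
) -> dict:
    """H1-H3 for one analysis sample, plus exploratory NCS correlations."""
    ids = list(participants["participant_id"])
    wide = merged.pivot(index="participant_id", columns="domain", values="mean_sv")
    wide = wide.loc[[i for i in ids if i in wide.index]]

    out: dict = {}
    h1 = bayes_correlation(
        wide["working_memory"].to_numpy(), wide["speech"].to_numpy(), prior=prior
    )
    out["h1_zero_order"] = _corr_dict(h1)

    # stage 2: residualize SV on load + performance within each domain
    resid_means = {}
    fits = {}
    scores = sv_scores[sv_scores["participant_id"].isin(wide.index)]
    for domain, covs in (
        ("working_memory", WM_COVARIATES),
        ("speech", SPEECH_COVARIATES),
    ):
        df = scores[scores["domain"] == domain].merge(
            perf_long, on=["participant_id", "load"], how="left"
        )
        means, fit = residualize_domain(
            df,
            covariates=covs,
            subtract_random_intercept=subtract_random_intercept,
        )
        resid_means[domain] = means
        fits[domain] = fit
    resid = pd.DataFrame(resid_means).loc[wide.index]
    h2 = bayes_correlation(
        resid["working_memory"].to_numpy(), resid["speech"].to_numpy(), prior=prior
    )
    out["h2_residualized"] = _corr_dict(h2)
    out["sv_models"] = {d: _fit_dict(f) for d, f in fits.items()}

    # stage 3: partial correlation controlling the trait composites
    comp = build_composites(participants.set_index("participant_id").loc[wide.index])
    covariates = np.column_stack(
        [comp.wm_capacity.to_numpy(), comp.reward_sensitivity.to_numpy()]
    )
    h3 = bayes_partial_correlation(
        resid["working_memory"].to_numpy(),
        resid["speech"].to_numpy(),
        covariates,
        prior=prior,
    )
    out["h3_partial"] = _corr_dict(h3)
    out["composite_correlations"] = {
        "capacity_vs_reward": _corr_dict(
            bayes_correlation(
                comp.wm_capacity.to_numpy(),
                comp.reward_sensitivity.to_numpy(),
                prior=prior,
            )
        ),
        **{
            f"capacity_vs_sv_{d}": _corr_dict(
                bayes_correlation(
                    comp.wm_capacity.to_numpy(), wide[d].to_numpy(), prior=prior
                )
            )
            for d in DOMAINS
        },
        **{
            f"reward_vs_sv_{d}": _corr_dict(
                bayes_correlation(
                    comp.reward_sensitivity.to_numpy(),
                    wide[d].to_numpy(),
                    prior=prior,
                )
            )
            for d in DOMAINS
        },
    }

    # per-load paired domain contrasts (wm - speech), averaged over amounts
    per_load = scores.groupby(["participant_id", "domain", "load"])["sv"].mean()
    contrasts = {}
    for load in DEFAULT_LOADS:
        wm = per_load.xs(("working_memory", load), level=("domain", "load"))
        sp = per_load.xs(("speech", load), level=("domain", "load"))
        common = wm.index.intersection(sp.index)
        res = paired_t_bf((wm.loc[common] - sp.loc[common]).to_numpy())
        contrasts[f"load_{load}"] = {
            "t": round(res.t_statistic, 6),
            "df": res.df,
            "mean_diff": round(res.mean_diff, 6),
            "ci95": [round(res.ci95[0], 6), round(res.ci95[1], 6)],
            "bf10": round(res.bf10, 6),
        }
    out["domain_contrasts"] = contrasts

    # exploratory: NCS vs behavioral cognitive motivation
    ncs = participants.set_index("participant_id").loc[wide.index, "ncs"].astype(float)
    grand = wide.mean(axis=1)
    out["ncs_exploratory"] = {
        "ncs_vs_sv_working_memory": _corr_dict(
            bayes_correlation(ncs.to_numpy(), wide["working_memory"].to_numpy(), prior=prior)
        ),
        "ncs_vs_sv_speech": _corr_dict(
            bayes_correlation(ncs.to_numpy(), wide["speech"].to_numpy(), prior=prior)
        ),
        "ncs_vs_sv_composite": _corr_dict(
            bayes_correlation(ncs.to_numpy(), grand.to_numpy(), prior=prior)
        ),
        "ncs_vs_residual_working_memory": _corr_dict(
            bayes_correlation(ncs.to_numpy(), resid["working_memory"].to_numpy(), prior=prior)
        ),
        "ncs_vs_residual_speech": _corr_dict(
            bayes_correlation(ncs.to_numpy(), resid["speech"].to_numpy(), prior=prior)
        ),
    }
    out["n"] = int(len(wide))
    out["residual_means"] = {
        d: {pid: round(v, 6) for pid, v in resid[d].items()} for d in DOMAINS
    }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and (optionally) write artifacts to disk."""
    if config.cohort_config is not None:
        cohort = generate_cohort(config.cohort_config)
        data = tbl.cohort_to_tables(cohort)
    else:
        base = Path(config.input_dir)
        data = {
            name: tbl.read_table(base / f"{name}.csv", name)
            for name in ("participants", "choices", "ratings")
        }

    violations = tbl.validate_tables(
        {k: v for k, v in data.items() if k in ("participants", "choices", "ratings")}
    )
    if violations:
        raise ValueError("input validation failed:\n" + "\n".join(violations))

    participants = data["participants"]
    sv_scores = score_choices(data["choices"])
    data["sv_scores"] = sv_scores

    # grand-mean SV per participant (for the effort-seeker sensitivity flag);
    # computable only for participants with complete grids
    complete_means = _mean_sv_table(
        sv_scores.groupby(["participant_id", "domain"])
        .filter(lambda g: len(g) == 9)
    )
    grand_mean = complete_means.groupby("participant_id")["mean_sv"].mean()

    report: dict = {
        "seed": config.seed,
        "config": config.to_dict(),
        "n_input": int(len(participants)),
    }

    samples = {}
    for mode in ("primary", "drop_effort_seekers"):
        retained, excl = apply_exclusions(
            participants, mean_sv_by_participant=grand_mean, sensitivity_mode=mode
        )
        ids = set(retained["participant_id"])
        scores_m = sv_scores[sv_scores["participant_id"].isin(ids)]
        merged = _mean_sv_table(scores_m)
        perf_long = _performance_long(retained)
        block = _three_stage(
            merged,
            scores_m,
            retained,
            perf_long,
            config.prior,
            config.subtract_random_intercept,
        )
        block["exclusions"] = {
            "counts": excl.counts,
            "n_retained": excl.n_retained,
            "dropped": {k: list(v) for k, v in excl.dropped.items()},
        }
        samples[mode] = block
    report["primary"] = samples["primary"]
    report["sensitivity_no_effort_seekers"] = samples["drop_effort_seekers"]

    # pooled two-domain model (load, domain, interaction) on the primary sample
    primary_ids = set(samples["primary"]["residual_means"]["working_memory"])
    pooled = sv_scores[sv_scores["participant_id"].isin(primary_ids)]
    pooled_fit = fit_mixed(
        ModelSpec(outcome="sv", fixed_effects=("load", "domain", "load:domain")),
        pooled,
    )
    report["pooled_sv_model"] = _fit_dict(pooled_fit)

    # workload-rating models on the primary sample
    ratings = data["ratings"]
    ratings_m = ratings[ratings["participant_id"].isin(primary_ids)]
    report["tlx_models"] = {
        scale: _fit_dict(fit)
        for scale, fit in fit_ratings_models(ratings_m).items()
    }

    if config.run_design:
        from .design import reproduction_config, simulate_sequential

        res = simulate_sequential(reproduction_config(seed=config.seed))
        report["design"] = res.summary()

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("participants", "choices", "ratings"):
            tbl.write_table(data[name], name, out / f"{name}.csv")
        if "truth" in data:
            tbl.write_table(data["truth"], "truth", out / "truth.csv")
        tbl.write_table(sv_scores, "sv_scores", out / "sv_scores.csv")
        resid_rows = []
        for domain, vals in samples["primary"]["residual_means"].items():
            for pid, v in vals.items():
                resid_rows.append(
                    {"participant_id": pid, "domain": domain, "mean_residual": v}
                )
        pd.DataFrame(resid_rows).to_csv(out / "residuals.csv", index=False)
        with open(out / "exclusions.json", "w") as fh:
            json.dump(
                {
                    mode: samples[m]["exclusions"]
                    for mode, m in (
                        ("primary", "primary"),
                        ("drop_effort_seekers", "drop_effort_seekers"),
                    )
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        with open(out / "model_fits.json", "w") as fh:
            json.dump(
                {
                    "pooled_sv_model": report["pooled_sv_model"],
                    "tlx_models": report["tlx_models"],
                    "sv_models_primary": samples["primary"]["sv_models"],
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        with open(out / "analysis_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
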