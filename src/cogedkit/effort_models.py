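"""Random-intercept mixed models of subjective value and workload ratings.

Linear mixed models are fit by REML through statsmodels' ``MixedLM``; the
original analyses fit the same models in a Bayesian framework with flat
priors, which the authors of that framework themselves describe as
ML-equivalent, so REML point estimates with Gaussian 95% intervals are the
reference implementation here (deterministic and fast).

The residuals exposed by :func:`residualize_domain` subtract only the
fixed-effect prediction — the participant's random intercept is *not*
removed.  Subtracting it would delete exactly the stable between-person
variance that the cross-domain correlation analyses are designed to
detect; with fixed-effects-only residuals that trait variance survives
into the per-participant averaged residual.  The alternative reading is
available via ``subtract_random_intercept=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_mixed",
    "residualize_domain",
    "fit_ratings_models",
    "WM_COVARIATES",
    "SPEECH_COVARIATES",
]

WM_COVARIATES = ("hit_rate", "cr_rate", "mean_rt")
SPEECH_COVARIATES = ("intelligibility",)

_ALLOWED_EFFECTS = {
    "load",
    "domain",
    "load:domain",
    "hit_rate",
    "cr_rate",
    "mean_rt",
    "intelligibility",
}


@dataclass(frozen=True)
class ModelSpec:
    """A random-intercept model: outcome ~ fixed effects + (1 | participant).

    Load is coded numerically (low = 0, medium = 1, high = 2) so a single
    coefficient captures the graded load effect; domain is an indicator
    (0 = working memory, 1 = speech).
    """

    outcome: str
    fixed_effects: tuple[str, ...]
    group: str = "participant_id"

    def __post_init__(self):
        bad = set(self.fixed_effects) - _ALLOWED_EFFECTS
        if bad:
            raise ValueError(f"unknown fixed effects: {sorted(bad)}")


@dataclass(frozen=True)
class FixedEffect:
    name: str
    estimate: float
    sd: float
    ci95: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.ci95
        # a degenerate (zero-residual-variance) fit has no finite interval
        if np.isfinite(lo) and np.isfinite(hi):
            if not lo <= self.estimate <= hi:
                raise ValueError("interval must contain the estimate")


@dataclass(frozen=True)
class ModelFit:
    spec: ModelSpec
    fixed_effects: dict[str, FixedEffect]
    random_intercept_var: float
    residual_var: float
    residuals_fixed: pd.Series  # observed - fixed-effect prediction
    residuals_full: pd.Series  # observed - (fixed + random intercept)
    fitted_fixed: pd.Series
    r2: float
    groups: pd.Series

    def coef(self, name: str) -> float:
        return self.fixed_effects[name].estimate


def _design_matrix(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    cols = {"const": np.ones(len(data))}
    def col(name):
        if name not in data:
            raise KeyError(f"column {name!r} required by the model is missing")
        return data[name].to_numpy(dtype=float)

    for eff in spec.fixed_effects:
        if eff == "load":
            cols["load"] = col("load") - 1.0  # levels 1..3 -> 0..2
        elif eff == "domain":
            cols["domain"] = (data["domain"] == "speech").to_numpy(dtype=float)
        elif eff == "load:domain":
            cols["load:domain"] = (col("load") - 1.0) * (
                (data["domain"] == "speech").to_numpy(dtype=float)
            )
        else:
            cols[eff] = col(eff)
    return pd.DataFrame(cols, index=data.index)


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns by greedy elimination
        kept = [0]
        dependent = []
        M = X.to_numpy()
        for j in range(1, M.shape[1]):
            cand = M[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept):
                dependent.append(X.columns[j])
            else:
                kept.append(j)
        raise ValueError(f"singular design; collinear columns: {dependent}")


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a random-intercept linear mixed model by REML.

    Estimates are invariant to row order; a singular fixed-effect design or
    a zero-variance outcome is an error.
    """
    if spec.outcome not in data:
        raise KeyError(f"outcome column {spec.outcome!r} missing")
    original_index = data.index
    # group-contiguous order for the solver; results are re-aligned below
    data = data.sort_values([spec.group], kind="stable")
    y = data[spec.outcome].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {spec.outcome!r} has zero variance")
    counts = data.groupby(spec.group).size()
    if (counts < 2).any():
        raise ValueError(
            "each participant needs at least 2 observations; offenders: "
            f"{list(counts.index[counts < 2])[:5]}"
        )
    X = _design_matrix(spec, data)
    if X.isna().to_numpy().any():
        raise ValueError("missing values in covariates")
    _check_design(X)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X.to_numpy(), groups=data[spec.group].to_numpy())
        try:
            result = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError:
            result = model.fit(reml=True, method="nm")

    names = list(X.columns)
    k = len(names)
    params = np.asarray(result.fe_params)[:k]
    bse = np.asarray(result.bse_fe)[:k]
    fixed = {}
    for j, name in enumerate(names):
        est, sd = float(params[j]), float(bse[j])
        fixed[name] = FixedEffect(
            name=name,
            estimate=est,
            sd=sd,
            ci95=(est - 1.96 * sd, est + 1.96 * sd),
        )
    re_var = float(np.asarray(result.cov_re)[0, 0])
    sigma2 = float(result.scale)

    fitted_fixed = pd.Series(X.to_numpy() @ params, index=data.index)
    resid_fixed = pd.Series(y, index=data.index) - fitted_fixed
    # empirical Bayes (BLUP) random intercepts
    blups = {g: float(np.asarray(v)[0]) for g, v in result.random_effects.items()}
    b = data[spec.group].map(blups).to_numpy(dtype=float)
    resid_full = pd.Series(y - (fitted_fixed.to_numpy() + b), index=data.index)

    pred = fitted_fixed.to_numpy() + b
    var_pred = float(np.var(pred))
    r2 = var_pred / (var_pred + float(np.var(resid_full)))

    # re-align all per-observation series with the caller's row order
    fitted_fixed = fitted_fixed.loc[original_index]
    resid_fixed = resid_fixed.loc[original_index]
    resid_full = resid_full.loc[original_index]
    groups_out = data[spec.group].loc[original_index]

    return ModelFit(
        spec=spec,
        fixed_effects=fixed,
        random_intercept_var=re_var,
        residual_var=sigma2,
        residuals_fixed=resid_fixed,
        residuals_full=resid_full,
        fitted_fixed=fitted_fixed,
        r2=r2,
        groups=groups_out,
    )


def residualize_domain(
    data: pd.DataFrame,
    covariates: tuple[str, ...],
    outcome: str = "sv",
    subtract_random_intercept: bool = False,
) -> tuple[pd.Series, ModelFit]:
    """Per-participant mean residual after removing load/performance effects.

    Fits ``outcome ~ load + covariates + (1 | participant)`` on one
    domain's data and averages the residuals within participant.  By
    default the residual keeps the participant's random intercept (see
    module docstring); ``subtract_random_intercept=True`` gives the
    alternative reading.
    """
    spec = ModelSpec(outcome=outcome, fixed_effects=("load",) + tuple(covariates))
    fit = fit_mixed(spec, data)
    resid = fit.residuals_full if subtract_random_intercept else fit.residuals_fixed
    means = resid.groupby(fit.groups.to_numpy()).mean()
    means.index.name = "participant_id"
    return means, fit


def fit_ratings_models(
    ratings: pd.DataFrame,
    scales: tuple[str, ...] = ("mental_demand", "effort", "frustration"),
) -> dict[str, ModelFit]:
    """Mixed models of workload ratings: scale ~ load + domain + (1 | id).

    Ratings must lie on the 1-21 visual-analog scale.  The ``level``
    column (0 = baseline .. 3 = hardest) is renamed to the model's load
    coding.
    """
    df = ratings.copy()
    if "level" in df and "load" not in df:
        df["load"] = df["level"] + 1  # _design_matrix subtracts 1
    fits = {}
    for scale in scales:
        if scale not in df:
            raise KeyError(f"ratings table lacks scale {scale!r}")
        vals = df[scale].astype(float)
        if ((vals < 1) | (vals > 21)).any():
            raise ValueError(f"{scale}: ratings outside the 1-21 scale")
        spec = ModelSpec(outcome=scale, fixed_effects=("load", "domain"))
        fits[scale] = fit_mixed(spec, df)
    return fits
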