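"""Mixed models of subjective value and ratings, and residual extraction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from cogedkit.effort_models import (
    ModelSpec,
    fit_mixed,
    fit_ratings_models,
    residualize_domain,
)


def simulate_sv(
    n_participants=100,
    load_slope=-0.09,
    subject_sd=0.25,
    noise_sd=0.1,
    seed=0,
    hit_effect=0.0,
):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        u = rng.normal(0, subject_sd)
        hits = rng.uniform(0.5, 1.0, size=3)
        for load in (1, 2, 3):
            for amount in (2, 3, 4):
                sv = (
                    0.8
                    + load_slope * (load - 1)
                    + u
                    + hit_effect * hits[load - 1]
                    + rng.normal(0, noise_sd)
                )
                rows.append(
                    {
                        "participant_id": f"p{i}",
                        "domain": "working_memory",
                        "load": load,
                        "hit_rate": hits[load - 1],
                        "cr_rate": rng.uniform(0.8, 1.0),
                        "mean_rt": rng.normal(600, 50),
                        "sv": sv,
                    }
                )
    return pd.DataFrame(rows)


class TestFitMixed:
    def test_recovers_load_slope_with_coverage(self):
        """The 95% interval covers a simulated load slope in >=90% of fits."""
        hits = 0
        for rep in range(100):
            df = simulate_sv(n_participants=60, seed=rep, noise_sd=0.12)
            fit = fit_mixed(ModelSpec(outcome="sv", fixed_effects=("load",)), df)
            lo, hi = fit.fixed_effects["load"].ci95
            if lo <= -0.09 <= hi:
                hits += 1
        assert hits >= 90

    def test_zero_variance_outcome_rejected(self):
        df = simulate_sv(n_participants=5)
        df["sv"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_mixed(ModelSpec(outcome="sv", fixed_effects=("load",)), df)

    def test_no_trait_variance_matches_ols_oracle(self):
        df = simulate_sv(n_participants=80, subject_sd=0.0, seed=4)
        fit = fit_mixed(ModelSpec(outcome="sv", fixed_effects=("load",)), df)
        X = sm.add_constant((df["load"] - 1).to_numpy())
        ols = sm.OLS(df["sv"].to_numpy(), X).fit()
        assert fit.random_intercept_var < 5e-3
        assert fit.fixed_effects["const"].estimate == pytest.approx(ols.params[0], abs=1e-3)
        assert fit.fixed_effects["load"].estimate == pytest.approx(ols.params[1], abs=1e-3)

    def test_row_order_invariance(self):
        df = simulate_sv(n_participants=30, seed=9)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = fit_mixed(ModelSpec(outcome="sv", fixed_effects=("load",)), df)
        b = fit_mixed(ModelSpec(outcome="sv", fixed_effects=("load",)), shuffled)
        assert a.fixed_effects["load"].estimate == pytest.approx(
            b.fixed_effects["load"].estimate, abs=1e-8
        )

    def test_singular_design_names_columns(self):
        df = simulate_sv(n_participants=20, seed=2)
        df["cr_rate"] = 2.0 * df["hit_rate"]  # exact collinearity
        with pytest.raises(ValueError, match="cr_rate"):
            fit_mixed(
                ModelSpec(outcome="sv", fixed_effects=("load", "hit_rate", "cr_rate")),
                df,
            )

    def test_r2_bounded_and_interval_contains_estimate(self):
        df = simulate_sv(n_participants=40, seed=3)
        fit = fit_mixed(ModelSpec(outcome="sv", fixed_effects=("load", "hit_rate")), df)
        assert 0.0 <= fit.r2 <= 1.0
        for fe in fit.fixed_effects.values():
            assert fe.ci95[0] <= fe.estimate <= fe.ci95[1]
        assert abs(fit.residuals_fixed.mean()) < 1e-6


class TestResidualize:
    def test_unrelated_covariates_preserve_centered_subject_means(self):
        df = simulate_sv(n_participants=150, seed=5, hit_effect=0.0)
        means, _ = residualize_domain(df, covariates=("hit_rate", "cr_rate", "mean_rt"))
        raw = df.groupby("participant_id")["sv"].mean()
        raw = raw - raw.mean()
        aligned = means.loc[raw.index]
        assert np.corrcoef(aligned, raw)[0, 1] > 0.95

    def test_perfect_linear_fit_leaves_zero_residuals(self):
        rows = []
        for i in range(20):
            for load in (1, 2, 3):
                for amount in (2, 3, 4):
                    rows.append(
                        {
                            "participant_id": f"p{i}",
                            "load": load,
                            "sv": 1.0 - 0.2 * (load - 1),
                        }
                    )
        df = pd.DataFrame(rows)
        means, fit = residualize_domain(df, covariates=())
        assert np.allclose(means.to_numpy(), 0.0, atol=1e-8)

    def test_idempotent_on_subject_means(self):
        df = simulate_sv(n_participants=60, seed=6, hit_effect=0.3)
        means1, fit1 = residualize_domain(df, covariates=("hit_rate",))
        df2 = df.copy()
        df2["sv"] = fit1.residuals_fixed.to_numpy()
        means2, _ = residualize_domain(df2, covariates=("hit_rate",))
        diff = (means2.loc[means1.index] - means1).abs().max()
        assert diff < 1e-6

    def test_cross_domain_trait_correlation_survives_covariate_control(self):
        """Residualizing on performance keeps the shared trait signal."""
        rng = np.random.default_rng(12)
        rho, n = 0.5, 300
        u1 = rng.normal(size=n)
        u2 = rho * u1 + np.sqrt(1 - rho * rho) * rng.normal(size=n)
        frames = {}
        for domain, u in (("working_memory", u1), ("speech", u2)):
            rows = []
            for i in range(n):
                hits = rng.uniform(0.4, 1.0, size=3)
                for load in (1, 2, 3):
                    for amount in (2, 3, 4):
                        sv = (
                            0.8
                            - 0.1 * (load - 1)
                            + 0.25 * u[i]
                            + 0.3 * hits[load - 1]  # performance influences sv
                            + rng.normal(0, 0.12)
                        )
                        rows.append(
                            {
                                "participant_id": f"p{i:04d}",
                                "load": load,
                                "hit_rate": hits[load - 1],
                                "sv": sv,
                            }
                        )
            frames[domain] = pd.DataFrame(rows)
        m1, _ = residualize_domain(frames["working_memory"], covariates=("hit_rate",))
        m2, _ = residualize_domain(frames["speech"], covariates=("hit_rate",))
        r = np.corrcoef(m1.to_numpy(), m2.loc[m1.index].to_numpy())[0, 1]
        assert r == pytest.approx(rho, abs=0.1)


class TestRatingsModels:
    @staticmethod
    def ratings(n=60, load_slope=3.0, domain_offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n):
            subj = rng.normal(0, 2)
            for domain in ("working_memory", "speech"):
                for level in range(4):
                    base = 6 + load_slope * level + subj + rng.normal(0, 2)
                    if domain == "speech":
                        base += domain_offset
                    rows.append(
                        {
                            "participant_id": f"p{i}",
                            "domain": domain,
                            "level": level,
                            "mental_demand": float(np.clip(base, 1, 21)),
                            "effort": float(np.clip(base - 1, 1, 21)),
                            "frustration": float(np.clip(base - 3, 1, 21)),
                        }
                    )
        return pd.DataFrame(rows)

    def test_increasing_load_gives_positive_slope_excluding_zero(self):
        fits = fit_ratings_models(self.ratings(load_slope=3.0, seed=1))
        fe = fits["mental_demand"].fixed_effects["load"]
        assert fe.estimate > 0
        assert fe.ci95[0] > 0

    def test_constant_ratings_rejected(self):
        df = self.ratings(n=10, seed=2)
        df["effort"] = 10.0
        with pytest.raises(ValueError, match="zero variance"):
            fit_ratings_models(df)

    def test_out_of_range_ratings_rejected(self):
        df = self.ratings(n=10, seed=3)
        df.loc[0, "mental_demand"] = 25.0
        with pytest.raises(ValueError, match="1-21"):
            fit_ratings_models(df)

    def test_null_domain_offset_interval_covers_zero(self):
        hits = 0
        for rep in range(100):
            fits = fit_ratings_models(
                self.ratings(n=40, domain_offset=0.0, seed=100 + rep),
                scales=("mental_demand",),
            )
            lo, hi = fits["mental_demand"].fixed_effects["domain"].ci95
            if lo <= 0.0 <= hi:
                hits += 1
        assert hits >= 90
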