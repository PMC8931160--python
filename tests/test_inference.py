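"""Bayesian correlation and paired-contrast Bayes factors.

Dual-route oracles: the correlation BF is checked against an independent
adaptive-quadrature implementation (different integrator, fully normalized
Hotelling density written from scratch); the paired-t JZS BF is checked
against the Zellner-Siow g-integral form (a different mathematical route
to the same quantity).
"""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import betaln, gammaln, hyp2f1

from cogedkit.inference import (
    CorrelationPrior,
    bayes_correlation,
    bayes_partial_correlation,
    correlation_log_bf10,
    paired_t_bf,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def hotelling_density(r, rho, n):
    """Exact sampling density of Pearson r, fully normalized."""
    logc = (
        math.log(n - 2)
        + gammaln(n - 1)
        - 0.5 * math.log(2 * math.pi)
        - gammaln(n - 0.5)
    )
    return math.exp(
        logc
        + 0.5 * (n - 1) * math.log1p(-rho * rho)
        + 0.5 * (n - 4) * math.log1p(-r * r)
        - (n - 1.5) * math.log1p(-rho * r)
    ) * hyp2f1(0.5, 0.5, n - 0.5, (1 + rho * r) / 2)


def oracle_bf10(r, n, prior):
    """BF10 by adaptive quadrature over rho."""

    def prior_pdf(rho):
        if prior.family == "stretched_beta":
            a = 1.0 / prior.width
            return math.exp(
                (a - 1) * math.log1p(-rho * rho)
                - (2 * a - 1) * math.log(2)
                - betaln(a, a)
            )
        dens = stats.cauchy.pdf(rho, scale=prior.cauchy_scale)
        if prior.renormalize:
            mass = stats.cauchy.cdf(1, scale=prior.cauchy_scale) - stats.cauchy.cdf(
                -1, scale=prior.cauchy_scale
            )
            dens /= mass
        return dens

    marg, _ = integrate.quad(
        lambda rho: prior_pdf(rho) * hotelling_density(r, rho, n),
        -1,
        1,
        limit=400,
    )
    return marg / hotelling_density(r, 0.0, n)


def oracle_paired_bf10(t, n, scale=math.sqrt(2) / 2):
    """JZS one-sample BF via the Zellner-Siow g-integral."""
    df = n - 1

    def integrand(g):
        return (
            (1 + n * g) ** -0.5
            * (1 + t * t / ((1 + n * g) * df)) ** (-(df + 1) / 2)
            * (scale**2 / 2) ** 0.5
            / math.gamma(0.5)
            * g ** -1.5
            * math.exp(-(scale**2) / (2 * g))
        )

    m1, _ = integrate.quad(integrand, 0, np.inf, limit=400)
    m0 = (1 + t * t / df) ** (-(df + 1) / 2)
    return m1 / m0


# ---------------------------------------------------------------------------
# bayes_correlation
# ---------------------------------------------------------------------------


class TestBayesCorrelation:
    def test_perfect_correlation_gives_overwhelming_evidence(self, rng):
        x = rng.normal(size=20)
        res = bayes_correlation(x, x + 1e-9 * rng.normal(size=20))
        assert res.r_median > 0.9
        assert res.bf10 > 100

    def test_large_null_sample_favors_the_null(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        res = bayes_correlation(x, y)
        assert res.bf10 < 1

    @pytest.mark.parametrize(
        "prior",
        [
            CorrelationPrior(),
            CorrelationPrior(width=1.0),
            CorrelationPrior(family="truncated_cauchy"),
            CorrelationPrior(family="truncated_cauchy", renormalize=False),
        ],
        ids=["medium", "uniform", "cauchy", "cauchy-unrenormalized"],
    )
    def test_matches_quadrature_oracle_within_one_percent(self, prior, rng):
        for _ in range(12):
            n = int(rng.integers(8, 60))
            rho = rng.uniform(-0.7, 0.7)
            x = rng.normal(size=n)
            y = rho * x + math.sqrt(1 - rho * rho) * rng.normal(size=n)
            res = bayes_correlation(x, y, prior=prior)
            expected = oracle_bf10(res.r_observed, n, prior)
            assert res.bf10 == pytest.approx(expected, rel=0.01)

    def test_scale_and_shift_invariance(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        a = bayes_correlation(x, y)
        b = bayes_correlation(3.0 * x - 7.0, -2.0 * (y + 100.0))
        assert a.bf10 == pytest.approx(b.bf10, rel=1e-9)
        assert a.r_median == pytest.approx(-b.r_median, abs=1e-9)

    def test_evidence_accumulates_with_n_under_a_real_effect(self, rng):
        medians = []
        for n in (50, 100, 200):
            bfs = []
            for _ in range(60):
                x = rng.normal(size=n)
                y = 0.3 * x + math.sqrt(1 - 0.09) * rng.normal(size=n)
                bfs.append(bayes_correlation(x, y, grid_size=401).bf10)
            medians.append(np.median(bfs))
        assert medians[0] < medians[1] < medians[2]

    def test_credible_interval_calibration_at_paper_scale(self, rng):
        rho = 0.3
        hits = 0
        for _ in range(200):
            x = rng.normal(size=104)
            y = rho * x + math.sqrt(1 - rho * rho) * rng.normal(size=104)
            res = bayes_correlation(x, y, grid_size=801)
            if res.ci95[0] <= rho <= res.ci95[1]:
                hits += 1
        assert hits >= 180

    def test_zero_variance_and_short_inputs_rejected(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="zero variance"):
            bayes_correlation(x, np.ones(10))
        with pytest.raises(ValueError, match="at least 4"):
            bayes_correlation(x[:3], x[:3])

    def test_bf_identity(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        res = bayes_correlation(x, y)
        assert res.bf10 * res.bf01 == pytest.approx(1.0)

    def test_vectorized_kernel_agrees_with_scalar_path(self, rng):
        rs = rng.uniform(-0.8, 0.8, size=5)
        vec = correlation_log_bf10(rs, 50.0, grid_size=1601)
        for r, lb in zip(rs, vec):
            single = correlation_log_bf10(float(r), 50.0, grid_size=1601)
            assert lb == pytest.approx(single, abs=1e-10)


class TestPartialCorrelation:
    def test_orthogonal_covariates_change_nothing_much(self, rng):
        n = 80
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        cov = rng.normal(size=(n, 2))  # independent of both
        full = bayes_correlation(x, y)
        part = bayes_partial_correlation(x, y, cov)
        assert part.r_median == pytest.approx(full.r_median, abs=0.05)
        assert part.n_effective == n - 2

    def test_residual_variance_zero_is_an_error(self, rng):
        n = 30
        c = rng.normal(size=n)
        x = rng.normal(size=n)
        with pytest.raises(ValueError, match="residual variance"):
            bayes_partial_correlation(x, 2.0 * c + 1.0, c)

    def test_confounder_attenuates_versus_zero_order(self, rng):
        # x and y share a strong confounder; partialling it out must
        # recover the closed-form partial correlation
        n = 400
        z = rng.normal(size=n)
        x = z + 0.5 * rng.normal(size=n)
        y = z + 0.5 * rng.normal(size=n)
        zero = bayes_correlation(x, y)
        part = bayes_partial_correlation(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / math.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert part.r_median < zero.r_median
        assert part.r_median == pytest.approx(closed, abs=0.05)

    def test_rank_deficient_covariates_named(self, rng):
        n = 40
        c = rng.normal(size=n)
        cov = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError, match="rank deficient"):
            bayes_partial_correlation(rng.normal(size=n), rng.normal(size=n), cov)


class TestPairedTBF:
    def test_near_zero_differences(self, rng):
        d = 1e-6 * rng.normal(size=50)
        res = paired_t_bf(d)
        assert abs(res.t_statistic) < 2
        assert res.bf10 < 1

    def test_real_effect_at_paper_sample_size(self, rng):
        wins = 0
        for _ in range(20):
            d = rng.normal(0.4, 1.0, size=104)
            if paired_t_bf(d).bf10 > 10:
                wins += 1
        assert wins >= 15  # most replicates give strong evidence

    def test_monotone_in_t_and_matches_g_integral_oracle(self):
        n = 40
        sd = 1.0
        bfs = []
        for t in np.linspace(0.0, 4.0, 9):
            d = np.zeros(n)
            # construct a sample with exactly this t statistic
            d[0] = 1.0
            d = (d - d.mean()) / d.std(ddof=1)  # mean 0, sd 1
            target_mean = t * sd / math.sqrt(n)
            d = d * sd + target_mean
            res = paired_t_bf(d)
            assert res.t_statistic == pytest.approx(t, abs=1e-8)
            assert res.bf10 == pytest.approx(oracle_paired_bf10(t, n), rel=0.01)
            bfs.append(res.bf10)
        assert all(b >= a for a, b in zip(bfs, bfs[1:]))

    def test_sign_consistency_and_df(self, rng):
        d = rng.normal(-0.5, 1.0, size=30)
        res = paired_t_bf(d)
        assert res.df == 29
        assert math.copysign(1, res.t_statistic) == math.copysign(1, res.mean_diff)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            paired_t_bf(np.ones(10))
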