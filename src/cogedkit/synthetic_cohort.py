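"""Synthetic COG-ED cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a domain-general motivation trait expressed as correlated latent
domain values, load-decreasing true subjective value on [0, 2] with a
minority of effort-seekers (SV > 1), load-dependent task performance,
weakly trait-correlated capacity / reward-sensitivity composites,
load-increasing workload ratings, and exclusion metadata.  Choice logs are
produced by running the real staircase (:mod:`cogedkit.task_engine`)
against a softmax choice policy, so the full pipeline runs identically on
synthetic and real exports.

Randomness: a single root seed; participant i draws from the substream
``default_rng([seed, i])``, so participant-level data are stable when the
cohort size changes.

Effort-seekers are a mixture component whose SV intercept is shifted above
1 in both domains.  Because a shared mixture shift itself correlates the
two domains, the Gaussian correlation of the latent domain values is
solved analytically so that the *total* cross-domain correlation of the
latent effort values equals ``rho_domains`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import task_engine
from .task_engine import (
    DEFAULT_AMOUNTS,
    DEFAULT_LOADS,
    DOMAINS,
    HIGH,
    LOW,
    OfferCell,
    TitrationSeries,
    run_titration,
    schedule_trials,
)

__all__ = [
    "PerformanceModel",
    "RatingsModel",
    "CohortConfig",
    "LatentProfile",
    "TrueSVGrid",
    "Participant",
    "Cohort",
    "choice_policy",
    "generate_cohort",
]

TLX_SCALES = ("mental_demand", "effort", "frustration")

#: realistic location/scale used to put latent factors on raw-score units
_RAW_SCALES = {
    "lspan": (42.0, 9.0),
    "ospan": (45.0, 12.0),
    "symspan": (28.0, 7.0),
    "bas_total": (40.0, 5.0),
    "grapes_reward": (52.0, 8.0),
    "spsrq_reward": (11.0, 4.0),
    "ncs": (60.0, 12.0),
}


@dataclass(frozen=True)
class PerformanceModel:
    """Coefficients linking load (and capacity) to familiarization performance.

    Working-memory performance (hit rate, correct-rejection rate, mean RT in
    ms) is linear in the high-effort load index (1..3 = 2/3/4-back);
    intelligibility is given per speech level (-4/-8/-12 dB SNR).  All
    probabilities are clipped to [0, 1] after noise.
    """

    hit_base: float = 0.85
    hit_slope: float = -0.10
    hit_capacity: float = 0.05
    hit_sd: float = 0.08
    cr_base: float = 0.96
    cr_slope: float = -0.03
    cr_capacity: float = 0.02
    cr_sd: float = 0.04
    rt_base: float = 550.0
    rt_slope: float = 100.0
    rt_capacity: float = -30.0
    rt_sd: float = 80.0
    intelligibility_by_load: tuple[float, float, float] = (0.90, 0.70, 0.45)
    intelligibility_capacity: float = 0.04
    intelligibility_sd: float = 0.08

    def hit_mean(self, load: int) -> float:
        return self.hit_base + self.hit_slope * (load - 1)

    def intelligibility_mean(self, load: int) -> float:
        return self.intelligibility_by_load[load - 1]


@dataclass(frozen=True)
class RatingsModel:
    """NASA-TLX generative settings (1-21 visual-analog scale).

    Level is coded 0 (baseline task) through 3 (hardest); slopes are per
    level step, matching the graded load effects the discounting phase
    assumes.
    """

    intercepts: dict = field(
        default_factory=lambda: {
            "mental_demand": 6.0,
            "effort": 7.0,
            "frustration": 4.0,
        }
    )
    load_slopes: dict = field(
        default_factory=lambda: {
            "mental_demand": 3.7,
            "effort": 2.5,
            "frustration": 1.0,
        }
    )
    domain_offsets: dict = field(
        default_factory=lambda: {
            "mental_demand": -1.0,
            "effort": -1.0,
            "frustration": 0.0,
        }
    )
    subject_sd: float = 2.0
    noise_sd: float = 2.5


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    The defaults are the package's reference condition: cross-domain
    trait correlation 0.3, per-level SV decrements of -0.09 (working
    memory) and -0.19 (speech), ~5% effort-seekers, near-zero trait
    correlations for the capacity and reward composites, and exclusion
    rates matching a 104-of-132 style retention pattern.
    """

    n_participants: int = 104
    rho_domains: float = 0.3
    sv_intercept_by_domain: dict = field(
        default_factory=lambda: {"working_memory": 0.75, "speech": 0.85}
    )
    sv_load_slope_by_domain: dict = field(
        default_factory=lambda: {"working_memory": -0.09, "speech": -0.19}
    )
    subject_sd: float = 0.25
    cell_noise_sd: float = 0.15
    softmax_temperature: float = 0.2
    p_effort_seeker: float = 0.05
    effort_seeker_shift: float = 0.6
    perf_model: PerformanceModel = field(default_factory=PerformanceModel)
    # SV change per SD of load-level performance; the working-memory value
    # matches a hit-rate regression coefficient of ~0.2 on the SV scale
    perf_sv_coupling: dict = field(
        default_factory=lambda: {"working_memory": 0.016, "speech": 0.01}
    )
    ratings_model: RatingsModel = field(default_factory=RatingsModel)
    composite_loadings: dict = field(
        default_factory=lambda: {
            "lspan": 0.7,
            "ospan": 0.7,
            "symspan": 0.7,
            "bas_total": 0.7,
            "grapes_reward": 0.7,
            "spsrq_reward": 0.7,
            "ncs": 0.8,
        }
    )
    r_capacity_sv: float = 0.1
    r_reward_sv: float = 0.1
    r_ncs_sv: float = 0.1
    p_no_headphones: float = 0.08
    p_incomplete: float = 0.1
    n_trials_per_cell: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if not -1.0 <= self.rho_domains <= 1.0:
            raise ValueError("rho_domains must lie in [-1, 1]")
        for name in (
            "p_effort_seeker",
            "p_no_headphones",
            "p_incomplete",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("r_capacity_sv", "r_reward_sv", "r_ncs_sv"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {r}")
        if self.softmax_temperature < 0:
            raise ValueError("softmax_temperature must be >= 0 (0 = deterministic)")
        if self.subject_sd <= 0 or self.cell_noise_sd < 0:
            raise ValueError("subject_sd must be > 0 and cell_noise_sd >= 0")
        for d in DOMAINS:
            mu = self.sv_intercept_by_domain[d]
            if not 0.0 < mu < 2.0:
                raise ValueError(f"sv intercept for {d} must lie in (0, 2)")
        # mixture variance contributed by the shared effort-seeker shift
        object.__setattr__(self, "_mixture_var", self._mixture_variance())
        object.__setattr__(self, "_rho_gauss", self._gaussian_rho())

    def _mixture_variance(self) -> float:
        p, s = self.p_effort_seeker, self.effort_seeker_shift
        return p * (1.0 - p) * s * s

    def _gaussian_rho(self) -> float:
        """Gaussian-part correlation so the total cross-domain correlation of
        per-participant true mean SV equals rho_domains.

        Two channels couple the domains outside the Gaussian copula of the
        latent domain values and must be compensated for: (a) the shared
        effort-seeker mixture shift, and (b) WM capacity acting as a common
        cause of both domains' SV through the performance coupling (better
        performers discount less in both domains).  Solving the covariance
        bookkeeping for the Gaussian correlation keeps the config's
        rho_domains an honest population target.
        """
        v = self._mixture_variance()
        s = self.subject_sd
        s2 = s * s
        pm = self.perf_model
        rc = self.r_capacity_sv
        # capacity weight of the (load-averaged) performance contribution
        k = {
            "working_memory": pm.hit_capacity / pm.hit_sd,
            "speech": pm.intelligibility_capacity / pm.intelligibility_sd,
        }
        w = {d: self.perf_sv_coupling[d] * k[d] for d in DOMAINS}
        cross = (
            v
            + s * rc * (w["working_memory"] + w["speech"])
            + w["working_memory"] * w["speech"]
        )
        # variance of the per-domain true mean SV (9 cells: 3 loads x 3 amounts)
        var = {}
        for d in DOMAINS:
            c = self.perf_sv_coupling[d]
            var[d] = (
                s2
                + v
                + w[d] ** 2
                + c * c / 3.0  # load-level performance noise, averaged
                + self.cell_noise_sd**2 / 9.0
            )
        denom = math.sqrt(var["working_memory"] * var["speech"])
        rho_g = (self.rho_domains * denom - cross) / s2
        if not -1.0 <= rho_g <= 1.0:
            raise ValueError(
                "rho_domains is unreachable given the effort-seeker mixture "
                "and performance coupling; required Gaussian correlation "
                f"{rho_g:.3f} outside [-1, 1]"
            )
        return rho_g


@dataclass(frozen=True)
class LatentProfile:
    g: float
    u_wm: float
    u_speech: float
    capacity: float
    reward_sens: float
    ncs_latent: float
    effort_seeker: bool


@dataclass(frozen=True)
class TrueSVGrid:
    """Ground-truth subjective values per (domain, load, amount) cell.

    Values live on the instrument's 0-2 scale: the number an ideal
    noiseless staircase-plus-scoring chain would report.  The latent
    effort preference that drives choices is the inverse instrument map
    of these values (identity below 1, 1/(2-SV) above 1).
    """

    values: dict  # (domain, load, amount) -> sv_true in [0, 2]

    def __post_init__(self):
        for key, v in self.values.items():
            if not 0.0 <= v <= 2.0:
                raise ValueError(f"true SV out of [0, 2] at {key}: {v}")

    def cell(self, domain: str, load: int, amount: int) -> float:
        return self.values[(domain, load, amount)]

    def load_mean(self, domain: str, load: int) -> float:
        vals = [v for (d, l, _), v in self.values.items() if d == domain and l == load]
        return float(np.mean(vals))

    def domain_mean(self, domain: str) -> float:
        vals = [v for (d, _, _), v in self.values.items() if d == domain]
        return float(np.mean(vals))


@dataclass(frozen=True, eq=False)
class Participant:
    participant_id: str
    latent: LatentProfile
    true_sv: TrueSVGrid
    performance: pd.DataFrame  # rows per (domain, load) with measure columns
    ratings: pd.DataFrame  # rows per (domain, level 0..3) with TLX columns
    spans: dict
    questionnaires: dict
    no_headphones: bool
    incomplete_discounting: bool
    titrations: tuple[TitrationSeries, ...]

    def __eq__(self, other):
        if not isinstance(other, Participant):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.latent == other.latent
            and self.true_sv == other.true_sv
            and self.performance.equals(other.performance)
            and self.ratings.equals(other.ratings)
            and self.spans == other.spans
            and self.questionnaires == other.questionnaires
            and self.no_headphones == other.no_headphones
            and self.incomplete_discounting == other.incomplete_discounting
            and self.titrations == other.titrations
        )


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    participants: tuple[Participant, ...]

    def __len__(self) -> int:
        return len(self.participants)


def choice_policy(
    sv_true: float,
    offer_high: float,
    offer_low: float,
    temperature: float,
) -> float:
    """Probability of choosing the harder option.

    Logistic in the subjective payoff difference
    ``(sv_true * offer_high - offer_low) / temperature`` (temperature in
    offer-currency units).  ``temperature == 0`` is the deterministic
    threshold limit (ties split 0.5); negative temperature is an error.
    """
    if offer_high <= 0 or offer_low <= 0:
        raise ValueError("offers must be positive")
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    diff = sv_true * offer_high - offer_low
    if temperature == 0:
        return 0.5 if diff == 0 else float(diff > 0)
    return float(1.0 / (1.0 + math.exp(-diff / temperature)))


def _latent_preference(sv_true: float) -> float:
    """Map instrument-scale true SV to the latent effort preference theta.

    True SV is defined on the instrument's 0-2 scale: the value an ideal
    noiseless staircase-plus-scoring chain would report.  For discounters
    (SV < 1) the scoring formula is the identity, theta = SV.  For
    effort-seekers the staircase titrates the hard option down to
    base/theta and scores it as 2 - 1/theta, so theta = 1/(2 - SV)
    inverts the instrument map.
    """
    if sv_true <= 1.0:
        return sv_true
    return 1.0 / (2.0 - min(sv_true, 2.0 - 1e-9))


def _make_chooser(sv_true: float, temperature: float, rng: np.random.Generator):
    """Stochastic chooser for the staircase; temperature 0 = threshold agent."""
    theta = _latent_preference(sv_true)
    if temperature == 0:
        return task_engine.threshold_chooser(theta)

    def choose(offer_low, offer_high):
        p_high = choice_policy(theta, float(offer_high), float(offer_low), temperature)
        return HIGH if rng.random() < p_high else LOW

    return choose


def _latent_correlation(config: CohortConfig) -> np.ndarray:
    """Correlation of (u_wm, u_speech, capacity, reward, ncs)."""
    rho_g = config._rho_gauss
    rc, rr, rn = config.r_capacity_sv, config.r_reward_sv, config.r_ncs_sv
    C = np.array(
        [
            [1.0, rho_g, rc, rr, rn],
            [rho_g, 1.0, rc, rr, rn],
            [rc, rc, 1.0, 0.0, 0.0],
            [rr, rr, 0.0, 1.0, 0.0],
            [rn, rn, 0.0, 0.0, 1.0],
        ]
    )
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError(
            "latent correlation matrix is not positive semidefinite; "
            "reduce rho_domains or the trait-SV correlations"
        )
    return C


def _chol_psd(C: np.ndarray) -> np.ndarray:
    # tolerate a semidefinite boundary (e.g. rho_domains = 1)
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (deterministic under a fixed seed)."""
    L = _chol_psd(_latent_correlation(config))
    pm = config.perf_model
    rm = config.ratings_model
    participants = []
    for i in range(config.n_participants):
        rng = np.random.default_rng([config.seed, i])
        z = L @ rng.standard_normal(5)
        u_wm, u_speech, capacity, reward, ncs_l = (float(v) for v in z)
        seeker = bool(rng.random() < config.p_effort_seeker)
        rho_g = config._rho_gauss
        g = (u_wm + u_speech) / math.sqrt(max(2.0 * (1.0 + rho_g), 1e-12))
        latent = LatentProfile(
            g=g,
            u_wm=u_wm,
            u_speech=u_speech,
            capacity=capacity,
            reward_sens=reward,
            ncs_latent=ncs_l,
            effort_seeker=seeker,
        )

        # --- familiarization performance ------------------------------------
        perf_rows = []
        perf_z = {}
        for load in DEFAULT_LOADS:
            hit = pm.hit_mean(load) + pm.hit_capacity * capacity + rng.normal(0, pm.hit_sd)
            hit = float(np.clip(hit, 0.0, 1.0))
            cr = pm.cr_base + pm.cr_slope * (load - 1) + pm.cr_capacity * capacity
            cr = float(np.clip(cr + rng.normal(0, pm.cr_sd), 0.0, 1.0))
            rt = pm.rt_base + pm.rt_slope * (load - 1) + pm.rt_capacity * capacity
            rt = float(max(150.0, rt + rng.normal(0, pm.rt_sd)))
            intel = (
                pm.intelligibility_mean(load)
                + pm.intelligibility_capacity * capacity
                + rng.normal(0, pm.intelligibility_sd)
            )
            intel = float(np.clip(intel, 0.0, 1.0))
            perf_rows.append(
                {
                    "load": load,
                    "hit_rate": hit,
                    "cr_rate": cr,
                    "mean_rt": rt,
                    "intelligibility": intel,
                }
            )
            perf_z[("working_memory", load)] = (hit - pm.hit_mean(load)) / pm.hit_sd
            perf_z[("speech", load)] = (
                intel - pm.intelligibility_mean(load)
            ) / pm.intelligibility_sd
        performance = pd.DataFrame(perf_rows)

        # --- ground-truth subjective values ---------------------------------
        values = {}
        for domain in DOMAINS:
            u_d = u_wm if domain == "working_memory" else u_speech
            for load in DEFAULT_LOADS:
                mean_dl = (
                    config.sv_intercept_by_domain[domain]
                    + config.sv_load_slope_by_domain[domain] * (load - 1)
                    + config.subject_sd * u_d
                    + (config.effort_seeker_shift if seeker else 0.0)
                    + config.perf_sv_coupling[domain] * perf_z[(domain, load)]
                )
                for amount in DEFAULT_AMOUNTS:
                    sv = mean_dl + rng.normal(0, config.cell_noise_sd)
                    values[(domain, load, amount)] = float(np.clip(sv, 0.0, 2.0))
        true_sv = TrueSVGrid(values=values)

        # --- workload ratings -------------------------------------------------
        rating_rows = []
        subj_off = {s: rng.normal(0, rm.subject_sd) for s in TLX_SCALES}
        for domain in DOMAINS:
            for level in range(4):  # 0 = baseline task
                row = {"domain": domain, "level": level}
                for scale in TLX_SCALES:
                    val = (
                        rm.intercepts[scale]
                        + rm.load_slopes[scale] * level
                        + (rm.domain_offsets[scale] if domain == "speech" else 0.0)
                        + subj_off[scale]
                        + rng.normal(0, rm.noise_sd)
                    )
                    row[scale] = float(np.clip(val, 1.0, 21.0))
                rating_rows.append(row)
        ratings = pd.DataFrame(rating_rows)

        # --- individual-difference measures ----------------------------------
        def raw_score(name: str, factor: float) -> float:
            lam = config.composite_loadings[name]
            mean, sd = _RAW_SCALES[name]
            latent_score = lam * factor + math.sqrt(max(0.0, 1 - lam * lam)) * rng.normal()
            return float(mean + sd * latent_score)

        spans = {k: raw_score(k, capacity) for k in ("lspan", "ospan", "symspan")}
        questionnaires = {
            k: raw_score(k, reward)
            for k in ("bas_total", "grapes_reward", "spsrq_reward")
        }
        questionnaires["ncs"] = raw_score("ncs", ncs_l)

        no_headphones = bool(rng.random() < config.p_no_headphones)
        incomplete = bool(rng.random() < config.p_incomplete)

        # --- decision phase ---------------------------------------------------
        titrations = []
        for domain in DOMAINS:
            for cell in schedule_trials(rng=rng, domain=domain):
                sv_cell = true_sv.cell(cell.domain, cell.load, int(cell.base_amount))
                chooser = _make_chooser(sv_cell, config.softmax_temperature, rng)
                titrations.append(
                    run_titration(cell, chooser, config.n_trials_per_cell)
                )
        if incomplete:
            # emulate dropping out partway through the second domain
            n_missing = int(rng.integers(1, 6))
            titrations = titrations[: len(titrations) - n_missing]

        participants.append(
            Participant(
                participant_id=f"p{i:04d}",
                latent=latent,
                true_sv=true_sv,
                performance=performance,
                ratings=ratings,
                spans=spans,
                questionnaires=questionnaires,
                no_headphones=no_headphones,
                incomplete_discounting=incomplete,
                titrations=tuple(titrations),
            )
        )
    return Cohort(config=config, participants=tuple(participants))
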