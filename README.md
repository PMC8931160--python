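# cogedkit

Tools for simulating and analyzing **cognitive-effort discounting (COG-ED)**
experiments that measure cognitive motivation across two task domains:
N-back working memory and speech-in-noise comprehension.

In the COG-ED paradigm, participants repeatedly choose between redoing an
easy task level (1-back, or listening at 0 dB SNR) for a smaller reward and
a harder level (2/3/4-back, or −4/−8/−12 dB SNR) for a larger one. Starting
from equal offers ($2, $3 or $4), the chosen option's offer is titrated
with successively halved steps over five choices; the final titrated offer
is the **indifference point**. Normalizing by the base amount gives a
**subjective value** SV ∈ [0, 2]:

- initial choice = easy task: SV = ip / base ∈ [0, 1] (effort discounting),
- initial choice = hard task: SV = 1 + (base − ip) / base ∈ [1, 2]
  (effort seeking).

The scientific question the analysis pipeline addresses: is cognitive
motivation a **domain-general trait**? It answers with a three-stage
correlational test across domains —

1. **H1** zero-order Bayesian correlation of mean SV across domains,
2. **H2** the same correlation after residualizing SV on task load and
   domain-appropriate performance (N-back hit rate, correct-rejection rate,
   mean RT; speech intelligibility) in a random-intercept mixed model,
3. **H3** a Bayesian partial correlation of the residual scores
   controlling working-memory-capacity and reward-sensitivity composites
   (sums of z-scores).

Correlation posteriors and Bayes factors use the exact sampling
distribution of Pearson's r integrated against a stretched-beta prior
(medium width 1/3 by default) on a fine grid; BF10 contrasts the marginal
likelihood against the point null ρ = 0. A sequential Bayes-factor design
analysis (evidence boundaries BF10 ≥ 10 / ≤ 0.1) provides stopping-time
Monte Carlo for planning such studies.

A synthetic-cohort generator with known ground truth (latent domain-general
motivation trait with configurable cross-domain correlation, effort-seeker
mixture, load-dependent performance, NASA-TLX ratings, span and
questionnaire scores, exclusion metadata) drives parameter-recovery tests
of the entire chain: generator → staircase → scoring → models → inference.

## Worked example

```python
from cogedkit import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort_config=CohortConfig(n_participants=104, seed=3),
    output_dir="out",
    seed=3,
)
report = run_pipeline(config)
p = report["primary"]
print("retained n:", p["exclusions"]["n_retained"])
print("H1:", p["h1_zero_order"]["r_median"], p["h1_zero_order"]["bf10"])
print("H2:", p["h2_residualized"]["r_median"], p["h2_residualized"]["bf10"])
print("H3:", p["h3_partial"]["r_median"], p["h3_partial"]["bf10"])
```

prints (synthetic cohort generated at population cross-domain ρ = 0.3,
~5% effort-seekers, exclusion rates ~8%/10%):

```
retained n: 79
H1: 0.440768 1945.418765
H2: 0.44352 2200.191671
H3: 0.443616 1796.500681
```

Read: after exclusions, this particular 79-person cohort realizes a
zero-order cross-domain correlation of mean subjective value of r = 0.44
with BF10 ≈ 1945 (a finite cohort drawn from a mixture population
fluctuates around the generating ρ = 0.3), and the association is
essentially unchanged after controlling load/performance (H2) and the
trait composites (H3) — the signature of a trait-like, domain-general
effect. The same report contains the pooled load × domain mixed model
(here: load slope −0.083 per level for working memory, domain offset
0.149 with interaction −0.100, i.e. steeper speech discounting), per-load
paired domain contrasts with default-prior Bayes factors, TLX rating
models, the effort-seeker sensitivity re-analysis (n = 74 retained), and
exploratory Need-for-Cognition correlations.

The same pipeline runs on exported CSV tables
(`PipelineConfig(input_dir=...)`), and a CLI wraps each stage:

```bash
cogedkit simulate-cohort --n 104 --seed 3 --out data/
cogedkit analyze --input-dir data/ --out results/
cogedkit design --rho 0.3 --n-sims 1000 --out design.json
cogedkit validate --input-dir data/
```

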