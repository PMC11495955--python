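# ceeresponse

Group-level behavioural response analysis for controlled exposure
experiments (CEEs) with mid-frequency active sonar (MFAS) on common
dolphin groups.

Free-ranging delphinids live in large, fast-moving groups that cannot be
instrumented with tags, so their response to naval sonar has to be read
from group-level data streams: drone-derived movement tracks of a focal
subgroup, whistle counts from passive acoustic recorders, and visual
counts of the number of subgroups in an aggregation.  A CEE is a
before–during–after design — a 10 min pre-exposure phase, a 10 min
exposure phase (sonar at a 212–215 dB source level, or a silent control),
and a 10 min post-exposure phase — analysed on a common grid of 5 s
blocks.  This package provides the full pipeline for such experiments:
simulation of synthetic CEEs with known ground truth, the latent-state
response models, detection summaries and the exposure–response
regression.  It is aimed at researchers developing or validating
behavioural response study analyses.

## The model

Each response variable is modelled with a two-state latent process on the
block grid and a log link:

    log(mean_t) = λ0 + λ1 z_t,   λ1 ≥ 0,   z_t ~ Bernoulli(p_phase[t])

with flat priors λ0 ~ U(−30, 30), λ1 ~ U(0, 30), p_phase ~ U(0, 1).  The
observation family is Poisson (subgroup counts), a zero-truncated normal
(whistle counts), or a switching Ornstein–Uhlenbeck block-velocity model
(movement: `β` governs directional persistence, `σ` velocity variability,
one shared z_t gates both enhancements; group speed is the Rayleigh mean
`σ √(π/(4β))`).  Fitting is Metropolis-within-Gibbs MCMC over three
chains.

Behavioural change is scored by the separation of the phase-probability
posteriors: `p(response) = max(Pr[p_exp > p_pre], Pr[p_exp < p_pre])`
(0.5 = identical posteriors, 1 = disjoint), `p(persistence)` the same for
the post phase, with a change *detected* when the statistic exceeds 0.9.
Per-CEE movement response probabilities then feed a hierarchical
regression on the maximum received level (RL) and pre-exposure speed v1:

    p_i = α_i + β (RL_i − 160) + ε_i,    α_i = α0 + κ (v1_i − mean v1),

with [0, 1]-truncated normal errors; α0 is the predicted response
probability at the 160 dB RMS regulatory reference level.

See `docs/methods.md` for the complete model description, priors, sampler
design and validation studies, and `docs/formats.md` for file formats.

## Worked example

```python
import ceeresponse as cr

cee = cr.simulate_cee(seed=42, cee_type="mfas_sim")

model = cr.LatentStateModel(
    family="trunc_normal", n_samples=20_000, n_burnin=20_000,
    n_chains=3, seed=7,
).fit(cee.whistles)
result = model.result(metric="whistles")

for phase in ("pre", "exp", "post"):
    mean, sd = result.phase_means[phase]
    print(f"{phase:>4}: {mean:5.1f} ({sd:.1f}) whistles per 5 s block")
print(f"p(response)    = {result.p_response:.3f} ({result.response_direction})")
print(f"p(persistence) = {result.p_persistence:.3f} ({result.persistence_direction})")
```

prints

```
 pre:   2.3 (0.3) whistles per 5 s block
 exp:   4.5 (0.5) whistles per 5 s block
post:   3.2 (0.4) whistles per 5 s block
p(response)    = 1.000 (increase)
p(persistence) = 0.999 (increase)
```

The synthetic CEE was generated with whistle enhancement λ1 = 2.08 and
phase probabilities (0.15, 0.55, 0.30): whistling roughly doubles during
the exposure phase and partially persists afterwards, and the fitted
phase means `exp(λ0 + λ1 p_phase)` recover that pattern; both posterior
separations exceed the 0.9 detection threshold.  The acoustic dose of the
same CEE:

```python
print(cr.max_rl(cee.pings), cr.cumulative_sel(cee.pings.sels()))
print(cr.initial_ping_slope(cee.pings))
```

```
146.4 dB RMS   159.1 dB re 1 uPa^2 s
(-1.84 dB, flagged=True)
```

— 24 pings at a 25 s repetition rate, a maximum received level inside the
study's 140–160 dB target window, the energy-summed cumulative exposure
level, and the range-opening decline in level over the first six pings.

A command-line front end wraps the same pipeline:

```sh
ceeresponse simulate --seed 42 --out cee42
ceeresponse fit --blocks cee42/blocks.csv --metric whistles \
    --family trunc_normal --iterations 20000 --burnin 20000 --seed 7 \
    --out whistles.json
ceeresponse dose-response --table covariates.csv --out dose.json
ceeresponse pipeline --seed 6 --n-mfas 3 --n-control 1 --out batch.json
```

The `pipeline` subcommand runs a whole synthetic batch — simulate, fit
all three metrics per CEE, build the detection summary and fit the
exposure–response regression — from a single seed, bit-reproducibly.

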