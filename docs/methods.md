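# Methods

## Model

`hostpar` models one generation of a host–parasitoid interaction inside a
closed vial. Each of `H0` host eggs independently ends the experiment in
one of three observable states: adult fly, adult wasp, or nothing. Two
multiplicative survival factors govern the fly channel: development
survival `s = exp(−m0·T − mτ)` and infection escape `q = exp(−a0·P)`
(the Nicholson–Bailey escape probability for `P` independently searching
wasps). Infected survivors (`s·(1−q)`) yield an adult wasp with
probability `ε`. The per-egg fate probabilities are therefore

```
p_fly  = s·q
p_wasp = s·(1−q)·ε
p_none = 1 − p_fly − p_wasp
```

Because the factors multiply, the log-scale mortalities add
(`m0·T + mτ + a0·P`); any departure from that sum in a combined
heat × parasitoid cell is a higher-order effect. Two instrumentation
terms inject such departures for testing: `γ` is added to the mortality
exponent and `δ` multiplies `a0`, both only where heat and parasitoids
co-occur. `γ = 0, δ = 1` recovers the additive null exactly.

Assumptions worth stating explicitly:

- **Single generation, fixed totals.** No reattack of emerged adults, no
  second wasp generation; all emergence after day `T` is folded into one
  end-of-experiment total per vial.
- **Homogeneous eggs within a vial.** One shared fate distribution per
  treatment cell; no between-vial random effects. Overdispersion relative
  to the multinomial is real data's problem, not the null model's — see
  limitations.
- **Infected-but-no-wasp is unobservable.** Hosts that are parasitized and
  die without producing a wasp (probability `s·(1−q)·(1−ε)`) are pooled
  into `p_none`; only emerged adults are counted.
- **Heat enters only through `mτ`** (and the test-only `γ`, `δ`); there is
  no within-day thermal physiology, and `mτ` is keyed by timing *category*
  (before/during/after), with the exposure day carried as metadata.

### Stochastic scheme

A vial is a single multinomial draw of size `H0` over
`(p_fly, p_wasp, p_none)`. A sequential scheme (survive first, then
infect, then convert) has identical marginals because the hazards are
multiplicative; the one-shot multinomial is the minimal scheme whose
expectations equal the closed forms exactly, which is what the fitting
layer inverts. All randomness flows through one explicitly threaded
`numpy.random.Generator`; nothing touches global state.

## Parameter estimation

Fitting uses only the control arms: combined heat × parasitoid cells are
reserved for the test. For pooled binomial counts with a shared
probability per stratum, inverting the pooled proportion is the MLE, so
the chain is exact closed forms, applied in order:

| parameter | stratum | closed form |
|---|---|---|
| `m0` (per host) | no-parasitoid, ambient | `−ln(Σflies/(n·H0))/T` |
| `mτ` (per host × timing) | no-parasitoid, heated | `−ln(Σflies/(n·H0)) − m0·T` |
| `a0` (per pair) | parasitoid, ambient | `−ln(F̄/(H0·e^(−m0·T)))/P` |
| `ε` (per pair) | parasitoid, ambient | `W̄/(H0·e^(−m0·T)·(1−e^(−a0·P)))` |

`mτ` may legitimately be negative (heat-accelerated development) and is
not clamped, only flagged. `a0` is clamped at 0 when mean fly emergence
exceeds the no-parasitoid expectation, and `ε` at [0, 1]; every clamp is
recorded in the fit's warning list. Zero total emergence in a stratum is a
degenerate-estimate error (the log diverges), not a silent value. `ε` is
fitted per host–parasitoid pair by default; `pool_epsilon=True` pools it
per parasitoid for communities where pair-level wasp counts are sparse,
and pair strata with fewer than 10 total wasps are flagged either way.

Standard errors come from a nonparametric bootstrap (default 1,000
resamples) that resamples vials with replacement *within each stratum*
and refits the whole chain, so the uncertainty in `m0` propagates into
`a0` and `ε` resample by resample; the SE is the standard deviation
across resamples (`se_method = "bootstrap_sd"`). Resamples that go
degenerate are skipped and counted.

## Additivity screen

For each combined cell the null projection simulates `n_sims` (default
10,000) pseudo-experiments of `replicates_per_cell` vials from the fitted
null parameters and takes the 2.5/97.5 percentiles of the
per-pseudo-experiment *mean* emergence (the per-treatment summary a
reader of an emergence figure sees; vial-level pooling would only narrow
the intervals). The observed side is a percentile bootstrap (default
10,000 resamples) of the replicate mean, resampling vials jointly so fly
and wasp intervals share resamples. Both interval constructions are
recorded in the `method` label of every `IntervalSummary`, since
reasonable alternatives (t-based observed intervals, totals instead of
means) exist.

The decision rule is binary: `higher_order` exactly when the two 95%
intervals are disjoint; touching endpoints count as overlap. No p-values
and no multiplicity correction are attached — overlap screening of two
95% intervals is conservative relative to a nominal 5% test, which the
measured calibration below reflects.

## Response metrics

`HS = flies/T̄` and `PR = wasps/T̄`, where `T̄` is the mean fly emergence
of the no-parasitoid controls matched on *both* host and heat timing
(never pooled across timings, so heat's direct effect on host
availability cancels). Both are capped at 1 per vial, before any
averaging. Denominators built from fewer than 3 control vials are
flagged.

## Synthetic data

The generator reproduces the factorial layout the model targets: 3 hosts
× 4 parasitoid levels (including the no-parasitoid control) × 4 heat
timings × 6 replicate vials of 50 eggs — 48 cells, 288 vials, 14,400
eggs. Default truth values are invented fixtures chosen once for
testability, not estimates of any real community: control survival
0.64–0.76 (`m0` 0.035–0.055/day over 8 days); one host heat-stressed
(`mτ` up to +1.1 for a late pulse, emulating an order-of-magnitude odds
drop) while the other two emerge 18–28% *better* under heat (`mτ` −0.18
to −0.25, emulating accelerated development). Negative `mτ` magnitudes
were chosen jointly with `m0` so `m0·T + mτ > 0` — the model requires the
implied survival to stay below 1 — while remaining large enough that a
moderately replicated experiment can measure them. Attack rates 0.15–0.32
put the infected fraction at 36–62%; `ε` spans 0.5–0.85.

Presets: `additive_null` (no higher-order terms), `synergy_mortality`
(`γ = 0.6` in heat-during combined cells — combined stress kills extra
hosts), `antagonism_parasitism` (`δ = 0.05` in heat-during and heat-after
cells — heat destroys freshly laid parasitoid eggs, collapsing attack
success and boosting fly emergence).

What the generator does *not* emulate: block/chamber effects (replicate
labels are opaque), between-vial overdispersion beyond multinomial noise,
development-time dynamics, and partial wasp mortality during foraging.
Passing tests therefore demonstrate correctness of the machinery under
the model's own noise assumptions, not robustness to real data's extra
variance — on overdispersed data the null intervals will be too narrow
and the screen less conservative.

## Numerical choices

- Fate probabilities are validated to sum to 1 within 1e-12; a negative
  total mortality exponent (implied survival > 1) is rejected as a
  parameter error rather than silently clamped.
- Counts are integers; fractional CSV inputs are rejected, not rounded.
- Interval endpoints are plain percentiles (no continuity corrections);
  a single-replicate cell degrades to a point "interval" with a warning.
- Ambient `mτ` defaults to 0 without being stored; all other missing
  parameter keys raise configuration errors naming the key.
- Seeds: every stochastic entry point takes an explicit seed or
  `Generator`; the CLI logs an auto-drawn seed when none is given.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use: 1,000 random parameter
draws for closed-form fidelity; 20 parameter sets × 10,000 vials for
stochastic/deterministic agreement; 50 seeded datasets at 200
vials/stratum for parameter recovery (median relative errors ≈ 1–3% per
parameter class); 50 seeded studies at the default 6 replicates for
calibration of the screen (measured fly-channel false-flag rate ≈ 3%,
comfortably below the 0.15 bound expected of a conservative overlap
rule) and for power under `antagonism_parasitism` (wasp-channel detection
≈ 100%). Null projections in these bulk runs use 2,000 pseudo-experiments
and 2,000 bootstrap resamples per cell — Monte-Carlo error on the
interval endpoints is well under half a fly at that size — while the
package defaults for single analyses stay at 10,000.

## Known limitations

- The closed-form chain conditions `a0`/`ε` on the point estimate of
  `m0`; the bootstrap propagates that dependence, but a joint likelihood
  would use fly and wasp counts in the combined cells too and is out of
  scope here by design (those cells are the test set).
- The overlap rule has no formal size; its operating characteristics are
  measured (calibration/power tests), not derived.
- `HS`/`PR` capping biases per-vial rates slightly downward near 1;
  capping is applied per vial because the rates are defined per
  observation.
- Parasitoid mortality during the foraging window is not modelled; `P`
  is the introduced number of females.
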