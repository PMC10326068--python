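# Methods

## The state model

A filament barbed end (B) occupies one of eight states according to which
of formin (F), capping protein (C) and twinfilin (T) are bound: B, BF, BC,
BCT, BFC, BFCT, plus two observationally absorbing states — DETACHED (the
filament left the field of view after formin loss; in the flow assays the
filament is anchored through formin, so formin loss *is* filament loss)
and UNCAPPED_DEPOL (a bare end undergoing twinfilin-driven
depolymerization). The model is a continuous-time Markov chain; all
sojourn times are exponential and rates are pseudo-first-order
(bimolecular on-rates are multiplied by the relevant concentration when
the propensity table is built, since concentrations are constant within an
experimental phase).

Two modeling layers coexist deliberately. The coarse two-route model of
decision-complex resolution has the closed-form solution

```
BFC(t)/BFC0 = exp(-(k'_-C + k'_-F) t)
BF(t)/BFC0  = k'_-C/(k'_-C + k'_-F) * (1 - exp(-(k'_-C + k'_-F) t))
BC(t)/BFC0  = k'_-F/(k'_-C + k'_-F) * (1 - exp(-(k'_-C + k'_-F) t))
```

and is what the inference layer fits. The mechanistic layer adds
twinfilin visits: `BFC -> BFCT` at `k_on_T * [Twf]`, departure at
`k_minus_T_BFCT` with per-visit CP removal probability `p_uncap_BFCT`
(default 1: CP and twinfilin leave the decision complex together as a
single `BFCT -> BF` event, because simultaneous departure is what is
observed), and analogously `BC <-> BCT` with `p_uncap_BCT` (default
1/30.9). With `[Twf] = 0` the table reduces exactly to the two-route
model; under twinfilin the *observed* `k'_-C` is an emergent,
concentration-dependent quantity. Formin loss from the trimeric complex
(`BFCT -> BCT`) was never observed experimentally and defaults to rate 0,
kept as an explicit parameter; CP arrival at a formin-bound end carrying
twinfilin is not modeled at all (never observed).

## Default parameters

| parameter | default | unit | origin |
|---|---|---|---|
| `kprime_minus_C` | (1/149)·30/72 ≈ 0.0028 | s⁻¹ | 149 s control BFC lifetime × BF route share (30/72) |
| `kprime_minus_F` | (1/149)·42/72 ≈ 0.0039 | s⁻¹ | same lifetime × BC route share (42/72) |
| `k_minus_F` | 1/2100 | s⁻¹ | ~35 min formin residence on BF |
| `k_minus_C` | 1/1800 | s⁻¹ | ~30 min spontaneous CP residence |
| `k_minus_T` | 1/1.9 | s⁻¹ | 1.9 s twinfilin dwell at capped ends |
| `k_minus_T_BFCT` | 1/1.4 | s⁻¹ | 1.4 s twinfilin dwell at decision complexes |
| `p_uncap_BCT` | 1/30.9 | – | ~31 visits per uncapping at capped ends |
| `p_uncap_BFCT` | 1 | – | single visit suffices at decision complexes |
| `k_on_T` | 1.08 | µM⁻¹s⁻¹ | *derived*: 20 nM twinfilin raises the BFC exit rate from 1/149 to 1/35.4 s⁻¹; with certain per-visit ejection the added rate is `k_on_T`·0.02 µM |
| `k_on_C` | 10 | µM⁻¹s⁻¹ | order-of-magnitude CP association; not measured here |
| velocities | BF 0.1, B 0.02, capped 0, depol −0.05 | µm/s | observation-layer configuration values only |

No absolute twinfilin on-rate is printed anywhere; `k_on_T` is a derived
calibration, and because the model is linear in concentration it
over-predicts the response at micromolar twinfilin, where the measured
dose dependence saturates. Conclusions drawn from the defaults should
stay in the tens-of-nanomolar regime they were calibrated in.

## Simulation and the synthetic observation layer

Trajectories are exact Gillespie realizations; cohorts draw per-filament
generators from `SeedSequence(cohort_seed, spawn_key=(i,))`, so results
are reproducible and independent of simulation order. The event table
records, per filament, the first resolution of the initial complex; the
`outcome` column records *which protein's departure* ended observation
(`to_BF` = CP left, `to_BC` = formin left) or `censored` at the window.

The observation layer renders what a time-lapse experiment would record.
A frame reports the protein content of the state occupying the majority
of the frame interval (ties break toward the earlier-indexed state), times
one intensity unit per unbleached fluorophore, plus Gaussian noise.
Photobleaching is one irreversible exponential off-time per fluorophore,
drawn fresh per presence episode (each arrival is a new molecule from
solution); the fluorophore count per molecule is configurable (1 for
monomeric labels, 2 for dimeric formin). The length channel integrates
the per-state velocity. What this emulates well: exponential dwells,
frame-limited detection, censoring, route statistics, bleaching
staircases. What it does not: spatial structure, diffraction, localization
error, flow artifacts, background drift, blinking. Tests passing on these
traces therefore validate the *statistical* pipeline, not image
processing.

### Frame-discretization bias (why measured dwells exceed the true mean)

Under the majority rule an event of duration `d` is detected only if it
dominates at least one frame; events shorter than half a frame vanish,
and detected events are measured as a whole number of frames. For
exponential dwells with mean `tau >> dt` the measured mean is
approximately `E[d · 1{d > dt/2}] / P(detect) ≈ (tau + dt/2) / (1 - …)`,
i.e. biased high by roughly half a frame plus the truncation of short
events. At `tau = 1.9 s`, `dt = 0.2 s` this is +6.4% (Monte Carlo:
2.022 ± 0.008 s), and *any* causal frame-sampling convention with
durations reported as whole frames carries a bias of at least ~`dt/2`.
The package reports durations as `(end − start)·dt` with single-frame
events flagged as lower bounds — matching how frame-limited data are
actually reported — and does not apply a post-hoc `−dt/2` correction, so
its measured dwell means should be read as `tau + dt/2` estimates. The
same mechanism makes trace-based visit counts ~5% low (sub-frame visits
are invisible); the trajectory-level counters
(`count_twinfilin_visits`, `presence_ground_truth`) provide the
ground truth against which these biases are quantified.

## Inference

**Survival fits.** The empirical survival fraction is
`1 − (#events ≤ t)/n0` with censored filaments contributing to `n0` only.
The rate is the unweighted least-squares fit of `exp(-k t)` (amplitude
fixed at 1, no offset) solved by bracketed bisection on the stationarity
condition — deterministic, and vectorizable across thousands of bootstrap
replicates at once. A censored-exponential maximum-likelihood estimate
(`rate_mle`) is provided as a cross-check; on uncensored data the two
agree within a few percent at n ≥ 1000.

*Evaluation grid.* Evaluating the step function exactly at the jump
times with the `≤` convention places every point half a step (1/2n) below
the true curve and inflates the fitted rate by ~`1/(2 n <kt>)` — +6% at
n = 50 on fully observed cohorts, worse under censoring. Time-lapse data
are recorded on a regular acquisition grid, where the empirical step is a
pointwise-unbiased estimate of `S(t)`; the pipeline and the experiment
helpers therefore fit on a regular grid (default spacing 5 s, matching
typical acquisition intervals), while `survival_curve` keeps event-time
evaluation as its default for exploratory use.

**Route decomposition.** `k_-BFC` comes from the pooled fit;
`k'_-C = k_-BFC · N_BF/(N_BF+N_BC)` and complementarily for `k'_-F`, with
censored rows excluded from the counts.

**Bootstrap.** Uncertainty follows a parametric bootstrap: simulate
`reps = 1000` cohorts of `n` exponential lifetimes at the fitted rate,
censor at the window, refit each identically, and report both the sd of
the refitted rates and the central 65% percentile interval (the interval
is widened to include the point estimate in the rare case it falls
outside). Calibration, measured rather than assumed: at the control
condition (rate 1/149 s⁻¹, 500 s window, n = 50) the nominal 65% interval
covers the true rate in ~64–66% of 1000 synthetic cohorts with grid
evaluation; with event-time evaluation the estimator bias drags coverage
to ~59–60%, which is the quantitative reason grid evaluation is the
default.

**Dwell analysis.** Binarization thresholds at a fixed value or an
automatic midpoint between the two intensity classes (Otsu's criterion on
the trace histogram); runs separated by at most `gap_tolerance` off
frames merge (default 0 — raw arrivals and departures, no blinking
correction); all events enter the mean (no trimming). The per-visit
uncapping probability is `1/mean(visit counts)` over resolved filaments
(geometric-law inversion) with a percentile bootstrap over filaments.
Depolymerization onset — the operational proxy for CP loss with an
unlabeled cap — is the first frame followed by ≥ 3 consecutive length
decreases (configurable); a capped end cannot shrink, so sustained
shortening marks uncapping. Photobleaching steps are counted by greedy
binary segmentation on the running mean (window 5 frames), accepting a
split while its SSE gain exceeds that of a `min_step/2` level change,
merging adjacent levels closer than `min_step`, and counting downward
level changes — a QC-grade counter for single/double-step classification,
not a general step-detection HMM.

## Numerical choices and degenerate inputs

- Occupancy fractions use `expm1` for the dissociated mass; conservation
  holds to < 1e-12 over 10^6 random parameter sets. Both route rates zero
  is flagged (warning + `degenerate`), not an error, except in
  `route_fraction_bf` where the split is genuinely undefined.
- A never-decaying survival curve returns rate 0 with a degenerate flag; a
  fully censored event table refuses route decomposition.
- Bisection runs 60 iterations after bracket expansion, giving rate
  precision far below sampling error; ties in the majority rule and in the
  change-point merge are broken deterministically, so every pipeline
  output is a pure function of (config, seed).

## Problem sizes used in the shipped analyses

Cohorts of 110–2,000 filaments for survival/route recovery, 1,000
synthetic cohorts × 1,000 bootstrap replicates for CI calibration, 300–
2,000 filaments for the uncapping assay, 100–200 traces for observation
QC. These sizes put Monte-Carlo error comfortably below the effect sizes
under test while keeping a full run of the suite plus the acceptance
script in the minutes range.

## Known limitations

- Pseudo-first-order twinfilin kinetics: no saturation, so micromolar
  extrapolations overshoot the measured dose response.
- No nucleotide-state dependence, no filament-side binding, no spatial or
  image-level realism (see observation layer above).
- The decision-complex formin-loss rate is treated as
  twinfilin-independent (as observed); if that changed with concentration
  the route decomposition would still be valid but the mechanistic
  defaults would not.
- Trace-derived dwell means and visit counts carry the frame-sampling
  biases quantified above; they are reported as measured, with the
  trajectory-level ground truth available for calibration.
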