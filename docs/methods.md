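# Methods

## The task and the error model

The package analyses delayed-reproduction ("cued recall") experiments in
which four items are presented **sequentially**, each defined by a feature on
a circular report dimension — bar orientation (period 180°) or color-wheel
hue (period 360°) — and a location on an invisible placement circle.  After a
delay one item is cued and its feature reproduced on the continuous scale.
Errors are classified with the standard three-component mixture: writing
`x` for the response, `t` for the target feature and `f_i` for the `m`
non-target features of the same trial,

```
p(x) = p_T · vm(x; t, κ) + p_NT · (1/m) Σ_i vm(x; f_i, κ) + p_U · 1/(2π)
```

where `vm` is the von Mises density and the three proportions sum to one.
The swap proportion `p_NT` — responses centred on an uncued item — is the
scientific quantity of interest; `p_U` captures random guessing and `κ`
(shared by all von Mises components) the report precision.  The model
deliberately treats non-targets as exchangeable (equal `1/m` weights); the
temporal/spatial structure of swaps is measured separately (below), not
folded into the likelihood.

Orientation data are mapped onto the full circle by doubling all angles
before any density evaluation, so the von Mises can be used in its standard
formulation; `κ` is always reported on this doubled "analysis circle".
Angles at rest (CSV files, the generator's output) stay on the raw scale.

## Maximum-likelihood fitting

`fit_mixture` runs expectation–maximisation over per-trial component
responsibilities, separately for each participant × condition slice (pooled
over ordinal positions).  The M-steps are closed-form: proportions are mean
responsibilities with the non-target weights tied to a common `p_NT`, and
`κ` solves `I₁(κ)/I₀(κ) = Σγ·cos(d)/Σγ`, the responsibility-weighted mean
cosine of component-centred deviations.  Because the component means are
fixed at the item features, the mean cosine — not the resultant length,
which re-estimates a free mean direction — is the sufficient statistic; the
distinction matters (the resultant variant biases `κ` upward and can lodge
EM at a sub-optimal fixed point).

Numerical choices:

- **Multistart.** 10 starts: one moment-based (κ from the mean cosine of
  target deviations) plus a 3 × 3 lattice of `(p_T, p_NT)` ∈ {(.8,.1),
  (.5,.3), (.3,.3)} × κ ∈ {2, 8, 32}, all iterated in one batched EM. Ties
  (within 1e-9 nats) break toward the lower concentration.
- **Convergence.** |Δ log-likelihood| < 1e-6 nats per start, cap 1000
  iterations.
- **κ ceiling = 700.** Beyond this the Bessel-ratio inversion is numerically
  degenerate and the density indistinguishable from a point mass.  Bessel
  functions are used in exponentially scaled form throughout so likelihoods
  stay finite at the ceiling.
- **Boundaries.** Proportions may converge to exact zeros and are reported
  as such; boundary estimates (e.g. `p_U = 0`) are meaningful.
- Deviations of exactly half a period wrap to `+period/2`, fixing the
  histogram bin of a measure-zero case deterministically.
- With uniform data the likelihood becomes flat in the proportions as
  `κ → 0`; fits then occasionally trade guess mass for a near-flat von
  Mises.  The fitted *density* is still essentially uniform — tests assert
  that, rather than a sharp `p_U` cutoff.

## Shuffle-corrected non-target histograms

Swaps show up as a central peak in the histogram of response deviations
from non-target features, but the minimum feature separation enforced
within trials (10° orientation, 20° color) makes that histogram non-uniform
even without swaps.  The correction transplants trial A's target-to-
non-target offsets onto trial B's target, for **every ordered pair** of
distinct trials within a participant × condition slice (`N·(N−1)` pairs,
computed exhaustively — no Monte-Carlo noise), histograms trial B's
response deviations from these pseudo-non-targets, rescales to the observed
mass and subtracts.  On swap-free data the corrected histogram is flat at
zero within binomial error; with swaps present the correction is slightly
conservative, since the chance construction shares the response-error
distribution with the observed histogram.  It is a visualisation and
null-check device; condition comparisons use the heuristic proportions and
the model fit.

Bin width defaults to one twelfth of the period (15° orientation, 30°
color) so that the two central bins coincide exactly with the heuristic
window: `p̃_T` counts responses within ±15° (±30° for color) of the target,
`p̃_NT` within the same window of *any* non-target, both on uncorrected
deviations; a response can count toward both.

## Swap gradients and their chance level

`mad_by_temporal_separation` pools response deviations from non-targets by
relative ordinal position (−3…+3 for four items); `mad_by_spatial_bin`
pools them by target-to-non-target angular distance on the placement
circle, different-location trials only, with right-closed bins
(0, 67.5], (67.5, 105], (105, 142.5], (142.5, 180] — the ≈30° minimum
angular spacing puts roughly a quarter of non-targets in each.  A mean
absolute deviation (MAD) below chance in a group indicates swaps at that
separation.  The chance level is the MAD of responses from all shuffled
non-target features (same exhaustive pairing as above); without separation
constraints it equals period/4 (45° orientation, 90° color).  The reference
line reported alongside profiles averages the per-slice shuffled MADs
across participants and conditions (per-slice values are also emitted).
The MAD measure cannot distinguish swaps from graded response biases toward
non-target features.

## Bayes factors and the sequential design

Condition effects are tested with default-prior (JZS) Bayesian t tests: a
Cauchy prior with scale `r = √2/2` on the standardized effect size under
the alternative, equivalently `g ~ InverseGamma(1/2, r²/2)` in the g-prior
form.  `jzs_bf_one_sample` evaluates the marginal-likelihood ratio by
adaptive quadrature after compactifying the g-integral onto (0, 1); the
numerical error is far below the 0.01 at which Bayes factors are read.
Only the analytic t-test route is implemented; model-averaged ANOVA
inclusion Bayes factors (which require posterior sampling) are out of
scope.

The location × ISI interaction on swaps is summarised per participant by
the difference of differences

```
Δp_NT = (p_NT(different, short) − p_NT(same, short))
      − (p_NT(different, long)  − p_NT(same, long))
```

and the sequential design monitors a one-sample Bayes factor on the
accumulated Δp_NT values, stopping at BF₁₀ > 10, BF₀₁ > 10, or 20
participants.  The monitoring starts at `n_min = 2` (the smallest n with a
variance estimate); this floor is configurable.  Note that with `r = √2/2`
and 20 participants the BF₀₁ > 10 boundary is unreachable (BF₀₁ at t = 0,
n = 20 is ≈ 5.6), so null runs typically end at the participant cap.

## The synthetic generator

`generate_dataset` emulates the experimental structure end to end: per
participant and condition, 120 trials in three blocks of 40 with each of
the four ordinal positions cued ten times per block in random order;
feature tuples drawn uniformly subject to the minimum pairwise wrapped
separation; locations on a 6-dva-radius circle, identical within
same-location trials and at least 3 dva apart (chord distance, ≈29° of
arc) in different-location trials.  Responses are drawn from the generative
reading of the mixture, with von Mises noise applied on the analysis circle
and mapped back, so generated and fitted `κ` are directly comparable.

Constrained tuples use **whole-tuple rejection** (the entire tuple is
redrawn on any violation, capped at 10⁵ draws per tuple on average): unlike
sequential placement this preserves exchangeability and keeps every
marginal uniform.  The minimum separation is enforced between *all* pairs
after wrapping, the stricter reading of the constraint.

Default per-condition mixtures encode the effect pattern characteristic of
this paradigm — swap proportion elevated in the same-location/short-ISI
condition (`p_NT = 0.25` vs 0.12/0.14/0.15 elsewhere, `p_T ≈ 0.67–0.70`,
`κ = 8`) — so a default simulated cohort carries a realistic interaction
for end-to-end exercises.  Optional knobs emulate structure the mixture
model itself does not assume: `swap_weights` biases swap destinations by
relative ordinal position (a target position left with no weighted
non-target, e.g. all mass on +1 with the last item cued, falls back to a
uniform destination), and `kappa_by_position` grades precision by ordinal
position to produce recency.  Randomness comes from one seed with fixed
per-participant substreams, so datasets are reproducible regardless of
cohort size.

What the generator does **not** emulate: perceptual encoding dynamics
(masking, temporal crowding) beyond condition-dependent parameters,
response times, feature-specific biases (e.g. the oblique effect),
aborted-and-repeated trials, or any dependence of errors on the actual
feature values.  Passing tests therefore validate the estimators and the
pipeline under the model's own assumptions — they do not certify the model
against real data, where such structure exists.

## Problem sizes used in tests and the acceptance script

Parameter recovery uses 100 single-condition datasets of 120 trials
(the per-condition trial count of the emulated design); the
shuffle-nullity check uses one 996-trial slice; the EM-versus-grid check
uses 20 fixtures of 20–28 trials against a grid with step 0.02 in the
proportions and 40 log-spaced concentrations; the design simulation uses
20 cohorts with the effect and 100 without, each recruiting up to 20
participants.  These sizes give stable Monte-Carlo estimates (binomial
error a few percent) at desk-scale runtimes.

## Known limitations

- The mixture assigns swaps by likelihood, so a guess that lands near a
  non-target is (correctly, probabilistically) partly credited as a swap;
  at n = 120 the swap-proportion estimate carries a small positive bias
  (≈ 0.01) visible in the recovery simulations.
- The shuffle correction undercounts swap mass when swaps are present (by
  design it is exact only under the null).
- Heuristic proportions are window-based and do not separate overlapping
  target and non-target windows.
- The stopping-rule simulation treats fitted Δp_NT values as exchangeable
  across participants; real cohorts add between-participant variance in
  all four proportions.
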