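# Methods

This note documents the models, conventions and numerical choices behind
`lexichain`, in the package's own terms. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. The response-time engine (`random_walk`)

A trial's RT is the first-passage time of a single-boundary accumulator:
starting value `start`, absorbing `criterion`, i.i.d. Gaussian evidence
increments with mean `drift` and SD `increment_sd` per step. Defaults:
start 0, criterion 10, increment SD 0.05, drift grid {0.25, 0.20, 0.15,
0.10} spanning easy-to-hard tasks. Steps map to physical time through
`step_duration_ms` (default 10 ms, chosen so the drift grid spans roughly
400–1000 ms, the range of mean RTs in batteries of this kind; it is fully
configurable and all ms outputs scale exactly linearly in it).

Because the increments are Gaussian, the walk is Brownian motion with drift
μ and volatility σ observed at integer times, and the continuous
first-passage law is Wald/inverse-Gaussian with mean `a/μ` and variance
`aσ²/μ³` for barrier distance `a = criterion − start` (`wald_moments`).

**Crossing-time definition.** Declaring absorption at the first integer
step with value ≥ criterion overstates the continuous first-passage time by
the expected overshoot divided by the drift, `(μ² + σ²)/(2μ²)` steps —
about +0.52 steps at μ = 0.25, σ = 0.05, and +0.625 at μ = 0.1. That fixed
bias dwarfs Monte-Carlo error at any realistic sample size (3 SE at
n = 10⁵ is ±0.012 steps at μ = 0.25), so an integer-step simulator can
never agree with the closed form to Monte-Carlo accuracy; linear
interpolation within the crossing step still leaves `σ²/(2μ²)` (+0.021 /
+0.125). The engine therefore reconstructs the continuous crossing time:

1. step the walk until a step's endpoint reaches the barrier, *or* an
   intra-step excursion is detected — for endpoints `h0, h1` below the
   barrier, a Brownian bridge crosses with probability
   `exp(−2·h0·h1/σ²)`;
2. bisect the straddling step 12 times, sampling the bridge midpoint at
   each level (by rejection, conditioned on the crossing actually occurring,
   when both endpoints lie below the barrier) and descending into the half
   that contains the first crossing with its conditional probability;
3. linearly interpolate inside the final sub-interval (width 2⁻¹²).

Validation at n = 2×10⁶ puts the residual bias below one Monte-Carlo
standard error at both μ = 0.25 and μ = 0.1, with sample variances matching
`aσ²/μ³`. Crossing times are therefore *fractional* steps; with
`increment_sd = 0` the walk is a deterministic ramp and the crossing time is
exact (e.g. 40.0 steps at μ = 0.25). Walks not absorbed within `max_steps`
(default 100 000) are flagged censored, reported at the cap, and excluded
from moment summaries with a warning; an all-censored sample (e.g. negative
drift) is an explicit error condition, never a silent truncation.

Distribution summaries (`rt_distribution_summary`) report n, mean, sample
SD (n−1), skewness as the biased third standardised moment `m₃/m₂^1.5`,
quantiles at {0.1, 0.25, 0.5, 0.75, 0.9}, and a histogram whose counts sum
to n. Single observations and zero-variance samples yield NaN for the
undefined moments rather than a number.

## 2. The generative battery model (`latent_model`)

The synthetic-data generator emulates a four-task battery: 48 participants;
120/240/240/120 trials for NRT/ADT/LDT/GDT; exact 50/50 target/foil splits,
order shuffled per participant × task; a 3000 ms response deadline.

Participant abilities `(d, l, w, s)` are standardized Gaussians: `d`
independent; `l` standard normal; `w = chain_lw·l + residual`;
`s = chain_ws·w + direct_ls·l + residual`, residuals scaled to keep unit
variances (parameterizations implying variance ≥ 1 are rejected).
`direct_ls = 0` is the chain hypothesis; with it, corr(l, s) =
chain_lw·chain_ws exactly (Markov property).

Drift for a cell is `base_drift[task][stimulus] · exp(Σ weights·abilities)`.
The exponential link guarantees positive drifts and makes expected RTs
log-normal across participants (right-skewed, as in real batteries).

Defaults, fixed analytically before any testing:

* chain weights `chain_lw = 0.5`, `chain_ws = 0.55`;
* loadings — NRT {d .12}; ADT {d .12, l .11}; LDT {d .12, l .02, w .10};
  GDT {d .12, w .02, s .12}. With the chain above these imply pairwise
  expected-RT correlations ≈ (ADT·LDT .83, LDT·GDT .81, ADT·GDT .66,
  NRT·{.74, .73, .67}) and NRT-partials ≈ (.63, .64) adjacent vs .33
  non-adjacent — the adjacency fingerprint at realistic strength;
* base drifts from the target battery means (yes: 536/499/613/1098 ms, no:
  555/515/693/1345 ms for NRT/ADT/LDT/GDT) via
  `base = (barrier/target_steps)·exp(Var(η)/2)`, the log-normal mean
  correction, giving yes-drifts (.1879, .2031, .1653, .0925) and no-drifts
  (.1815, .1967, .1462, .0755). "No" responses get a lower base drift per
  task rather than a shifted criterion — one mechanism reproduces
  "yes faster than no" everywhere;
* error rates per task × stimulus type are the battery's published-scale
  values (yes: 2.48/2.93/4.04/6.30%; no: 1.59/1.59/3.07/16.4%), drawn as
  independent Bernoulli overlays rather than second-boundary absorptions —
  the walk has one criterion, and error trials are discarded by the
  pipeline anyway;
* fast guesses: 0.1% of trials uniform in [150, 299] ms, so the < 300 ms
  filter is exercised;
* timeouts: walks not absorbed by the deadline are recorded at the cap and
  marked incorrect.

`implied_task_rt_correlations` is the Monte-Carlo oracle used for
recovery: it maps sampled abilities through the closed-form expected RT
`(criterion − start)/drift · step_duration` (no trial noise) and returns
the 4×4 correlation matrix.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: item-level effects (word frequency, letter
size, specific sentences), sequential trial dependencies and practice or
fatigue, speed–accuracy trade-offs (errors are independent of the walk),
participant-level variation in error rates, and RT distributions of error
responses. One deliberate tail: with unit ability SDs, roughly 0.1% of
simulated participants are fast enough that much of their ADT cell falls
under the 300 ms floor; the pipeline's small-cell and empty-cell handling
covers this and the affected participants are flagged.

## 3. The exclusion pipeline (`preprocessing`)

Order is fixed and matters (a fixture in the tests demonstrates that
permuting the last two steps changes the output):

1. **participant gate** — drop participants below 75% accuracy in *any*
   task, computed over all of that task's trials before any trial
   filtering (the gate precedes the trial-level filters conceptually and
   chronologically); the boundary is inclusive (exactly 75% is retained);
2. **incorrect trials** removed, tallied per task against all trials;
3. **fast trials** — remaining correct trials with RT strictly below
   300 ms, tallied against remaining correct trials;
4. **outliers** — within each participant × task × response-type cell,
   trials more than 2.5 *sample* SDs (n−1) from the cell mean, in a single
   pass on the post-filter trials (no re-iteration). Cells with fewer than
   3 trials are skipped with a warning. A tolerance of 10⁻⁹ × cell mean
   guards the comparison against float roundoff in constant cells.

Where a convention was genuinely open (sample vs population SD, pre- vs
post-floor outlier basis, single vs iterated passes), the choices above are
the package's defaults and the thresholds are exposed (`min_accuracy`,
`rt_floor_ms`, `outlier_k`) so alternative conventions can be run.

Summaries: one mean RT per participant × task over retained correct trials
of the configured response type (yes by default — the correlation input);
group descriptives pool trials (mean and SE = sd/√n over trials); error
percentages are computed per stimulus type on the post-gate, pre-filter
trials. Standardization z-scores each task column across participants
(listwise-complete, ≥ 3 participants, zero-SD columns rejected);
downstream correlations are invariant to it, but it is the conventional
input scale.

## 4. Correlation inference (`correlations`)

All statistics are computed from their defining formulas; scipy supplies
only the t and normal distribution functions.

* Pearson r, `t = r√(n−2)/√(1−r²)`, two-sided p on n−2 df.
* First-order partial
  `r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²))`,
  `t = r√(n−3)/√(1−r²)` on n−3 df; the data-vector overload equals the
  residual-regression correlation to 10⁻¹⁰ (property-tested). Triads are
  checked for positive semi-definiteness.
* Dependent overlapping correlations (r_jk vs r_jh sharing j): default
  Steiger's Z with the *back-transformed average* — Fisher-transform both
  correlations, set `r̄ = tanh((z₁+z₂)/2)`, estimate their covariance as
  `c = [r_kh(1−2r̄²) − ½r̄²(1−2r̄²−r_kh²)]/(1−r̄²)²`, and refer
  `(z₁−z₂)√((n−3)/(2−2c))` to the standard normal. Williams' t (n−3 df) is
  selectable. The variant behind any given published p-value is usually
  unstated, so reproduction of such values is to tolerance, not bit-exact:
  on the triad (0.83, 0.76, 0.56) at n = 41 these variants give
  p = 0.332–0.334.
* Permutation oracle: swap the roles of the two non-shared variables
  within each participant uniformly at random, recompute Δr, two-sided
  add-one p. Under a simulated equal-correlation null its p-values are
  uniform, and Steiger's Z rejects at 5.0 ± 1.5% over 2000 null replicates
  at n = 41 (both computed in the test suite).
* All p-values are two-sided; no multiple-testing correction is applied;
  participants with any missing task mean are dropped listwise and n is
  reported. Degenerate triads (|r| = 1, e.g. duplicated columns) make the
  partial/comparison formulas undefined; `correlation_matrix` records them
  in a `degenerate` list rather than refusing the pairwise grid.

## 5. Pipeline objects and the recovery study (`pipeline`)

`CrossTaskModel.fit()` chains the stages deterministically; every number
in a `CrossTaskResults` report is reproducible from (input table, config,
seed), and the exclusion counts reconcile exactly with the input row
counts (asserted in tests). RT ratios are each task's mean yes-RT over the
NRT mean, reported to 4 decimals; the baseline-relative convention is used
because a difficulty ladder is most interpretable against the common
reference task.

`run_recovery_study` simulates n_replicates cohorts (≥ 50), runs the full
pipeline on each, and reports the distribution of the six pairwise
correlations and three partials, the frequency with which both adjacent
partials exceed the non-adjacent one, and the frequency with which the
non-adjacent partial is non-significant at α. Problem sizes used by the
shipped tests: 200 replicates at 41 participants for the ordering
frequency, one 500-participant cohort against the implied-correlation
oracle (tolerance ±0.05), 10⁵ walks for the Wald-equivalence checks.

**A limitation worth knowing.** Partialling out a *measured* control task
removes the shared decision component only up to the control's
reliability. In the degenerate architecture where every task loads on `d`
alone, the residuals after regressing on noisy NRT still share leaked
decision variance, and because leakage and residual noise shrink together,
the partials converge to roughly 0.5 rather than 0 no matter how small the
trial noise is (classic measurement-error attenuation). What distinguishes
the chain architecture is therefore not "partials = 0 under the null" but
the *adjacency ordering* of the partials — which is exactly what the
recovery study measures, and which is absent under the decision-only
model (tested).

## 6. Known limitations

* The engine models a single absorbing boundary; it does not fit choice
  probabilities or two-boundary diffusion parameters to data, and no
  RT-likelihood estimation is provided.
* The generative model is deliberately minimal: no phonology or
  morphology, no item effects, no trial-order dynamics.
* Steiger/Williams tests are asymptotic; at small n the permutation oracle
  is the safer reference and is provided for that purpose.
* Exact reproduction of any specific dataset's exclusion percentages can
  depend on SD conventions the pipeline exposes as flags but whose
  original values may be unknown.
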