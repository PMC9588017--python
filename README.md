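# lexichain

Simulation and correlation analysis of four-task speeded binary-decision
batteries that probe the hierarchy of reading: letter-level processing
(alphabetic decision, ADT), word-level processing (lexical decision, LDT),
sentence-level processing (grammatical decision, GDT), and a non-reading
baseline (animal/non-animal picture decision, NRT) used to partial out
generic binary-decision machinery.

The scientific question the package operationalises: if reading is organised
as a chain — letters feed words, words feed sentences, with no direct
letter-to-sentence link — then per-participant response times in tasks at
*adjacent* levels (ADT–LDT, LDT–GDT) should correlate more strongly than
tasks at *non-adjacent* levels (ADT–GDT), and once the shared decision
component (NRT) is partialled out, the non-adjacent partial correlation
should collapse. `lexichain` provides the full loop: a generative model of
such a battery, the standard trial-exclusion pipeline, the correlation
inference, and a parameter-recovery study showing the design can detect the
chain architecture at realistic sample sizes.

## The model

**Response times.** Each trial is a single-criterion random walk: evidence
starts at `start` (0), accumulates Gaussian increments with mean `drift`
(the rate of information accumulation) and SD `increment_sd` (0.05) per
step, and a response is made when the total first reaches `criterion` (10).
Gaussian increments make the walk Brownian motion observed at unit steps, so
first-passage times follow the Wald (inverse-Gaussian) law with

```
E[T]   = (criterion − start) / drift           (steps)
Var[T] = (criterion − start) · sd² / drift³    (steps²)
```

Task difficulty maps to drift: a flatter slope yields a slower mean *and* a
more spread-out, right-skewed RT distribution, the signature pattern across
the four tasks (drift grid 0.25 → 0.10, 10 ms per step).

**Participants.** Each participant carries four standardized latent
abilities: decision `d`, letter `l`, word `w`, sentence `s`. The reading
abilities form a Gaussian chain (`w ~ l`, `s ~ w`, with a direct `l → s`
path fixed at 0 by default — the hypothesis under test). Task drifts are
`base_drift · exp(Σ weights · abilities)` with loadings NRT←d; ADT←d,l;
LDT←d,l,w; GDT←d,w,s. Errors are Bernoulli overlays per task and stimulus
type; a small fraction of trials are anticipatory fast guesses.

**Inference.** Pearson r with t-tests, first-order partial correlations
(`r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))`), Steiger's Z (or
Williams' t) for comparing dependent overlapping correlations, and a
within-participant permutation oracle for validating them — all implemented
from the formulas. See `docs/methods.md` for every convention and default.

## Worked example

```python
import lexichain as lx

results = lx.CrossTaskModel.from_simulation(seed=7).fit()
print(results.summary())
```

```
Cross-task RT correlation analysis
==========================================================
participants retained: 48   (excluded: 0)

Descriptives (correct responses)
task      yes RT    (SE)     no RT    (SE)  yes err%  no err%
NRT          557    1.15       576    1.18      2.40     1.94
ADT          512    1.26       529    1.32      2.47     1.63
LDT          647    1.37       731    1.55      4.15     3.07
GDT         1173    2.70      1440    3.58      6.23    17.03

Mean yes-RT ratios vs NRT: NRT 1.00, ADT 0.92, LDT 1.16, GDT 2.10

Pairwise Pearson r (n = 48)
           NRT     ADT     LDT     GDT
NRT      1.000   0.713   0.735   0.734
ADT      0.713   1.000   0.823   0.678
LDT      0.735   0.823   1.000   0.839
GDT      0.734   0.678   0.839   1.000

Partial r controlling NRT:
  r(ADT,LDT|NRT) = 0.628   p = 2.242e-06
  r(ADT,GDT|NRT) = 0.325   p = 0.02596
  r(LDT,GDT|NRT) = 0.651   p = 7.352e-07

Dependent-correlation comparisons (steiger_z):
  r = 0.823 vs 0.839 (shared LDT): stat = -0.307, p = 0.7585
  r = 0.678 vs 0.823 (shared ADT): stat = -2.773, p = 0.005559
  r = 0.678 vs 0.839 (shared GDT): stat = -3.025, p = 0.002483
```

Reading the output: mean correct RTs rise with task difficulty (ADT < NRT <
LDT < GDT), yes-responses are faster than no-responses everywhere, and GDT
no-stimuli draw the most errors. The adjacent-level correlations (0.82,
0.84) exceed the non-adjacent one (0.68), the gap is significant under the
dependent-correlation tests, and after partialling out NRT the non-adjacent
partial (0.33) sits far below the adjacent partials (0.63, 0.65) — the
chain architecture leaves exactly the fingerprint it should.

The same analysis runs on any trial-level CSV with columns
`participant_id, task, trial_index, stimulus_class, response, correct,
rt_ms` via `CrossTaskModel.from_csv(path, column_map=...)`, or from the
shell:

```bash
lexichain simulate -c config.yaml -o trials.csv
lexichain analyze trials.csv -o report.json
lexichain recover -c config.yaml -o recovery.json   # 200-cohort recovery study
lexichain randomwalk --drift 0.25 --drift 0.1 -o walk.json
```

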