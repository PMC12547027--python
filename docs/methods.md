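# Methods

## Data model

All estimators consume one type: a `k x (k+1)` integer matrix of guess
counts, rows = randomized arms, columns = treatment guesses plus a final
IDK ("I don't know") column.  The guess at ordinal position `j` is by
definition the correct guess for the arm at position `j`; correctness is
positional, never string matching, so the same estimators serve 2x2, 2x3,
2x5-Likert and k-arm layouts.  Three scale tags cover the formats found in
practice:

* `binary` — the questionnaire offered no IDK option; the IDK column is
  present but all zero, so 2x2 data are an ordinary special case.
* `ternary` — guesses plus IDK (any number of arms).
* `likert5` — two arms with five response options (strongly/somewhat
  believe A, somewhat/strongly believe B, IDK); the raw 2x5 counts are
  retained alongside their side-collapsed ternary form.

Respondents removed by IDK exclusion are carried on the table
(`idk_excluded`) and surface in every report: analytical sample loss is
reported, never silent.  Respondents who decline to answer at all are out
of scope — they never enter the table, and no imputation is attempted.

## The three indices

**James (JBI).**  `JBI = [1 + P_D + (1 − P_D)·κ]/2` with
`κ = (P_O − P_E)/P_E`, where `P_O = Σ w_ij n_ij / N / (1 − P_D)` runs over
treatment-guess cells and `P_E` is its independence analogue
`Σ w_ij P_i·(P_·j − P_Dj)/(1 − P_D)²`.  Default weights: 0 correct, 0.5
incorrect, 1 IDK.  The k-arm generalization applies the same 0/0.5/1
weights to every incorrect cell; a full arm-by-guess weight matrix is
accepted (`WeightScheme(matrix=...)`) but no alternative default is
shipped, because any non-uniform choice is subjective.  Note that because
κ is a ratio, uniformly rescaling the incorrect weights is a no-op; only
asymmetric matrices change the index.

When `P_D = 1` (every response IDK) κ is 0/0.  The estimator returns NaN
with an `undefined` flag by default; `undefined_as_one=True` adopts the
convention that total uncertainty is perfect blinding (JBI = 1).  Both
readings are legitimate; explicitness is the default.  `P_E = 0` with
`P_D < 1` (conceivable only with degenerate custom weights) raises a
degeneracy error.

**Bang (BBI_A, BBI_B, sumBI).**  Per arm,
`BBI_j = (n_correct − n_incorrect)/N_j`, IDK kept in the denominator.  The
equivalent conditional form `[2·p_correct|answered − 1]·(answered/N_j)` is
computed alongside and asserted equal to 1e-12 — the forms diverge only
for an all-IDK arm, where the conditional form is 0/0 and the estimator
raises a degeneracy error rather than silently returning 0 (published
software disagrees on this case; we choose explicitness).  Variance is the
multinomial-contrast form `[p₁ + p₂ − (p₁ − p₂)²]/N_j`; `sumBI` adds the
two arm values and, arms being independent by randomization, the two
variances.  One-sided intervals (`sided="lower"/"upper"`) use
`z_{1−α}` with the unused bound at the range limit.  Designs beyond two
arms or 1:1 allocation are reported, not refused, with `multi_arm` /
`unequal_allocation` caveat flags.

**Simple (SBI).**  `SBI = p̂_A − p̂_B`, the between-arm difference in the
proportion guessing the *active* treatment, defined on 2x2 data; ternary
input is auto-reduced by IDK exclusion (flagged, counted).  The CI is the
Newcombe/MOVER hybrid of two Wilson score intervals: with per-arm Wilson
bounds `(l₁,u₁)`, `(l₂,u₂)`,
`(d − √((p̂₁−l₁)² + (u₂−p̂₂)²), d + √((u₁−p̂₁)² + (p̂₂−l₂)²))`.
This is the natural reading of "Wilson score method" for a difference of
proportions, and it reproduces every published SBI interval in the
bundled datasets at two decimals.  It is never zero-width on finite
samples and needs no symmetry.  Wilson intervals themselves come from
statsmodels.  No continuity-corrected or exact variants are offered.
SBI formula antisymmetry: reversing arm *order* negates the index;
relabeling which treatment is "active" (rows and columns together) leaves
it unchanged, since guessing-active and guessing-control differences
coincide on 2x2 data.

## Confidence intervals: numerical choices

* JBI: leave-one-respondent-out jackknife, variance
  `(N−1)/N·Σ(θ₋ᵣ − θ̄)²`, normal interval centered on the full-sample
  estimate (not the jackknife mean), truncated to [0, 1].  The jackknife
  is computed per occupied cell with count weights — removing any
  respondent of the same cell gives the same replicate — and is asserted
  (in the test suite) to equal the literal per-respondent loop.  A
  replicate that degenerates (e.g. empties the non-IDK mass) scores the
  all-IDK convention value and raises a warning flag; identical replicates
  give a zero-width interval, flagged.
* BBI/sumBI: normal intervals reported **untruncated** even when they
  spill past [−1, 1] / [−2, 2] — that is how such intervals are
  conventionally published, and truncating would hide the small-sample
  symmetry defect the zero-width/overshoot flags are meant to expose.
* Default `alpha = 0.05`, two-sided, everywhere.
* Text reports round to two decimals and normalize `−0.00` to `0.00`;
  JSON keeps full precision.

The closed-form (delta-method) James variance is deliberately not
implemented; the jackknife is the shipped method.  On the bundled
datasets the two agree at two decimals everywhere except one endpoint
each of the acupuncture and statin intervals (jackknife 0.35/0.79 vs
published 0.36/0.78), which the manifest notes and the regression suite
therefore excludes.

## Likert-format scoring

Five-point tables are collapsed by belief side (strong + somewhat) before
James and Simple scoring; a 5-level weighted James mode is not provided.
For Bang, two conventions circulate and both appear in published
analyses: plain collapse (default), and a weighted contrast in which a
"strongly" belief counts 1 and a "somewhat" belief 0.5 toward the
correct/incorrect side (`likert_weights=(1, 0.5)`), with variance
`[Σc²pᵢ − (Σcpᵢ)²]/N_j`.  The bundled statin dataset is reproduced by the
weighted convention, the spinal-manual-therapy dataset by the plain one;
the manifest records which applies to each.  The statin control arm is
reproduced by *neither* convention consistently (point by plain collapse,
interval roughly by the weighted contrast) and is excluded from the
regression as an unreproducible published cell.

Published `sumBI` values are occasionally the sum of the *rounded* arm
values (two bundled datasets differ from exact computation by 0.01 for
this reason, and are excluded), and no single variance convention
reproduces all published sumBI intervals — independent-sum matches some
exactly and misses others badly — so sumBI intervals are reported under
the independence rationale but not regression-tested.

## Interpretation rules

Ad-hoc cutoffs, labeled as such and never reduced to a bare verdict:
JBI > 0.5 suggests success, strengthened to "CI lower limit > 0.5" when it
holds; an interval containing 0.5 reads "random guess" (a CI-based rule is
reproducible where "point estimate ≈ 0.5" is not).  BBI magnitudes are
held against 0.2 (stringent, default) or 0.3, sign separating
correct-guess excess from opposite guessing; BBI = 1 with a zero-width CI
is labeled "complete correct guessing within arm; see study-level
indices", since comparable same-guess proportions in both arms can rescue
the study-level picture.  No cutoff exists for SBI ("no interpretation
guidance available") or sumBI, and none is invented.  Labels are a pure
function of estimates and flags.  No p-values or hypothesis tests are
offered: point estimates and intervals are the inferential output.

## Simulator

A scenario is one multinomial probability row per arm (guesses + IDK) and
per-arm sizes; presets `all_idk`, `opposite_guess`, `random_guess`,
`same_guess_active` (both arms guess active with probability 0.8),
`unblinded` (0.8 correct per arm, 0.1 IDK) mirror the canonical
hypothetical scenarios.  Preset leakage/uncertainty rates are fixed
round numbers chosen to put the population indices well inside the
non-degenerate interior; they are study conditions, not tuning knobs.
Replicate `r` draws from `default_rng([seed, r])` — a counter-based
stream, so any replicate is reproducible in isolation and results do not
depend on execution order.

Population index values are obtained by evaluating the same index
formulas on expected counts `n_j·p_j`; on a table's own empirical
proportions this reproduces the sample estimates exactly (tested).
`coverage_experiment` reports per-index empirical CI coverage, mean bias,
and Monte-Carlo SEs, skipping and counting degenerate replicates.

What the simulator emulates: independent multinomial guessing with fixed
arm sizes under randomization.  What it does not: clustering by site or
interviewer, guess-outcome dependence, repeated within-respondent
assessments, non-response distinct from IDK, or drift in beliefs over
time.  Passing coverage/bias checks therefore validate the estimators
under the stated sampling model, not under those real-world violations.

Monte-Carlo problem sizes in the test suite: coverage at n = 200/arm with
2000 replicates (binomial MC error ≈ 0.005, against an acceptance band of
0.95 ± 0.02); bias monotonicity over n ∈ {50, 100, 200, 400, 800} at 1200
replicates each, with a 2·MC-SE slack on each successive comparison since
the linear-contrast indices are already unbiased up to noise.

## Known limitations

* The James closed-form variance is not implemented (see above).
* No exact, bootstrap, or small-sample CIs for any index.
* The three-arm disulfiram dataset's published James value (0.56) rests
  on an unpublished multi-arm weight matrix; the uniform-weight
  generalization gives 0.567 → 0.57, and the manifest excludes the cell.
* Multi-arm tables get the James index only; Bang and Simple require two
  arms (combine arms first, as the disulfiram example does).
* Timing of assessment is metadata: repeated guesses per respondent are
  not modeled.
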