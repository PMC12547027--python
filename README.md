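# blindindex

Estimation and interpretation of **blinding indices** for randomized
controlled trials.

After randomization, trial participants (or clinicians, assessors,
outcome adjudicators) can be asked which treatment they believe they
received — active (`A`), control (`B`), or "I don't know" (IDK).
Cross-tabulating these guesses against the true assignment gives a small
`k x (k+1)` count table, and the success of blinding can be estimated from
it.  `blindindex` implements the three indices in use for this purpose,
with point estimates, standard errors, confidence intervals, and
cutoff-based interpretation, for trial statisticians and methodologists:

* **James index (JBI)** — study-level disagreement beyond chance, scaled to
  [0, 1] with 1 = perfect blinding.  With cell weights `w_ij` (0 correct,
  0.5 incorrect, 1 IDK) and IDK proportion `P_D`:

  `JBI = [1 + P_D + (1 − P_D)·(P_O − P_E)/P_E] / 2`

  where `P_O` and `P_E` are the weighted observed and expected guess
  proportions; `(P_O − P_E)/P_E` is a kappa-like term.  Variance by a
  leave-one-respondent-out jackknife.  Handles two or more arms.
* **Bang indices (BBI_A, BBI_B, sumBI)** — per-arm correct-minus-incorrect
  guess proportions, `BBI_j = (n_correct − n_incorrect)/N_j` on [−1, 1]
  with 0 = perfect blinding, plus the study-level `sumBI = BBI_A + BBI_B`.
  Normal CIs from the multinomial-contrast variance
  `[p₁ + p₂ − (p₁ − p₂)²]/N_j`.
* **Simple index (SBI)** — between-arm difference in the proportion
  guessing the *active* treatment on 2x2 data (IDK excluded),
  `SBI = n_AA/(n_AA + n_BA) − n_AB/(n_AB + n_BB)`, with a
  Wilson-score MOVER (Newcombe) interval.  Robust to any allocation ratio.

The package also ships guess-table I/O (cross-tab and respondent-level
CSV, five-point Likert collapsing, arm combining, IDK exclusion with
explicit sample-loss reporting), fourteen bundled reference datasets
(seven canonical hypothetical scenarios and six real trials), a
multinomial scenario simulator with coverage/bias experiments, and a CLI.

## Worked example

```sh
blindindex fixtures --out fixtures/
blindindex compute --input fixtures/acupuncture.csv
```

```
Blinding assessment — 2 arms, N=63 (binary scale)
  arm A: n=42, IDK=0
  arm B: n=21, IDK=0

JBI = 0.44 (0.35, 0.52) [jackknife-normal, 95%]
    random guess (CI includes 0.5)
BBI_A = 1.00 (1.00, 1.00) [multinomial-normal, 95%]
    complete correct guessing within arm; see study-level indices
BBI_B = -0.81 (-1.06, -0.56) [multinomial-normal, 95%]
    opposite guessing within arm (BBI <= -0.2)
sumBI = 0.19 (-0.06, 0.44) [multinomial-normal, 95%]
    between-arm difference in same-guess proportions (a sum in form only); no established cutoff
SBI = 0.10 (-0.01, 0.29) [wilson-mover, 95%]
    no interpretation guidance available

Notes:
  - BBI_A: arms are not 1:1 (42/21); the Bang index assumes equal allocation — interpret with caution
  - BBI_A: zero-width CI from a normality-based variance of zero (all informative responses identical)
```

This acupuncture trial collected guesses without an IDK option.  Every
active-arm participant guessed "active" (BBI_A = 1, complete within-arm
unblinding, with the degenerate zero-width interval typical of
normality-based CIs), but 90% of the *control* arm also guessed "active":
the study-level sumBI (0.19) and SBI (0.10) show the arms barely differ —
a *same-guess* pattern, not a blinding failure.  The James index (0.44)
sits near its chance value of 0.5.  The three indices are complementary;
reports always carry estimates and intervals, never a bare verdict.

The same pipeline is available as a library:

```python
import blindindex as bi

table = bi.fixtures.fixture("acupuncture")   # or bi.read_crosstab(path)
report = bi.analyze(table, alpha=0.05)
print(bi.render_report(report, "json"))
```

Other entry points: `bi.james_jackknife_ci`, `bi.bang_arm`, `bi.bang_sum`,
`bi.simple_ci`, `bi.collapse_likert`, `bi.combine_arms`, `bi.drop_idk`,
and `bi.coverage_experiment` for seeded Monte-Carlo experiments
(`blindindex simulate --preset unblinded --reps 2000 --coverage`).

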