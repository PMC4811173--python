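# Methods

## Model and assumptions

The classifier treats the lab-value curve of one medication episode as a
discrete-time biosignal on a daily grid.  Its premises:

* values are normalized to the patient-specific reference interval
  (`0` = lower bound, `1` = upper bound; values outside `[0, 1]` are
  meaningful and common in pathology);
* time is measured in whole days; sub-daily sampling is out of scope;
* each episode involves one drug, administered on a known set of days that
  lie inside the observation window;
* the relevant reactions are short-term — changes that begin during or
  shortly after the administration window.  Immediate (same-hour) reactions
  and late effects months after exposure are outside the design envelope;
* no information about the drug, the analyte or the patient is used, so the
  cascade cannot model confounders (co-medication, underlying disease).  A
  detected temporal correlation is *not* a causal claim; its intended use
  is screening — in particular, excluding clearly unchanged curves from
  manual expert review, which is why the specificity of the *no change*
  class is treated as the critical quality measure.

The cascade itself is a fixed sequence of 18 heuristic tests (see the
README for the step layout).  Sequential short-circuiting is essential:
an episode that receives a label drops out, so later tests only ever see
curves that every earlier test declined to classify.

## Phase partitioning

Pre-phase: observation days strictly before the first administration;
mid-phase: days from the first administration to the last, both inclusive
(so a single administration day yields a non-empty mid window); post-phase:
days strictly after the last administration.  Phases are defined over
observation days only — an administration day without a lab observation
still bounds the phases but contributes no value.  The main-loop and
post-chain tests that compare "pre" against "later" pool the mid- and
post-phase values.

## Numerical choices

**Gap filling.**  Convolution-type operations need contiguous samples, so
missing days are filled with zeros carrying weight 10⁻⁶ (observed samples
carry weight 1).  Every fit and mean downstream is weighted, which makes
the fillers numerically irrelevant; raising the gap weight to 10⁻⁴ changes
no classification on the synthetic suite (asserted by a test), consistent
with the original calibration of the algorithm, where results only began to
vary near 10⁻³.

**Fits and residuals.**  Constant and linear fits are weighted least
squares solved in closed form; for these models the closed-form optimum
coincides with the Levenberg–Marquardt optimum (asserted against
`scipy.optimize.least_squares(method="lm")` in a test).  The fit-quality
statistic is the weighted RMS deviation `sqrt(Σ wᵢ(yᵢ−ŷᵢ)²/Σ wᵢ)`.  RMS was
chosen over maximum deviation because single spikes are handled separately
by the outlier-removal pass; tolerances are therefore in normalized
lab-value units.

**Main-loop step 1 (ML1).**  "Constant in the pre-phase but no longer in
mid/post" is operationalized as: the constant fitted to the pre-phase has
residual ≤ `constant_fit_tol` **and** the mid/post values deviate from that
*pre-phase level* by more than the same tolerance.  (Fitting a fresh
constant to mid/post instead would declare a clean level shift "still
constant" and route it to the mid/post-linear test — the opposite of the
intended reading.)

**Smoothing.**  One-dimensional Gaussian low-pass, σ = 1.5 days, truncated
at 4σ, reflective boundary handling (`scipy.ndimage.gaussian_filter1d`).
The filter runs on the gap-filled series — weights cannot enter a
convolution — so the 10⁻⁶-weighted zeros are smoothed along with the data;
at the default gap weight the error this introduces is negligible.  Both
smoothed passes (steps 6–9 and 10–13) use the same σ; nothing suggests a
per-pass bandwidth, and one σ keeps the parameter space small.

**Outlier removal.**  The two observed values deviating most (in absolute
terms) from the median of the observed values are replaced by that median.
Exactly two values are always replaced, even if the second barely deviates;
ties are broken in favor of the earliest day.  Gap fillers are excluded
from the median and never replaced.

**Edge detection (steps 14–15).**  Per phase, a weighted line is fitted to
the low-pass values; slope > `slope_threshold` (per day) is *rising*,
< −`slope_threshold` *falling*, else *flat*.  Phases with fewer than two
samples count as flat, so the chain degrades gracefully on empty phases.
All three phases are evaluated, then the two rules are applied: pre-edge
with flat mid and post → *no change*; pre-edge with a mid or post edge →
*no assessment*.

**Step 16** tests the outlier-removed (not low-passed) observed values:
if no value deviates from their mean by more than `mean_dev_tol`, the curve
is *no change*.  **Step 17** tests the gap-filled raw values for strong
alternation: consecutive differences with magnitude > `zigzag_amp` are
kept, and the curve zig-zags iff there are at least three of them and the
fraction of sign alternations between successive kept differences is at
least `zigzag_frac`.  Caveat: for a curve that survives to step 17 *and*
has gaps *and* runs at a high level, the inserted zeros could mimic
alternation; such curves do not occur in the synthetic corpus, and the
amplitude threshold suppresses the effect at ordinary levels.

**Degenerate episodes.**  Fewer than three observed values do not allow an
assessment (no fit, no outlier removal): the result is *no assessment* with
`step = None` and a degenerate-input marker in the trace, outside the
numbered cascade.

**Main-loop skipping.**  ML1 and ML4 need at least `min_pre_points`
observed pre-phase values (default 2) and at least one later value; ML2/ML3
need two observed values.  A test whose data requirements fail is skipped —
recorded in the trace, never fired — and the cascade continues.

## Parameters

| parameter | default | unit | role |
|---|---|---|---|
| `constant_fit_tol` | 0.08 | normalized units (RMS) | constancy of pre-phase / departure from the pre level (ML1) |
| `linear_fit_tol` | 0.08 | normalized units (RMS) | linearity of the whole or mid/post curve (ML2, ML3) |
| `mean_diff_tol` | 0.3 | normalized units | minimal pre vs. mid/post mean difference to call a change (ML1, ML4) |
| `slope_threshold` | 0.1 | normalized units / day | minimal fitted slope of a low-passed phase to call an edge (steps 14–15) |
| `zigzag_amp` | 0.5 | normalized units | minimal step magnitude counted as an alternation (step 17) |
| `zigzag_frac` | 0.8 | — | minimal fraction of sign alternations (step 17) |
| `mean_dev_tol` | 0.3 | normalized units | maximal deviation from the mean for *no change* at step 16 |
| `gaussian_sigma` | 1.5 | days | low-pass bandwidth |
| `gap_weight` | 10⁻⁶ | — | weight of artificial gap fillers |
| `min_pre_points` | 2 | observations | minimal pre-phase size for mean/constancy tests |
| `no_change_if_in_reference_range` | off | — | optional step-1 pre-check |

σ and the gap weight are the two values fixed by the algorithm's original
description; the remaining tolerances are open calibration parameters.  The
defaults above were fixed by a one-time calibration against the synthetic
archetype suite: the fit tolerances (0.08) sit above the designed
observation-noise level (SD 0.05, whose RMS a 20-point series approaches)
so that noise alone cannot flip a constancy or linearity verdict, while
staying well below the designed effect sizes (≥ 0.4); `mean_diff_tol` (0.3)
separates the smallest designed mean shift (0.4) from the mean wobble of
unshifted noisy curves; `slope_threshold` (0.1/day) separates the designed
pre-phase transients (0.15–0.25/day after smoothing) from the near-zero
fitted slopes of undulating plateaus.  The calibration was not revisited
afterwards.  A consequence worth knowing: a bare ±1 zig-zag (e.g.
alternating 0/2) is flattened so effectively by the σ = 1.5 filter that the
smoothed curve passes the 0.08 linearity tolerance and is classified
*no change* at step 7; the zig-zag branch (step 17) catches stronger
alternations (the suite uses ±1.8).

## The synthetic corpus

`generate_labeled_suite` builds 58 episodes from 16 parametric archetypes
(3 seeded replicates each, plus extras for the most common clinical
shapes): flat, level shift at drug start, linear trend, linear after
admission, pre-phase edge with and without a later edge, low-noise flat,
zig-zag, isolated outlier pair, gapped level shift, in-reference-range
shift, noisy mean shift, noisy mid-phase ramp, outlier-masked level shift,
pre-phase outlier over a shifted plateau, outlier-contaminated ramp, small
smooth wiggle, and an irregular two-tone wiggle.  Each archetype carries
the label the default-parameter classifier must produce and the set of
cascade steps allowed to produce it; together they route through steps
{2, 3, 4, 5, 7, 8, 10, 11, 12, 13, 14, 15, 16, 17, 18}.  Steps 6 and 9
(the mean-difference tests of the smoothed pass) fire only for curves whose
phase-mean difference straddles the tolerance before and after smoothing —
a knife-edge region that corpus-level archetypes cannot occupy robustly, so
those two branches are exercised by direct unit tests of the main loop
instead.

Episodes are 19–40 daily observations; effects are 0.4–3 normalized units;
intrinsically noisy archetypes use Gaussian observation noise with SD
0.08–0.12; gapped archetypes drop named days from the grid.  The generator
is deterministic given its master seed and emulates the features the
cascade keys on: level shifts, trends, transients, alternation, isolated
outliers, interrupted series.  It does **not** emulate pharmacokinetic
profiles, analyte-specific dynamics, irregular (non-daily) sampling,
reference-interval drift, or co-medication — so a perfect score on the
suite shows that the cascade's branches behave as designed, not that the
default tolerances are optimal for any particular clinical corpus.
Recalibration against an expert-assessed corpus is expected for production
use, keeping the *no change* specificity high (a false *no change* hides a
potentially relevant curve from review).

## Evaluation machinery

The evaluation module reproduces the validation arithmetic used for this
class of screening algorithms: a 3×3 confusion matrix (algorithm ×
reference); one-vs-rest sensitivity and specificity per class (zero
denominators yield flagged NaNs); the per-step classification histogram
with percentage deltas (percentages rounded to two decimals *before*
differencing, matching the printed convention of the published tables, with
the mean reported alongside the population SD, minimum and maximum over
steps 2–18 — step 1 is excluded while the pre-check is disabled); and the
review-reduction fraction (share of episodes labeled *no change*).

Applied to the published validation counts of the original study, these
definitions reproduce the printed sensitivities (0.777 / 0.932 / 0.170) and
two of the three specificities (0.967 / 0.960) exactly; for the
temporal-correlation class the published matrix forces a specificity of
190/267 = 0.712, whereas the published table prints 0.803 — a value
identical to the study's concordance score and not reproducible from the
matrix under any definition consistent with the other five cells.  The
acceptance suite computes and documents this discrepancy rather than
special-casing it.

The concordance score — the scalar agreement measure of the expert-corpus
methodology — is pluggable: `concordance_score(..., strategy=...)` accepts
the corpus methodology's exact weighting when available.  The shipped
default is the plain agreement fraction, which satisfies the score's
contract (range `[0, 1]`, 1 on identical classification vectors, symmetric)
but is not guaranteed to equal the original partial-credit definition on
disagreeing vectors.

## Problem sizes

The test and acceptance runs use the 58-episode synthetic corpus (plus a
noisy variant of the same size) and the published 400/502-episode count
tables; the whole suite completes in a few seconds.

## Known limitations

* The cascade is a fixed heuristic: it has no notion of uncertainty, no
  confounder handling, and its thresholds interact (a curve rescued from
  one trap can fall into the next).
* Tolerances are global across the three passes; per-pass overrides are
  possible through separate `AlgorithmParameters` instances but not
  plumbed through a single run.
* The default concordance strategy is agreement fraction (see above).
* Very short episodes (< 3 observations) are never assessed, by design.
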