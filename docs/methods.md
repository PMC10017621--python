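# Methods

## Scope and model

`surgagree` implements (1) a machine-readable hierarchical annotation schema
for surgical workflow — *phases* (first-level temporal components executed
sequentially) composed of *steps*, with *facultative* elements that may
legitimately be absent from an individual procedure — and (2) a complete
two-rater reliability evaluation for temporal annotations made under such a
schema. The packaged instance describes laparoscopic Roux-en-Y gastric
bypass (LRYGB): 12 phases and 46 steps. All metrics depend only on label
identity, never on name text, so the schema can be re-authored for any
procedure.

An annotation is a set of labeled half-open intervals `[start_ms, end_ms)`
in integer milliseconds, one track per level. Before comparison a track is
**totalized**: un-annotated time is filled with a reserved `idle` label so
the track tiles `[0, duration_ms)` exactly. This is a convention of this
package — whether clinical raters annotate gap-free is generally unknown —
and it makes the metrics well defined on the whole timeline. When two raters
of one video disagree on total duration, both tracks are totalized onto the
maximum.

## Classical time-weighted metrics

The duration-weighted confusion matrix `C[a,b]` is the number of
milliseconds on which the reference carries label `a` and the other track
label `b`. It is accumulated by a sweep over the merged interval boundaries
of both tracks, which is exact integer arithmetic and provably equivalent to
dense 1 ms sampling (the test suite verifies this equivalence against a
brute-force rasterization oracle on randomized tracks). From `C`:

* accuracy = trace / total;
* per-class precision `C[c,c]/colsum(c)`, recall `C[c,c]/rowsum(c)`,
  F1 = harmonic mean; zero-denominator values are 0 by convention, which
  penalizes hallucinated or omitted classes deterministically;
* Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` with `p_o = trace/total` and
  `p_e = Σ_c rowsum(c)·colsum(c)/total²`. When `p_e = 1` (both raters spent
  the whole video on a single identical label) kappa is undefined and
  reported as `None`; aggregation skips undefined values and records how
  many contributed. `κ ≤ accuracy` always holds, with equality iff
  `p_e = 0`.

**Averaging scheme.** Macro averaging over the union of classes present in
either track, with idle as an ordinary class, is the default
(`macro-present`). It is the only scheme under which per-video values are
comparable across videos containing different facultative phases.
`macro-all` (every ontology label) and `micro` (pooled; equals accuracy)
are available.

**Symmetric protocol.** Two human raters are interchangeable, so each track
is treated once as ground truth and the two metric sets are averaged
element-wise. Swapping roles transposes the confusion matrix, hence
accuracy and kappa are direction-invariant, and symmetric-averaged macro
precision equals symmetric-averaged macro recall *exactly* — which is why
reliability tables produced this way show identical precision and recall
columns.

## Transition (application-dependent) metrics

Every label change on the totalized timeline is a **transitional moment**
(idle participates like any label: an un-annotated gap produces two
moments).

* **Matching.** Annotated and real transitions are matched one-to-one:
  first, pairs sharing the same `from → to` signature, greedily by smallest
  absolute delay; then the remainder, greedily by smallest absolute delay
  regardless of signature. No time window is imposed at the matching stage;
  the relaxation threshold enters only the relaxed metrics. An exhaustive
  minimum-total-|delay| assignment (via `scipy.optimize.
  linear_sum_assignment`) serves as the test oracle on small instances.
* **Average transitional delay (ATD)**: mean matched delay in seconds,
  signed by default (`annotated − real`; positive = late). An absolute mode
  is provided; note that the signed ATD averaged over both ground-truth
  directions is identically ~0, since swapping roles negates every delay —
  per-direction values are therefore retained in every report.
  *Sensitivity*: when raters disagree structurally (inserted or omitted
  segments), the forced cross-signature matches contribute |delays| on the
  scale of minutes and dominate the mean. The per-direction diagnostics
  therefore also carry an ATD restricted to corresponding (same-signature)
  pairs, which reflects pure boundary disagreement.
* **Coefficient of transitional moments (C_TM)**: `100 × annotated/real`
  transition counts; undefined when the reference has no transitions.
* **Noise level (NL)**: percentage of annotated segments (maximal
  same-label runs, idle excluded) with zero temporal overlap with any
  reference segment of the same label. Segment-count weighting is used;
  "proportion of annotated phases or steps" could also be read as
  time-share, and the segment-count reading was chosen and fixed here.
* **Relaxed metrics.** A millisecond with reference label `g` and annotated
  label `p ≠ g` is credited to the diagonal of `g` when it lies within
  `δ` of a reference transition and `p` equals the reference label adjacent
  to that transition (before or after; configurable to one side only).
  The default `δ` is 5 s — appropriate when the downstream use is, e.g.,
  remaining-time estimation; real-time decision support would need a
  smaller `δ`. At `δ = 0` the relaxed metrics equal the classical metrics
  exactly; they are monotone non-decreasing in `δ` and never below the
  classical values. AD metric sets apply the same symmetric protocol.

All per-video metrics are computed independently at phase and step level;
cohort summaries are unweighted means with sample (n−1) SD over videos, and
a pooled "overall" row averages over all videos rather than over cohort
means.

## Synthetic cohorts

The paper-scale clinical datasets behind reliability studies of this kind
are typically not deposited, so the package ships a generator whose role is
to make every metric testable by **parameter recovery**, not to model
annotator cognition.

*Ground truth.* Phases appear in canonical order; facultative phases are
included by Bernoulli draw; durations are log-normal (positive,
right-skewed, matching the long tail of surgical durations; only means and
SDs are typically reported, so the family is this package's choice, with
CV 0.4 by default). Steps tile each phase with log-normal weight fractions;
facultative steps are included with a per-profile probability. Short idle
gaps separate phases.

*Shipped profiles.* `STRASBOURG_LIKE` (longer procedures: pouch creation
26 min, jejunojejunal anastomosis 24 min; omentum division/Petersen
closure/mesenteric closure included at 95/98/100 %) and `BERN_LIKE`
(shorter: 15/18 min; 36/16/21 %). The remaining facultative-phase
inclusion probabilities were calibrated once so the expected phase count is
exactly 10.0 and 8.0 per video, and step-inclusion probabilities so the
expected step count is ≈33 and ≈27 — the reported per-center means. The
resulting expected video durations are ≈108 and ≈73 min.

*Rater noise.* Per-track: (1) Gaussian boundary jitter (mean, SD; optional
absolute clip), with shifted boundaries clamped to preserve ordering and
≥1 ms durations — this clamping slightly biases recovery under extreme
jitter and is why recovery tests use moderate SDs; (2) per-segment label
substitution with a confusable (adjacent-in-ontology-order, or uniform)
label; (3) Poisson-count spurious insertions placed strictly inside an
original host segment with a different label, so each insertion adds
exactly two transitional moments and exactly one noise segment; (4)
omission of facultative segments (relabeled idle) with a per-segment
probability. One global seed fans out through `SeedSequence.spawn` to
independent per-video streams (truth, rater A, rater B).

The noise model is shared across levels, so it does not reproduce the
empirically larger step-level (vs phase-level) noise of clinical raters;
the shipped presets (`INTER_RATER_NOISE`, `INTRA_RATER_NOISE`) were chosen
once to produce boundary delays in the high-single-digit seconds range
inter-rater and roughly half that intra-rater.

*What passing recovery tests shows.* That the metrics measure what they
claim on data whose generating parameters are known: injected jitter mean
is recovered as signed directional ATD within Monte-Carlo error; injected
insertion counts are recovered exactly through the C_TM closed form
`100·(m+2k)/m` (m real transitions, k insertions) and the NL closed form
`100·k/n_ann` (n_ann annotated non-idle segments); jitter bounded below δ
yields perfect AD accuracy with imperfect classical accuracy. It does not
show that clinical raters behave like the noise model.

## Numerical and degenerate-case conventions

* All interval arithmetic is exact on integer milliseconds; no dense
  arrays are ever materialized by the library (only by test oracles).
* Undefined markers (`None`): kappa at `p_e = 1`; ATD with no matches;
  C_TM with no reference transitions; NL with no annotated segments.
  Aggregation skips and counts them (`n_defined`).
* Single-video cohorts report SD 0 with `n_defined = 1` flagging the
  degeneracy.
* Hierarchy violations (step time outside its parent phase) are warnings,
  not errors: the metrics treat the two levels independently.
* Matching tie-breaks: equal |delay| pairs are ordered by earlier real,
  then earlier annotated time.

## Problem sizes

Default test and acceptance runs use randomized tracks up to 10 min at
1 ms resolution for oracle equivalence (200 pairs), 100 random pairs for
the symmetry suite, and 50-video cohorts for parameter recovery; the
acceptance script evaluates three 10-video cohorts. These sizes give
Monte-Carlo standard errors well below the asserted tolerances while
keeping a full run in the order of seconds.

## Known limitations

* Single parentage: the schema assumes each step belongs to exactly one
  phase.
* The matching procedure is a concretization chosen here (the literature
  it descends from does not fully specify it); the exhaustive-assignment
  oracle bounds its behaviour only on small instances.
* NL counts segments, not time; a time-share variant would weight long
  spurious segments more heavily.
* The generator produces strictly ordered phases and cannot emulate
  interleaved or repeated phases (e.g. returning to hemostasis late in a
  procedure).
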