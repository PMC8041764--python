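# Methods notes

These notes document the models, scoring conventions, numerical choices and
known limitations of `ocsplus`, in the spirit of a statistical package's
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Data model

A session is a versioned JSON document (`ocsplus-session/1`) holding ten
subtask blocks in administration order. Events carry a trial index, a
stimulus identifier, an optional response value, a ternary correctness flag
(true / false / unscored), a millisecond timestamp relative to session
start, and optional tap coordinates (screen pixels, origin top-left,
y downward). Timestamps must be non-decreasing within a block and trial
indices unique. A skipped block must carry a reason and no events; skipped
subtasks propagate *not assessed* downstream — never zero. Durations are
always derived from timestamps, never stored redundantly. Audio is
referenced by an optional pointer only; no payloads. The tablet's native
export format is not parsed; sessions enter through this schema.

Every measure name in the package resolves against a single registry
(`ocsplus.registry`) fixing its range, direction of impairment, cut-off
method and domain membership. Cohort CSVs are validated against it: empty
cells become explicit missing values, out-of-range scores are rejected with
the row and measure named, and per-measure Ns downstream always count
non-missing rows.

## 2. Scoring conventions

* **Choice tasks** (picture naming, semantics, orientation, episodic
  recognition): count of correct responses out of 4.
* **Word memory**: the five-word target list is fixed (bicycle, mist,
  wardrobe, teacher, rectangle; translations configurable). Words match by
  exact case-folded, trimmed string equality — no fuzzy matching, since
  misspelled near-misses cannot be adjudicated automatically; duplicates
  collapse (set semantics). The two encoding attempts are scored
  independently. Delayed recall is 0–5; forced-choice recognition is
  offered only for missed words, and a recognition outcome supplied for a
  freely recalled word is an error. The combined total never falls below
  free recall.
* **Trails**: the two baseline trails have 7 connections each; the
  switching trail length is configurable with a default of 13 connections
  (`TrailsConfig.switch_max`) — a package choice, flagged prominently,
  since only the baseline length is part of the fixed task description.
  The executive score is the ratio of the switching proportion to the
  summed-baseline proportion, ×100, capped at 100 (the observed healthy
  range is 0–100 with a near-ceiling median; the cap is configurable).
  Processing speed divides total baseline time by the baseline accuracy
  proportion with the combined maxima (14) as denominator, so connecting
  only a few shapes quickly does not masquerade as fast processing. A
  baseline proportion of zero yields an explicit *unscorable* result, not
  infinity.
* **Rule finding**: 46 scoreable anticipation trials across 5 rule
  segments (default layout 9+9+9+9+10; configurable), excluding the trial
  immediately after each rule change. A rule counts as learned when at
  least two consecutive scoreable guesses within its segment are correct.
  Excluded trials neither count toward nor break a run — the run-spanning
  ambiguity is resolved in favour of the participant and is configurable
  via `RuleFindingConfig.consecutive_needed` and the sequence layout.
* **Figures**: 20 elements × binary (presence, position, accuracy) = 0–60
  per drawing, identically for copy and recall. Element sub-scores are
  binary because no partial-credit scheme is defined for them; no automatic
  image analysis is attempted — element scores are human- or
  simulator-supplied, and figure measures without element scores are
  reported *unscored* (greyed in the report).
* **Cancellation**: taps are hit-tested against axis-aligned bounding
  boxes from a layout config (30 targets required); taps outside every box
  are ignored, overlapping boxes resolve to the smallest box (ties by
  layout order). Hits are distinct targets selected. Distractor selections
  are false positives (feedback condition); repeat selections of an
  already-found target are correct revisits (no-feedback condition).

## 3. Normative cut-offs and classification

Wide-range measures (trails, rule finding, figures, cancellation
accuracies) use the one-tailed z rule, mean ± 1.65·SD; restricted-range
measures use the empirical 5th/95th percentile of the uncorrected sample
distribution. The quantile estimator is the inclusive linear-interpolation
percentile (numpy's default, "type 7"), fixed and documented because the
choice is consequential at small n. Cut-offs are rounded half-up to 2
decimals (integers for centile cut-offs on integer measures, matching how
such tables are printed) and classification compares against the rounded
value. Error counts whose 95th percentile is 0 receive the conservative
"≥ 1" rule; the rules-learned cut-off is inclusive ("≤ c") with a floor of
1 for the same reason.

Age bands are <60, 60–70 and >70 years. Ages exactly 60 and 70 are
assigned to the middle band; the boundary is configurable
(`assign_age_band(..., middle=...)`) because band edges are a convention,
not a property of the data. Banded classification falls back to the pooled
row when a band row is absent, and a measure missing from the table is
classified *not assessed* with a warning — never silently.

Per-measure row filters allow a measure's norms to be derived from a
subset of the cohort; the default filters figure-copy norms to the 'UK'
site when a site column is present, reflecting the situation where a
multi-site cohort shows a site difference on one task and the larger site
is normed alone. The mechanism is a generic `(column, value)` filter, not
nationality logic. Education-stratified norms are not implemented (the
data model retains the education band for users who have the cohorts to
support them).

Domain summative scores are signed sums: delayed memory = delayed recall +
recall-and-recognition (0–10); attention = feedback + no-feedback hits
(0–60); encoding = the two encoding attempts (0–10); naming/semantics =
picture naming + semantics (0–8); praxis = figure copy + recall (0–120);
executive function = rule accuracy + rules learned + executive score −
false positives. The executive combination is a declared default with
configurable weights (the published description of that domain lists its
constituents but not the exact formula, and its printed maximum is not
reconcilable with any simple sum, so the formula is stated here as the
package's own choice). Domain cut-offs are always derived from a user
cohort at the 5th centile — never hard-coded.

## 4. Psychometrics

* **Split-half reliability**: each iteration randomly partitions the items
  into two halves, correlates half sums across participants and applies
  Spearman–Brown; the estimate is the mean over iterations (default 5000)
  with a 2.5/97.5-percentile interval. "Bootstrapped split-half" is
  ambiguous between split-only and resample-then-split; split-only is the
  default and `scheme="bootstrap_split"` provides the resampling variant
  for sensitivity analysis. Zero-variance halves are skipped and counted;
  when more than half the iterations are degenerate the estimate is
  flagged uninterpretable — this is exactly the restricted-range/ceiling
  regime in which single errors whipsaw a 4-item task's consistency.
  Time-based measures with no item structure carry a declared reliability
  of 1 (an assumption flag, not a computed value).
* **Attenuation correction**: r_c = r/√(rel_x·rel_y), never clamped;
  |r_c| > 1 sets a flag (it indicates non-randomly distributed measurement
  error rather than a valid coefficient).
* **Wilcoxon signed-rank** (test–retest): zero differences discarded;
  exact null distribution below 20 non-tied pairs, continuity-corrected
  normal approximation above; two-sided. Effect size is the matched-pairs
  rank-biserial correlation. All-tied inputs return an explicit "no change
  detectable" result. The reliable change index is the Jacobson–Truax form
  with the baseline SD and the test–retest reliability (observed Pearson r
  between sessions unless supplied); it is zero at no change and
  antisymmetric in session order.
* **Mann–Whitney U** (cohort harmonisation): two-sided, with raw and
  Bonferroni-corrected significance per measure.
* **Validity tables**: Kendall tau-b (tie-corrected) over
  pairwise-complete observations; family-wise alpha thresholds are
  0.05 / (comparisons in that family), with family sizes counted from the
  mapping file rather than hard-coded. Corrected coefficients above 0.20
  in magnitude are marked as acceptable convergence.
* **Power of the validity design**: `correlation_power` simulates
  bivariate-normal samples and applies the Pearson t-test. The
  detectable-effect bound of a convergent-validity design is directional
  (a predicted positive association), so the default alternative is
  one-sided; analytically, a one-sided test at n = 159 and α = 0.05 has
  ≈78% power against ρ = 0.19 (Fisher-z approximation), consistent with an
  80%-power design bound, whereas a two-sided test would need ρ ≈ 0.22.
  Hypothesis tests elsewhere in the package are two-sided.

## 5. Synthetic data

The generator emulates a healthy-ageing normative cohort: restricted-range
tasks at ceiling (per-item success rates 0.82–0.97, declining mildly with
age band), wide-range measures as age-banded truncated normals rounded to
the registry grid, rare-event error counts (Poisson rates 0.03–0.15), and
trail speed coupled to accuracy through the proportional-accuracy formula
itself. Band weights (111/101/108 out of 320) and the default band
means/SDs follow the magnitudes typical of published healthy-ageing norms
for this kind of screen and are labelled illustrative — they are not
anyone's data. Retest pairs and external batteries use a Gaussian latent
model: the second session (or external score) is ρ-correlated with the
standardised first score, with measurement error consolidated on the
simulated side so the attenuation correction recovers the configured
latent coefficient; for tau-based round trips the Greiner relation
r = sin(πτ/2) maps tau back to the Pearson scale.

Sessions are *constructively* realisable: trial streams are built so the
scoring module recovers the intended scores exactly (e.g. the rule-finding
sequence places a consecutive correct block in each learned segment and
alternating correct responses in unlearned ones; feasibility of an
(accuracy, rules-learned) pair is checked against the segment layout and
infeasible intents raise). This makes the simulate → score → norm loop a
genuine end-to-end oracle.

What the generator does **not** model: cross-measure latent correlations
within a participant (measures are conditionally independent given the age
band), pathology profiles, fatigue/order effects, response-time
distributions beyond the trail totals, and real figure drawings. Passing
pipeline tests therefore demonstrates the correctness and calibration of
the machinery, not clinical validity on real populations.

Because bounded scores are generated by truncation and rounding, sample
SDs shrink slightly and 1.65·SD cut-offs sit a little closer to the mean
than in the untruncated ideal: truncated-normal analysis puts the expected
held-out flag rate at roughly 5–6% for the near-Gaussian measures
(processing speed, rule accuracy, figure recall) and the calibration tests
check the pooled empirical rate against a binomial band around the 5%
design level with that allowance stated up front. Ceiling-proximal
z-measures (cancellation accuracies, figure copy, executive score) cannot
flag ≈5% by construction — e.g. an SD of ~0.6 against a maximum of 30 —
and are deliberately outside the calibration check.

## 6. Problem sizes and determinism

Every stochastic routine takes an explicit seed (numpy `default_rng`) and
is bit-reproducible. The test suite and acceptance script use cohorts of
300–5000, 2000-replicate power simulations, and 200–500 split-half
iterations in unit tests (5000 is the API default) — sizes chosen so the
whole pipeline, including exhaustive 2^n enumeration oracles, runs in
seconds on a single CPU while keeping Monte-Carlo error well inside the
asserted tolerances.

## 7. Known limitations

* No diagnostic labels: output is impairment relative to norms, per
  measure and domain; allocating patients to clinical groups is explicitly
  out of scope.
* Figure scoring requires element scores from a human rater or the
  simulator.
* The published cohort-level coefficients (per-task alphas, validity
  coefficients, the site-comparison U statistic) depend on raw cohort data
  that this package does not ship; the machinery that would compute them
  is fully tested on synthetic stand-ins instead.
* The report "wheel" is emitted as structured JSON plus a text rendering;
  no raster image is produced.
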