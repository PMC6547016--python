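# Methods

## Problem setting

Ward patients deteriorate along trajectories that early warning scores
(EWS) summarise as an integer: each vital sign is banded, each band
carries a weight 0–3, and the weights are summed. The National Early
Warning Score (NEWS) treats supplemental oxygen as a binary item (0 on
room air, 2 on any oxygen), discarding the dose. This package implements
a graded alternative: estimate the fractional inspired oxygen
concentration (FiO₂) from the recorded delivery device and flow, band it
into four weights with data-derived cut-points, and substitute that item
into the chart (NEWS-FiO₂). The outcome against which both variants are
evaluated is the composite adverse event — in-hospital death or unplanned
ICU admission — within a 24-hour look-back window of each observation set.

## FiO₂ estimation

For variable-performance devices (nasal cannula, simple mask, reservoir
mask) the inspired fraction is modelled as the oxygen volume fraction of
the inhaled mixture: of the minute volume MV = RR × V_T, the supplied
flow F is pure oxygen and the entrained remainder is room air, so
FiO₂ = (F + 0.21(MV − F))/MV. The tidal volume is fixed at V_T = 0.45 L
per breath for every patient; MV therefore scales only with respiratory
rate. This is deliberately crude — real tidal volume varies severalfold —
and `tidal_volume_sensitivity` quantifies the effect over a 0.30–0.70 L
grid (0.05 L steps): at fixed flow the estimate falls monotonically as
the assumed V_T rises.

Behaviour classes, not device names, drive the computation: *formula*
(above), *prescribed* (fixed-performance/Venturi masks report their
charted fraction), *max* (high-flow nasal oxygen and NIV are assigned
1.0 — an acknowledged over-estimate that cannot disturb the banding,
since the top band already starts at 53%), and *room_air* (0.21). The
device → behaviour mapping ships with sensible defaults but is YAML
configuration, because observation charts differ between hospitals.

When flow exceeds minute volume the formula exceeds 1.0; the estimate is
clamped to [0.21, 1.0] and flagged (`clamped=True`) rather than rejected,
consistent with the ceiling treatment of the saturating modes.

## Eligibility and labeling

Admissions are the unit of analysis (repeat admissions are independent).
Filters, applied in order and tallied once per admission: age < 16 at
admission; stay under 24 h ending in event-free discharge (an admission
whose stay is cut short by the adverse event itself is retained); ward
period reached via ICU; no complete observation set. A complete set has
all of HR, RR, SBP, SpO₂, temperature, a consciousness level (AVPU
directly or via the GCS map) and the inhaled-gas fields. Conservation
holds by construction: retained + excluded = input.

The event time is the earlier of unplanned ICU admission and death (when
ICU admission precedes death, the ICU admission is the event). Each
complete observation with 0 < event_time − t ≤ 24 h is a positive and
carries its time-to-event; observations at or after the event are
dropped, not labeled negative, because post-event ward observations are
not part of a prediction task; everything else is a negative. The window
boundary is inclusive at exactly 24 h (`window_inclusive=True`) — the
more positive-generous reading of a "within 24 h" rule — and
configurable. The GCS→AVPU map defaults to 15→A, 9–14→V, 4–8→P, 3→U, a
common correspondence; it is configuration, since published conversion
tables vary.

## Band derivation

The three FiO₂ cut-points are found by a classification tree grown on the
single feature calculated FiO₂ against the event label: Gini impurity,
best-first growth (each step splits whichever leaf offers the largest
total impurity decrease), candidate thresholds at midpoints between
adjacent distinct values, stopping after three internal splits or when
the minimum-leaf constraint (default 1% of observations) binds. Ties in
gain break deterministically toward the lower FiO₂ cut, so no seed is
involved. Weights 0–3 are assigned in ascending FiO₂ order — the
clinical reading of "risk increases with oxygen requirement" — and a
diagnostic flags, but does not re-rank, non-monotone band event rates.

Greedy growth is not globally optimal: on noisy data the best-first tree
can differ from the exhaustive-search optimum over all cut triples. The
test suite therefore checks exact agreement with the exhaustive oracle on
most strongly banded small instances and near-optimality (total impurity
within 2% of the optimum) on all of them, plus exact equivalence with an
independent best-first tree implementation (scikit-learn,
`max_leaf_nodes=4`) as a cross-check.

Reported thresholds are rounded to one decimal on the percent scale;
internal values stay unrounded. Band-edge semantics are right-closed:
with cuts c₁ < c₂ < c₃ the bands are [0.21, c₁], (c₁, c₂], (c₂, c₃],
(c₃, 1.0], which reproduces one-decimal percent banding
(21–22 / 22.1–37 / 37.1–53 / >53 for the default cuts 0.22/0.37/0.53)
without gaps.

## Scoring

The default chart encodes the published 2012 RCP NEWS bands and is
shipped as configuration to be verified against the chart in force
locally. The consciousness item scores A→0, V/P/U→3. NEWS-FiO₂ *replaces*
the binary oxygen item with the band weight of the calculated FiO₂
(rather than adding a second oxygen item): the weight-2 band is by
construction score-neutral relative to NEWS, which anchors the two
variants to a common scale. Observations diluted to ≤22% (trace oxygen at
high respiratory rate) score 0, like room air. Structural maxima under
the default chart: 20 (binary variant) and 21 (graded variant, when the
top FiO₂ band replaces the binary 2).

## Evaluation

All primary metrics are observation-level. AUROC uses the Mann–Whitney
form with ties counted ½ (computed via average ranks, O(n log n)). The
95% CI is a stratified percentile bootstrap: positives and negatives are
resampled separately at their original sizes, preserving prevalence
exactly in every replicate; percentile (not BCa) intervals match the
plain resampling description of the analysis being reproduced; replicates
are ranked in batches for speed. Operating points use alert ⟺ score ≥
threshold; efficiency is the alert fraction of all observations, a
workload proxy. The AUROC-versus-window analysis shrinks the positive set
(time-to-event ≤ w) against a fixed negative set of event-free
observations — event observations outside the window are set aside, not
relabeled, an assumption the source analysis leaves open. The
admission-level summary aggregates by the maximum score over the stay,
another choice the source leaves unstated; both are documented here as
this package's conventions.

## Synthetic data

The generator emulates the structure, not the physiology, of an
acute-ward database. Study conditions (the defaults): 38% of admissions
receive oxygen; admission-level adverse-event rate 4% before FiO₂-band
scaling; ~25 observations per admission at uniform random times;
truncated-normal vital marginals HR 84 (18) bpm, RR 18 (4) /min, SBP
125 (23) mmHg, temp 36.7 (0.6) °C, and FiO₂ 47 (15) % within the oxygen
cohort; SpO₂ as 100 minus a right-skewed gamma deviate floored at 70 (no
published marginal exists); planted FiO₂ cut-points 0.22/0.37/0.53 with
per-band event-window probabilities 0.005/0.02/0.05/0.12. Event
admissions' observations in the final 24 h drift: HR and RR rise, SBP
and SpO₂ fall, and FiO₂ rises through the bands, scaled by
`drift_strength`. Oxygen device and flow are chosen by inverting the
dilution formula, so estimation round-trips the generator exactly.

Two generators serve different purposes. `generate_cohort` produces the
full admission/observation structure; its observation-level hazard is
dominated by the pre-event drift, so bands derived from its labeled
output sit *above* the planted cuts — a realistic confounding effect,
and the reason cut-recovery claims are tested on
`generate_banded_fio2_labels`, which plants the band hazard directly with
no drift. The banded generator draws FiO₂ from the oxygen-cohort marginal
(truncated normal, 47/15 on the percent scale) rather than uniformly:
under a uniform draw the lowest band (21–22%) holds only ~1.3% of
observations and its cut is statistically unidentifiable at the tested
sample sizes, whereas the cohort marginal keeps every band populated.

What passing tests on this generator do **not** show: performance on real
ward data, where vitals are correlated, observation cadence is
policy-driven and informative, measurement error is non-Gaussian, and the
oxygen-therapy population differs systematically. The synthetic results
demonstrate correctness of the machinery and the direction of the
graded-item advantage, not its clinical magnitude.

## Numerical and design choices

- FiO₂ is a fraction in [0.21, 1.0] internally; percentages appear only
  at I/O and reporting boundaries.
- Timestamps are timezone-naive local time (single-site EHR assumption).
- Duplicate (admission, timestamp) observation pairs are kept and flagged.
- Degenerate inputs fail loudly: single-class labels, out-of-range GCS or
  FiO₂, windows with no positives (reported as missing points), and
  thresholds with no alerts (PPV reported as missing) all produce typed
  errors or explicit missing values, never silent NaNs.
- Problem sizes in the test suite and acceptance script (200,000 banded
  observations for cut recovery; 100 × 200-replicate bootstrap coverage at
  n = 20,000; 2,500–3,000-admission cohorts end-to-end) are chosen so each
  statistical claim is comfortably powered while the whole suite runs in
  about a minute plus the coverage study.

## Known limitations

- The fixed-V_T assumption biases FiO₂ for patients with atypical tidal
  volumes; the sensitivity grid quantifies but does not correct this.
- Assigning 1.0 to high-flow nasal oxygen and NIV over-states FiO₂ for
  many such patients; it cannot change band membership (top band starts
  at 53%) but inflates within-band values.
- Calibration is out of scope: the scores are ordinal triggers, not
  probabilities.
- Patients on end-of-life pathways cannot be identified or excluded from
  either the synthetic cohorts or the data model.
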