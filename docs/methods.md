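# Methods

## The classification problem

A positive urine culture from a catheterized patient is *catheter-
associated bacteriuria* (by convention here including funguria). It is
CA-UTI — an infection that merits antibiotics — only when accompanied by
signs or symptoms compatible with urinary infection and not explained by
another cause; otherwise it is CA-ABU, for which antibiotics confer no
benefit. The two conditions share every laboratory feature of the urine
itself (bacterial growth, pyuria, odor, sediment, organism type), so a
correct classifier must rest entirely on the clinical-cue panel, and must
*ignore* the urine-centric cues clinicians habitually weight.

## The rule engine

`classify_case` evaluates, in order:

1. **Growth gate.** At least one isolate at or above `cfu_threshold`
   (default 10³ CFU/mL, inclusive). Laboratory counts are interval-
   censored: ">10⁵" is `[1e5, ∞)`, "<10⁴" is `[0, 1e4)`, ">10³–<10⁵" is
   `[1e3, 1e5)`, with the upper bound exclusive. Two policies resolve an
   interval against the threshold:
   - `permissive` (default): significant unless the entire interval lies
     below threshold — i.e. the report does not *exclude* significant
     growth. This is the clinically conservative reading for censored
     reports: a "<10⁴" culture can still represent ≥ 10³ organisms.
   - `lower_bound`: significant only when the interval's lower bound
     reaches the threshold (strict reading).
   Failing the gate yields `NO_CA_BACTERIURIA` and ends the trace.
2. **Qualifying symptoms.** A concordant cue qualifies when present,
   admissible, and unattributed:
   - *fever* is a temperature, canonical unit °C; it counts as present
     only at ≥ `fever_threshold_c` (default 38.0 °C, the conventional
     cutoff — the underlying guidelines do not fix a number);
   - *urgency, frequency, dysuria, suprapubic pain* are admissible only
     when the catheter was removed within the preceding 48 h
     (`local_symptom_gate`, default on): with a catheter in place these
     sensations are produced by the device itself. The published cue
     tables do not draw this qualifier explicitly while the case
     definition does, so the gate is configurable;
   - an `alternative_source` attribution (an explicit clinical assertion
     supplied in the input, e.g. fever attributed to pneumonia,
     leukocytosis to corticosteroids) *suppresses* a cue: it is reported
     in `suppressed_symptoms` but does not qualify. The engine never
     infers attributions — "work up another cause" is a human judgment
     the engine consumes.
3. **Diagnosis and treatment.** Any qualifying cue → CA-UTI, treated
   with a response-dependent duration (defaults 7 days prompt / 14 days
   delayed response; configurable, and flagged as defaults in the note).
   No qualifying cue → CA-ABU, "antibiotics not indicated".

Discordant cues are listed in `ignored_discordant_cues` and in
`discordant_cue_report` with one-line cautions, but by construction no
code path reads them when deciding: the invariance test flips random
subsets of all ten discordant flags across thousands of generated cases
and requires an unchanged diagnosis. Organism class (gram-negative,
gram-positive, fungal) is treated identically — it is stored, displayed,
and never consulted.

Degenerate inputs: a case with no isolates is a sterile culture
(`NO_CA_BACTERIURIA`); an empty cue panel is a legal record meaning no
findings documented (chart-review convention).

## Agreement statistics

Fleiss' generalized kappa is computed from the subjects × categories
count matrix by the standard formulas (per-subject agreement P_i, mean
P̄, chance agreement P_e = Σ p_j²). The standard error is the
Fleiss–Nee–Landis overall-kappa formula

    SE = √2 / (Σ_j p_j q_j · √(Nn(n−1))) · √[(Σ_j p_j q_j)² − Σ_j p_j q_j(q_j − p_j)]

chosen because it is the estimator implemented by the SAS MAGREE macro
that produced the reference confidence interval this package reproduces;
the simpler 1971 null-variance formula gives a different CI and is not
offered. Cohen's kappa is the unweighted pairwise statistic with the
Fleiss–Cohen–Everitt large-sample variance (cross-checked in tests
against `statsmodels.stats.inter_rater.cohens_kappa`; the package's own
implementation is the one used, statsmodels serves only as an
independent oracle). CIs are κ ± 1.96·SE clipped to [−1, 1].

Display rounding is half-away-from-zero — two decimals for kappa and CI,
whole percent for rates — matching how such tables are printed; all
internal arithmetic is full precision.

Interpretation bands are the standard Landis–Koch cut-points (< 0 poor;
≤ 0.20 slight; ≤ 0.40 fair; ≤ 0.60 moderate; ≤ 0.80 substantial; > 0.80
almost perfect). Published prose sometimes applies these labels
inconsistently (calling 0.80 "almost perfect" but 0.88 "substantial");
this package applies the boundaries mechanically.

Out of scope by design: weighted kappa, Krippendorff's alpha, bootstrap
intervals (asymptotic only).

## The synthetic world

`generate_cases` draws positive-culture episodes:

- the true label is Bernoulli(`prevalence`);
- each concordant cue is drawn with a class-conditional probability
  (higher given CA-UTI); each discordant cue with a *single* probability
  used for both classes, making "discordant cues carry no information"
  literally true rather than approximately so;
- fever temperatures, when febrile, are normal(39.2, 0.6) °C clipped to
  [38, 41], so every generated fever clears the default threshold;
- every case receives significant growth (1–2 isolates drawn from common
  uropathogens with interval counts at or above 10³ CFU/mL), because the
  population of interest is positive cultures;
- catheter status: removed-within-48 h with probability 0.25, otherwise
  in place (chronic in 30% of those) — enough mix to exercise the local-
  symptom gate;
- **truth = guideline diagnosis.** A true CA-UTI case is rejection-
  resampled (budget 1000 draws) until it has at least one admissible,
  unattributed concordant cue; in a true CA-ABU case every concordant cue
  that happens to be present is given an alternative-source attribution
  (the synthetic analogue of steroid-explained leukocytosis). The
  reference standard against which accuracy is measured is therefore the
  guideline classification itself, which is exactly the criterion the
  validation design uses; it also makes "algorithm-aided raters at ε = 0
  are perfectly accurate" a theorem of the setup rather than an empirical
  accident, which is what the simulation is meant to demonstrate.

Default cue probabilities live in `data/default_cues.json` and are
labeled illustrative: no quantitative cue prevalences or clinician error
rates are available to estimate them from, and no simulated statistic is
claimed to match any published large-sample kappa.

Simulated raters perceive each of the 20 cue flags with independent
misreading probability ε (a flipped fever materializes at 39.0 °C; a
missed fever erases the temperature). Heuristic raters apply a
non-negative cue-weight sum against a threshold — the minimal formalism
for a "mental model" understood as a set of cues that influence a yes/no
decision; algorithm-aided raters run the rule engine on the perceived
case. `run_experiment` scores per-rater accuracy, concordance with the
engine, pairwise Cohen kappas and overall Fleiss kappa, and every run is
a pure function of the integer seed (generation and each rater's
perception use separate child seed sequences).

A note on the futility of discordant-cue models: any rater whose weights
touch only discordant cues is statistically independent of the true
label, so their expected accuracy is q·π + (1−q)(1−π), where q is the
probability the weighted sum reaches threshold and π the prevalence.
This is at most max(π, 1−π), with equality only for a constant
(majority-class) prediction. The tests assert both facts: empirical
accuracy matches the closed-form expectation within binomial sampling
error, and never exceeds the majority-class ceiling.

## Problem sizes and numerical choices

Property tests use ≥ 1000 case×flip-mask combinations for discordant
invariance, 100 random matrices for kappa oracle equivalence (tolerance
10⁻¹²), and simulation checks at n = 5000 cases (futility), n = 1500 per
ε grid point (noise degradation, tolerance 0.05 on pairwise kappa), and
n = 2000 (prevalence calibration, central 99% binomial interval) — sizes
chosen so binomial noise is well below the effects being demonstrated
while the whole suite runs in seconds. Degenerate marginals (all ratings
in one category) raise an error rather than returning NaN. CSV round-
trips write floats at 17 significant digits and read with round-trip
float parsing so temperatures survive serialization exactly.

## Limitations

- The engine encodes the decision points the distilled case definitions
  name (growth gate, symptom check with alternative-source workup,
  response-dependent treatment duration); a deployed pocket-card
  flowchart may carry additional practical boxes (e.g. catheter
  replacement before re-culture) that are out of scope here.
- Cues arrive as structured flags; no parsing of free-text notes or EHR
  exports is attempted, and attribution judgments must be supplied.
- The synthetic world models cue panels as conditionally independent
  given the class; real signs cluster (fever with rigors, delirium with
  frailty). Passing simulation tests therefore demonstrates the
  engine's properties and the agreement machinery, not clinical
  performance on real cases.
- "Vague malaise" is treated as discordant even though some case
  definitions admit unexplained malaise/lethargy as a symptom; the cue
  table this package follows lists it as discordant.
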