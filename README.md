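# cautikit

Tools for classifying **catheter-associated bacteriuria** — distinguishing
catheter-associated urinary tract infection (**CA-UTI**, merits
antibiotics) from catheter-associated asymptomatic bacteriuria
(**CA-ABU**, antibiotics not indicated) — together with the inter-rater
agreement statistics used to validate such classification, and a
simulated-rater harness for studying how clinicians' "mental models"
affect diagnostic accuracy.

It is written for antimicrobial-stewardship and quality-improvement teams
who need to classify positive urine cultures from catheterized patients
reproducibly: the habitual cues clinicians reach for (pyuria, systemic
leukocytosis, foul-smelling urine, organism type, patient frailty) occur
in *both* conditions and therefore cannot separate them, which is why
unaided classification is inaccurate and inconsistent.

## What it does

**Rule engine** (`decision_algorithm`). A deterministic, auditable
distillation of the evidence-based case definitions:

1. *Significant growth*: any isolate with ≥ 10³ CFU/mL (interval-censored
   laboratory reports such as ">10⁵" or "<10⁴" are handled as intervals;
   the default `permissive` policy calls growth significant unless the
   whole interval lies below threshold).
2. *Qualifying symptoms*: any guideline-concordant cue — fever ≥ 38.0 °C,
   new-onset delirium, rigors, flank pain, acute hematuria, pelvic
   discomfort, or (within 48 h of catheter removal) urgency, frequency,
   dysuria, suprapubic pain — that is present and **not** attributed to an
   alternative source (e.g. fever explained by pneumonia).
3. *Diagnosis*: qualifying symptom → CA-UTI with a response-dependent
   treatment duration (7 days prompt / up to 14 days delayed response);
   none → CA-ABU, antibiotics not indicated.

Every classification returns a rule trace and the list of present
discordant cues that were deliberately ignored.

**Agreement statistics** (`agreement_stats`). Fleiss' generalized kappa
for N subjects × n raters with the Fleiss–Nee–Landis standard error

    κ = (P̄ − P_e) / (1 − P_e),   P_e = Σ_j p_j²,
    SE = √2 / (Σ_j p_j q_j · √(Nn(n−1))) · √[(Σ_j p_j q_j)² − Σ_j p_j q_j (q_j − p_j)]

plus Cohen's simple kappa with its asymptotic variance, concordance
rates against a reference standard, Landis–Koch interpretation bands, and
whole-percent tallies.

**Rater simulation** (`rater_simulation`). A synthetic-case generator in
which discordant cues are, by construction, equally frequent in both
classes (zero diagnostic information), and simulated raters that are
either cue-weighted linear classifiers ("mental models") or
algorithm-aided users of the rule engine, each with a per-cue perception
error rate ε.

## Worked example

Four packaged cases ship with the library (command: `cautikit fixtures`):

```python
>>> import cautikit as ck
>>> for case in ck.load_fixtures():
...     r = ck.classify_case(case)
...     print(case.case_id, r.diagnosis.value, dict(r.rule_trace)["qualifying_symptoms"])
case-1 CA-ABU none
case-2 CA-UTI fever, new_onset_delirium, acute_hematuria
case-3 CA-ABU none
case-4 CA-ABU none
```

Case 1 (>10⁵ CFU/mL *K. pneumoniae*, leukocytosis explained by
corticosteroids) is CA-ABU: its leukocytosis, pyuria and frailty are
discordant cues and the attributed finding is suppressed. Case 2
(gram-positive organisms at 10³–10⁴ CFU/mL, fever 103.3 °F with no other
source) is CA-UTI on fever. Cases 3 (polymicrobial growth, leg weakness
only) and 4 (>10⁵ CFU/mL *C. albicans*, no urinary symptoms) are CA-ABU.

Scoring a 10-rater diagnosis table against those guideline diagnoses:

```python
>>> m = ck.load_unaided_rating_table()
>>> k = ck.fleiss_kappa(m)
>>> k.rounded(2), k.band
((0.35, 0.21, 0.5), 'fair')
>>> c = ck.concordance_from_matrix(m, ["CA-ABU", "CA-UTI", "CA-ABU", "CA-ABU"])
>>> c.count, c.total, c.percent
(21, 40, 53)
```

Only 21 of 40 unaided diagnoses (53%) match the guideline standard, with
fair inter-rater agreement (κ = 0.35, 95% CI 0.21–0.50) — the level of
disagreement that motivates an explicit algorithm.

The same numbers from the shell:

```bash
cautikit agree src/cautikit/data/unaided_ratings.csv --method fleiss
# kappa = 0.35, 95% CI (0.21, 0.50), fair
cautikit simulate --n 500 --prevalence 0.4 --seed 7 --out summary.json
```

The simulation summary shows algorithm-aided raters at ε = 0 with
accuracy 1.0 and pairwise κ = 1, while a leukocytosis-weighted heuristic
rater stays near chance — discordant cues carry no information in the
generated world, so no weighting of them can help.

## Layout

- `src/cautikit/case_model.py` — case schema (pydantic), JSON/CSV I/O,
  packaged fixtures, rating-table reader
- `src/cautikit/decision_algorithm.py` — the rule engine
- `src/cautikit/agreement_stats.py` — kappas, concordance, bands, tallies
- `src/cautikit/rater_simulation.py` — case generator and simulated raters
- `src/cautikit/cli.py` — `cautikit {classify, agree, simulate, fixtures}`
- `docs/methods.md` — model assumptions, parameter choices, limitations
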