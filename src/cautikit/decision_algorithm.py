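"""Deterministic rule engine separating CA-UTI from CA-ABU.

The engine distills the evidence-based case definitions for
catheter-associated bacteriuria into an auditable decision sequence:

1. **Significant growth** — does any urine-culture isolate reach the
   colony-count threshold (default 10^3 CFU/mL)? If not, there is no
   catheter-associated bacteriuria to classify.
2. **Qualifying symptoms** — is any guideline-concordant sign or symptom
   present, admissible in context, and *not* attributed to an alternative
   source? Fever qualifies only at or above the fever threshold (default
   38.0 °C). Local urinary symptoms (urgency, frequency, dysuria,
   suprapubic pain) are admissible only within the post-removal window,
   because an indwelling catheter itself produces them.
3. **Diagnosis** — qualifying symptom present → CA-UTI (treat); none →
   CA-ABU (antibiotics not indicated).

Guideline-discordant findings (pyuria, leukocytosis, organism type, foul
urine, frailty, ...) are deliberately never consulted: they occur in both
conditions and carry no discriminating information. They are surfaced in
the result's ``ignored_discordant_cues`` and by ``discordant_cue_report``
so a user can see which habitual-but-uninformative cues were present.

Every classification returns a ``rule_trace``: the ordered list of
decision points visited and their outcomes, so any diagnosis can be
audited back to the rule that produced it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .case_model import (
    CONCORDANT_CUES,
    DISCORDANT_CUES,
    LOCAL_URINARY_CUES,
    BacteriuriaCase,
    CfuCount,
)


class Diagnosis(str, enum.Enum):
    CA_UTI = "CA-UTI"
    CA_ABU = "CA-ABU"
    NO_CA_BACTERIURIA = "NO-CA-BACTERIURIA"


class AlgorithmConfig(BaseModel):
    """Tunable thresholds of the rule engine.

    ``strict_growth`` controls how interval-censored colony counts meet the
    threshold: ``permissive`` (default) calls growth significant unless the
    whole reported interval lies below the threshold, which is what lets a
    "<10^4 CFU/mL" report still count; ``lower_bound`` requires the
    interval's lower bound itself to reach the threshold.
    """

    model_config = ConfigDict(extra="forbid")

    cfu_threshold: float = Field(1000.0, gt=0)
    fever_threshold_c: float = Field(38.0, ge=37.0, le=41.0)
    post_removal_window_h: float = Field(48.0, gt=0)
    strict_growth: Literal["permissive", "lower_bound"] = "permissive"
    local_symptom_gate: bool = True
    treatment_days_prompt: int = Field(7, ge=1)
    treatment_days_delayed: int = Field(14, ge=1)


DEFAULT_CONFIG = AlgorithmConfig()


@dataclass(frozen=True)
class TreatmentPlan:
    treat: bool
    duration_days_prompt_response: int
    duration_days_delayed_response: int
    note: str

    def __post_init__(self) -> None:
        if not self.treat:
            assert (
                self.duration_days_prompt_response == 0
                and self.duration_days_delayed_response == 0
            )
        assert self.duration_days_prompt_response <= self.duration_days_delayed_response


@dataclass(frozen=True)
class ClassificationResult:
    diagnosis: Diagnosis
    qualifying_symptoms: tuple[str, ...]
    suppressed_symptoms: tuple[str, ...]
    ignored_discordant_cues: tuple[str, ...]
    rule_trace: tuple[tuple[str, str], ...]
    treatment: Optional[TreatmentPlan] = None

    def to_dict(self) -> dict:
        return {
            "diagnosis": self.diagnosis.value,
            "qualifying_symptoms": list(self.qualifying_symptoms),
            "suppressed_symptoms": list(self.suppressed_symptoms),
            "ignored_discordant_cues": list(self.ignored_discordant_cues),
            "rule_trace": [list(step) for step in self.rule_trace],
            "treatment": None
            if self.treatment is None
            else {
                "treat": self.treatment.treat,
                "duration_days_prompt_response": self.treatment.duration_days_prompt_response,
                "duration_days_delayed_response": self.treatment.duration_days_delayed_response,
                "note": self.treatment.note,
            },
        }


def _cfu_significant(cfu: CfuCount, config: AlgorithmConfig) -> bool:
    threshold = config.cfu_threshold
    if cfu.exact is not None:
        return cfu.exact >= threshold
    if cfu.lower >= threshold:
        return True
    if config.strict_growth == "lower_bound":
        return False
    # permissive: significant unless the whole interval [lower, upper)
    # lies below threshold
    return cfu.upper is None or cfu.upper > threshold


def has_significant_growth(
    case: BacteriuriaCase, config: AlgorithmConfig = DEFAULT_CONFIG
) -> bool:
    """True iff at least one isolate's colony count meets the threshold."""
    return any(_cfu_significant(iso.cfu, config) for iso in case.isolates)


def qualifying_symptoms(
    case: BacteriuriaCase, config: AlgorithmConfig = DEFAULT_CONFIG
) -> tuple[list[str], list[str]]:
    """Split present concordant cues into qualifying vs suppressed.

    Returns ``(qualifying, suppressed)``: qualifying cues are present,
    contextually admissible and unattributed; suppressed cues are present
    and admissible but carry an alternative-source attribution. Cues gated
    off by context (local urinary symptoms with the catheter still in
    place; fever below threshold) appear in neither list.
    """
    qualifying: list[str] = []
    suppressed: list[str] = []
    cues = case.cues
    for cue in CONCORDANT_CUES:
        if cue == "fever":
            present = (
                cues.fever_temp_c is not None
                and cues.fever_temp_c >= config.fever_threshold_c
            )
        else:
            present = cues.cue_flag(cue)
        if not present:
            continue
        if (
            cue in LOCAL_URINARY_CUES
            and config.local_symptom_gate
            and not case.catheter.removed_within_48h
        ):
            continue
        (suppressed if cues.attributed(cue) else qualifying).append(cue)
    return qualifying, suppressed


def recommend_treatment(
    diagnosis: Diagnosis, config: AlgorithmConfig = DEFAULT_CONFIG
) -> TreatmentPlan:
    """Antibiotic recommendation for a diagnosis.

    CA-UTI merits treatment; the recommended duration depends on clinical
    response (defaults: 7 days with prompt response, up to 14 with delayed
    response). CA-ABU and non-significant cultures get no antibiotics.
    """
    if isinstance(diagnosis, ClassificationResult):
        diagnosis = diagnosis.diagnosis
    if diagnosis is Diagnosis.CA_UTI:
        return TreatmentPlan(
            treat=True,
            duration_days_prompt_response=config.treatment_days_prompt,
            duration_days_delayed_response=config.treatment_days_delayed,
            note=(
                f"treat {config.treatment_days_prompt} days with prompt response, "
                f"up to {config.treatment_days_delayed} days with delayed response "
                "(default durations; adjust to the patient's response to therapy)"
            ),
        )
    return TreatmentPlan(
        treat=False,
        duration_days_prompt_response=0,
        duration_days_delayed_response=0,
        note="antibiotics not indicated",
    )


def classify_case(
    case: BacteriuriaCase, config: AlgorithmConfig = DEFAULT_CONFIG
) -> ClassificationResult:
    """Run the full decision sequence on one case.

    Growth gate fails → ``NO_CA_BACTERIURIA``; otherwise ``CA_UTI`` exactly
    when at least one qualifying concordant symptom fires, else ``CA_ABU``.
    The result carries the ordered rule trace and the list of present
    discordant cues (which never influence the outcome).
    """
    trace: list[tuple[str, str]] = []
    ignored = tuple(c for c in DISCORDANT_CUES if case.cues.cue_flag(c))

    growth = has_significant_growth(case, config)
    trace.append(
        (
            f"significant_growth (>= {config.cfu_threshold:g} CFU/mL)",
            "yes" if growth else "no",
        )
    )
    if not growth:
        trace.append(("diagnosis", Diagnosis.NO_CA_BACTERIURIA.value))
        return ClassificationResult(
            diagnosis=Diagnosis.NO_CA_BACTERIURIA,
            qualifying_symptoms=(),
            suppressed_symptoms=(),
            ignored_discordant_cues=ignored,
            rule_trace=tuple(trace),
            treatment=recommend_treatment(Diagnosis.NO_CA_BACTERIURIA, config),
        )

    qualifying, suppressed = qualifying_symptoms(case, config)
    trace.append(("qualifying_symptoms", ", ".join(qualifying) if qualifying else "none"))
    if suppressed:
        trace.append(
            ("alternative_source_workup", "attributed elsewhere: " + ", ".join(suppressed))
        )
    diagnosis = Diagnosis.CA_UTI if qualifying else Diagnosis.CA_ABU
    trace.append(("diagnosis", diagnosis.value))
    return ClassificationResult(
        diagnosis=diagnosis,
        qualifying_symptoms=tuple(qualifying),
        suppressed_symptoms=tuple(suppressed),
        ignored_discordant_cues=ignored,
        rule_trace=tuple(trace),
        treatment=recommend_treatment(diagnosis, config),
    )


#: One-line cautions for each discordant cue, used in feedback output.
DISCORDANT_CAUTIONS: dict[str, str] = {
    "pyuria": "pyuria accompanies catheterization itself and does not distinguish CA-UTI from CA-ABU",
    "foul_smelling_urine": "urine odor reflects bacterial metabolism, not invasive infection",
    "urine_color_change": "urine color change is nonspecific and common with catheters",
    "urine_sediment": "sediment forms in catheterized urine regardless of infection",
    "systemic_leukocytosis": "leukocytosis is not a reliable cue for CA-UTI and often has another cause",
    "prior_uti_history": "a prior UTI label does not make the current bacteriuria symptomatic",
    "resistant_organism": "antimicrobial resistance does not make colonization an infection",
    "vague_malaise": "vague malaise is too nonspecific to attribute to bacteriuria",
    "weakness": "weakness is not a urinary-specific symptom and occurs in both conditions",
    "elderly_or_frail": "age and frailty raise colonization rates, not the probability of true infection",
}


def discordant_cue_report(case: BacteriuriaCase) -> list[tuple[str, str]]:
    """List each present discordant cue with a one-line caution.

    Intended for feedback output: shows the user which habitual cues in
    this case should *not* drive the CA-UTI vs CA-ABU decision.
    """
    return [
        (cue, DISCORDANT_CAUTIONS[cue])
        for cue in DISCORDANT_CUES
        if case.cues.cue_flag(cue)
    ]
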