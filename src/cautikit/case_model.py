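"""Clinical case data model for catheter-associated bacteriuria.

A case is one patient episode: the urine-culture isolates (with colony
counts reported as intervals, the way clinical laboratories print them),
the urinary-catheter status, and a panel of structured sign/symptom flags.
The flag panel is split into two fixed groups:

* *concordant* cues — signs and symptoms that evidence-based guidelines
  accept as pointing to catheter-associated urinary tract infection
  (CA-UTI): fever, new-onset delirium, rigors, flank pain, acute
  hematuria, pelvic discomfort, and — only after catheter removal —
  urgency, frequency, dysuria and suprapubic pain;
* *discordant* cues — findings clinicians commonly cite but that do not
  discriminate CA-UTI from asymptomatic bacteriuria (CA-ABU): pyuria,
  foul-smelling or discolored urine, urine sediment, systemic
  leukocytosis, prior UTI history, a resistant or particular organism
  type, vague malaise, weakness, and patient frailty.

A clinician may assert that a concordant cue has an alternative,
non-urinary explanation (e.g. fever from pneumonia, leukocytosis from
corticosteroids); such attributions are explicit inputs, stored per cue in
``ClinicalCues.alternative_source``, never inferred by the engine.

Missing cue flags default to absent (``False``): records follow
chart-review convention where absence of mention means absence of the
finding. Temperatures are stored in Celsius; Fahrenheit is accepted on
input only (field ``fever_temp_f``) and converted on parse.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import (
    CaseValidationError,
    DuplicateRatingError,
    RatingTableError,
    TemperatureConflictError,
)

SCHEMA_VERSION = "1"

#: Guideline-concordant cue names, in canonical order. "fever" is backed by
#: the ``fever_temp_c`` field (presence = a recorded temperature).
CONCORDANT_CUES: tuple[str, ...] = (
    "fever",
    "new_onset_delirium",
    "rigors",
    "flank_pain",
    "acute_hematuria",
    "pelvic_discomfort",
    "urgency",
    "frequency",
    "dysuria",
    "suprapubic_pain",
)

#: Guideline-discordant cue names: present in both CA-UTI and CA-ABU, hence
#: carrying no discriminating information.
DISCORDANT_CUES: tuple[str, ...] = (
    "pyuria",
    "foul_smelling_urine",
    "urine_color_change",
    "urine_sediment",
    "systemic_leukocytosis",
    "prior_uti_history",
    "resistant_organism",
    "vague_malaise",
    "weakness",
    "elderly_or_frail",
)

ALL_CUES: tuple[str, ...] = CONCORDANT_CUES + DISCORDANT_CUES

#: Local urinary symptoms that the guideline case definition admits only
#: within a window after catheter removal.
LOCAL_URINARY_CUES: tuple[str, ...] = (
    "urgency",
    "frequency",
    "dysuria",
    "suprapubic_pain",
)

OrganismClass = Literal["gram_negative", "gram_positive", "fungal"]


class CfuCount(BaseModel):
    """A colony count in CFU/mL, reported as an interval.

    Laboratory notations map to half-open intervals: ``>10^5`` becomes
    ``lower=1e5`` with unbounded ``upper``; ``<10^4`` becomes
    ``[0, 1e4)``; ``>10^3 - <10^5`` becomes ``[1e3, 1e5)``. ``upper`` is
    exclusive and ``None`` means unbounded above. An ``exact`` count sets
    ``lower == upper == exact`` (degenerate closed interval).
    """

    model_config = ConfigDict(extra="forbid")

    lower: float = Field(0.0, ge=0.0)
    upper: Optional[float] = Field(None, ge=0.0)
    exact: Optional[float] = Field(None, ge=0.0)

    @model_validator(mode="after")
    def _check_interval(self) -> "CfuCount":
        if self.exact is not None:
            if (self.lower not in (0.0, self.exact)) or (
                self.upper is not None and self.upper != self.exact
            ):
                raise ValueError("exact count conflicts with interval bounds")
            object.__setattr__(self, "lower", self.exact)
            object.__setattr__(self, "upper", self.exact)
        elif self.upper is not None and self.lower > self.upper:
            raise ValueError(
                f"inverted CFU interval: lower={self.lower} > upper={self.upper}"
            )
        return self


class OrganismIsolate(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    organism_class: OrganismClass
    cfu: CfuCount


class CatheterStatus(BaseModel):
    """Urinary-catheter context: indwelling, recently removed, or chronic."""

    model_config = ConfigDict(extra="forbid")

    in_place: bool = True
    removed_within_48h: bool = False
    chronic: bool = False

    @model_validator(mode="after")
    def _mutually_exclusive(self) -> "CatheterStatus":
        if self.in_place and self.removed_within_48h:
            raise ValueError("in_place and removed_within_48h are mutually exclusive")
        return self


class ClinicalCues(BaseModel):
    """Structured sign/symptom flags, plus alternative-source attributions.

    ``alternative_source`` maps a cue name to a flag asserting that the
    finding has a non-urinary explanation. Attributions on concordant cues
    suppress them from the diagnosis; attributions on discordant cues are
    recorded for the audit trail only (discordant cues never influence the
    diagnosis in any event).
    """

    model_config = ConfigDict(extra="forbid")

    # concordant
    fever_temp_c: Optional[float] = Field(None, ge=30.0, le=45.0)
    new_onset_delirium: bool = False
    rigors: bool = False
    flank_pain: bool = False
    acute_hematuria: bool = False
    pelvic_discomfort: bool = False
    urgency: bool = False
    frequency: bool = False
    dysuria: bool = False
    suprapubic_pain: bool = False
    # discordant
    pyuria: bool = False
    foul_smelling_urine: bool = False
    urine_color_change: bool = False
    urine_sediment: bool = False
    systemic_leukocytosis: bool = False
    prior_uti_history: bool = False
    resistant_organism: bool = False
    vague_malaise: bool = False
    weakness: bool = False
    elderly_or_frail: bool = False
    # attribution
    alternative_source: dict[str, bool] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_attribution_keys(self) -> "ClinicalCues":
        canonical = {}
        for key, flag in self.alternative_source.items():
            name = "fever" if key == "fever_temp_c" else key
            if name not in ALL_CUES:
                raise ValueError(f"alternative_source names unknown cue {key!r}")
            canonical[name] = bool(flag)
        object.__setattr__(self, "alternative_source", canonical)
        return self

    def cue_flag(self, cue: str) -> bool:
        """Raw presence of a cue (fever = any recorded temperature)."""
        if cue == "fever":
            return self.fever_temp_c is not None
        return bool(getattr(self, cue))

    def attributed(self, cue: str) -> bool:
        return bool(self.alternative_source.get(cue, False))


class BacteriuriaCase(BaseModel):
    model_config = ConfigDict(extra="forbid")

    case_id: str
    isolates: list[OrganismIsolate] = Field(default_factory=list)
    catheter: CatheterStatus = Field(default_factory=CatheterStatus)
    cues: ClinicalCues = Field(default_factory=ClinicalCues)


def _fahrenheit_to_celsius(f: float) -> float:
    return (f - 32.0) * 5.0 / 9.0


def parse_case(record: Union[str, dict]) -> BacteriuriaCase:
    """Parse one case record (JSON text or a dict) into a ``BacteriuriaCase``.

    Fahrenheit temperatures (``fever_temp_f`` inside ``cues``) are converted
    to Celsius before storage. If both temperature fields are present they
    must agree to within 0.1 °C after conversion.

    Raises
    ------
    CaseValidationError
        On any schema violation; the message names the offending field.
    TemperatureConflictError
        If Celsius and Fahrenheit values disagree.
    """
    if isinstance(record, str):
        try:
            record = json.loads(record)
        except json.JSONDecodeError as exc:
            raise CaseValidationError(f"invalid JSON: {exc}") from exc
    if not isinstance(record, dict):
        raise CaseValidationError("case record must be a JSON object")
    record = json.loads(json.dumps(record))  # deep copy, plain types
    record.pop("schema_version", None)
    cues = record.get("cues")
    if isinstance(cues, dict) and "fever_temp_f" in cues:
        fahrenheit = cues.pop("fever_temp_f")
        if fahrenheit is not None:
            celsius = _fahrenheit_to_celsius(float(fahrenheit))
            stated = cues.get("fever_temp_c")
            if stated is not None and abs(float(stated) - celsius) > 0.1:
                raise TemperatureConflictError(
                    f"fever_temp_c={stated} conflicts with "
                    f"fever_temp_f={fahrenheit} ({celsius:.2f} °C)"
                )
            cues["fever_temp_c"] = celsius
    try:
        return BacteriuriaCase.model_validate(record)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(part) for part in first["loc"]) or "<root>"
        raise CaseValidationError(f"invalid case field {loc}: {first['msg']}") from exc


def parse_cases(payload: Union[str, dict, list]) -> list[BacteriuriaCase]:
    """Parse a JSON payload holding one case or an array of cases."""
    if isinstance(payload, str):
        try:
            payload = json.loads(payload)
        except json.JSONDecodeError as exc:
            raise CaseValidationError(f"invalid JSON: {exc}") from exc
    if isinstance(payload, dict):
        payload = [payload]
    cases = [parse_case(rec) for rec in payload]
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise CaseValidationError("case_id values must be unique within a collection")
    return cases


def write_case(case: BacteriuriaCase) -> dict:
    """Serialize a case to a plain dict in the published JSON schema."""
    record = case.model_dump(mode="json")
    record["schema_version"] = SCHEMA_VERSION
    return record


def write_cases_json(cases: Iterable[BacteriuriaCase]) -> str:
    return json.dumps([write_case(c) for c in cases], indent=2)


_DATA_DIR = Path(__file__).parent / "data"


def load_fixtures() -> list[BacteriuriaCase]:
    """The four packaged long-term-care bacteriuria cases.

    These are the worked examples used throughout: a steroid-explained
    leukocytosis case, a febrile low-count gram-positive case, a
    polymicrobial case with weakness only, and an asymptomatic candiduria
    case. Their guideline diagnoses are CA-ABU, CA-UTI, CA-ABU, CA-ABU.
    """
    payload = (_DATA_DIR / "fixtures.json").read_text(encoding="utf-8")
    return parse_cases(payload)


# ---------------------------------------------------------------------------
# Flat CSV case format: one row per case, isolates as pipe-delimited triples
# "name|class|lower|upper" joined by ";" (empty upper = unbounded).
# ---------------------------------------------------------------------------

_BOOL_CUE_FIELDS = tuple(c for c in ALL_CUES if c != "fever")


def _isolate_to_token(iso: OrganismIsolate) -> str:
    upper = "" if iso.cfu.upper is None else f"{iso.cfu.upper:g}"
    return f"{iso.name}|{iso.organism_class}|{iso.cfu.lower:g}|{upper}"


def _isolate_from_token(token: str) -> dict:
    parts = token.split("|")
    if len(parts) != 4:
        raise CaseValidationError(f"malformed isolate token {token!r}")
    name, cls, lower, upper = parts
    return {
        "name": name,
        "organism_class": cls,
        "cfu": {"lower": float(lower), "upper": float(upper) if upper else None},
    }


def write_cases_csv(cases: Iterable[BacteriuriaCase], path: Union[str, Path]) -> None:
    rows = []
    for case in cases:
        row: dict = {
            "case_id": case.case_id,
            "isolates": ";".join(_isolate_to_token(i) for i in case.isolates),
            "catheter_in_place": case.catheter.in_place,
            "catheter_removed_within_48h": case.catheter.removed_within_48h,
            "catheter_chronic": case.catheter.chronic,
            "fever_temp_c": case.cues.fever_temp_c,
        }
        for cue in _BOOL_CUE_FIELDS:
            row[cue] = getattr(case.cues, cue)
        row["alternative_source"] = ";".join(
            cue for cue, flag in sorted(case.cues.alternative_source.items()) if flag
        )
        rows.append(row)
    # %.17g keeps temperatures exact through the text round-trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_cases_csv(path: Union[str, Path]) -> list[BacteriuriaCase]:
    df = pd.read_csv(path, dtype={"case_id": str}, float_precision="round_trip")
    cases = []
    for _, row in df.iterrows():
        isolates_field = row.get("isolates")
        tokens = (
            str(isolates_field).split(";")
            if isinstance(isolates_field, str) and isolates_field
            else []
        )
        cues: dict = {}
        temp = row.get("fever_temp_c")
        if pd.notna(temp):
            cues["fever_temp_c"] = float(temp)
        for cue in _BOOL_CUE_FIELDS:
            if cue in df.columns:
                cues[cue] = bool(row[cue])
        attributions = row.get("alternative_source")
        if isinstance(attributions, str) and attributions:
            cues["alternative_source"] = {c: True for c in attributions.split(";")}
        record = {
            "case_id": row["case_id"],
            "isolates": [_isolate_from_token(t) for t in tokens],
            "catheter": {
                "in_place": bool(row.get("catheter_in_place", True)),
                "removed_within_48h": bool(row.get("catheter_removed_within_48h", False)),
                "chronic": bool(row.get("catheter_chronic", False)),
            },
            "cues": cues,
        }
        cases.append(parse_case(record))
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise CaseValidationError("case_id values must be unique within a collection")
    return cases


# ---------------------------------------------------------------------------
# Rating tables
# ---------------------------------------------------------------------------

_LONG_FORM_COLUMNS = {"subject_id", "rater_id", "category"}


def read_rating_table(path: Union[str, Path]):
    """Read a categorical rating table CSV into a ``RatingMatrix``.

    Two layouts are accepted: *long form* with columns
    ``subject_id, rater_id, category`` (one row per individual rating), or
    *count form* with a ``subject_id`` column followed by one column per
    category holding non-negative counts. Long form is aggregated to count
    form with categories in sorted order; count form keeps the file's
    column order.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise RatingTableError("empty rating-table CSV") from exc
    return read_rating_table_from_frame(df)


def read_rating_table_from_frame(df: pd.DataFrame):
    """Build a ``RatingMatrix`` from an already-loaded rating DataFrame."""
    from .agreement_stats import RatingMatrix

    if df.empty:
        raise RatingTableError("rating table has no data rows")
    if _LONG_FORM_COLUMNS.issubset(df.columns):
        dup = df.duplicated(subset=["subject_id", "rater_id"])
        if dup.any():
            pair = df.loc[dup, ["subject_id", "rater_id"]].iloc[0]
            raise DuplicateRatingError(
                f"duplicate rating for subject {pair['subject_id']!r} "
                f"by rater {pair['rater_id']!r}"
            )
        categories = sorted(df["category"].astype(str).unique())
        subjects = list(dict.fromkeys(df["subject_id"]))  # first-appearance order
        counts = pd.crosstab(df["subject_id"], df["category"].astype(str))
        counts = counts.reindex(index=subjects, columns=categories, fill_value=0)
        return RatingMatrix(
            counts=counts.to_numpy(dtype=int),
            category_labels=categories,
            subject_ids=[str(s) for s in subjects],
        )
    if "subject_id" not in df.columns:
        raise RatingTableError(
            "rating table must be long form (subject_id, rater_id, category) "
            "or count form with a subject_id column"
        )
    categories = [c for c in df.columns if c != "subject_id"]
    if not categories:
        raise RatingTableError("count-form table has no category columns")
    try:
        counts = df[categories].to_numpy(dtype=float)
    except ValueError as exc:
        raise RatingTableError(f"non-numeric count entry: {exc}") from exc
    if (counts < 0).any():
        raise RatingTableError("count-form table has negative entries")
    if not (counts == counts.astype(int)).all():
        raise RatingTableError("count-form entries must be integers")
    return RatingMatrix(
        counts=counts.astype(int),
        category_labels=[str(c) for c in categories],
        subject_ids=[str(s) for s in df["subject_id"]],
    )


def write_rating_table(matrix, path: Union[str, Path]) -> None:
    """Write a ``RatingMatrix`` as a count-form CSV (inverse of reading one)."""
    subjects = matrix.subject_ids or [f"s{i + 1}" for i in range(matrix.n_subjects)]
    df = pd.DataFrame(matrix.counts, columns=matrix.category_labels)
    df.insert(0, "subject_id", subjects)
    df.to_csv(path, index=False)


def load_unaided_rating_table():
    """The packaged 4-case x 10-rater unaided-clinician diagnosis table."""
    return read_rating_table(_DATA_DIR / "unaided_ratings.csv")
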