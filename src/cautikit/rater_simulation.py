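"""Synthetic cases and simulated raters with parameterized "mental models".

Clinicians diagnose by matching a case against an internal cue-to-disease
mapping — a *mental model*. Here a mental model is operationalized as a
cue-weighted linear classifier: a rater sums non-negative weights over the
cues they perceive as present and calls CA-UTI when the score reaches a
threshold. A rater may instead be *algorithm-aided*, in which case the
rule engine does the classifying. Either way, cue perception is noisy:
each cue flag is independently misread with probability ``ε``.

The case generator makes the central claim literal: concordant cues are
drawn with class-conditional probabilities (more frequent in true CA-UTI),
while discordant cues are drawn with identical probabilities in both
classes, so they carry exactly zero diagnostic information. A heuristic
rater whose weights sit on discordant cues therefore cannot beat baseline
accuracy max(prevalence, 1 − prevalence), whereas algorithm-aided raters
at ε = 0 recover the true labels perfectly — the mechanism by which
guideline-discordant mental models degrade accuracy and agreement, and a
guideline-derived algorithm restores them.

Every run is a pure function of its integer seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .agreement_stats import (
    KappaResult,
    RatingMatrix,
    cohen_kappa,
    fleiss_kappa,
)
from .case_model import (
    ALL_CUES,
    CONCORDANT_CUES,
    DISCORDANT_CUES,
    BacteriuriaCase,
    CatheterStatus,
    CfuCount,
    ClinicalCues,
    OrganismIsolate,
)
from .decision_algorithm import (
    DEFAULT_CONFIG,
    AlgorithmConfig,
    Diagnosis,
    classify_case,
    qualifying_symptoms,
)
from .errors import ConfigurationError, InvalidInputError

_DATA_DIR = Path(__file__).parent / "data"

#: Culture patterns the generator samples from (all significant at the
#: default 10^3 CFU/mL threshold — the study population is positive cultures).
_CULTURE_PATTERNS: tuple[tuple[float, Optional[float]], ...] = (
    (1e5, None),
    (1e4, None),
    (1e3, 1e5),
    (1e4, 1e5),
)

_ORGANISMS: tuple[tuple[str, str], ...] = (
    ("Escherichia coli", "gram_negative"),
    ("Klebsiella pneumoniae", "gram_negative"),
    ("Proteus mirabilis", "gram_negative"),
    ("Enterococcus faecalis", "gram_positive"),
    ("Staphylococcus aureus", "gram_positive"),
    ("Candida albicans", "fungal"),
)

_RESAMPLE_BUDGET = 1000


@dataclass(frozen=True)
class CueDistribution:
    """Class-conditional cue prevalences for the case generator.

    ``concordant[cue] = (P(present | CA-UTI), P(present | CA-ABU))``;
    ``discordant[cue]`` is a single probability applied to both classes,
    which is what makes discordant cues uninformative by construction.
    Fever temperatures, when febrile, are drawn normal and clipped to
    [38, 41] °C so a generated fever always clears the default threshold.
    """

    concordant: dict[str, tuple[float, float]]
    discordant: dict[str, float]
    fever_temp_mean_c: float = 39.2
    fever_temp_sd_c: float = 0.6

    def __post_init__(self) -> None:
        for cue, (p_uti, p_abu) in self.concordant.items():
            if cue not in CONCORDANT_CUES:
                raise InvalidInputError(f"unknown concordant cue {cue!r}")
            if not (0 <= p_uti <= 1 and 0 <= p_abu <= 1):
                raise InvalidInputError(f"probabilities for {cue!r} outside [0, 1]")
        for cue, p in self.discordant.items():
            if cue not in DISCORDANT_CUES:
                raise InvalidInputError(f"unknown discordant cue {cue!r}")
            if not 0 <= p <= 1:
                raise InvalidInputError(f"probability for {cue!r} outside [0, 1]")

    @classmethod
    def default(cls) -> "CueDistribution":
        """Illustrative defaults shipped in ``data/default_cues.json``."""
        payload = json.loads((_DATA_DIR / "default_cues.json").read_text("utf-8"))
        return cls(
            concordant={c: tuple(p) for c, p in payload["concordant"].items()},
            discordant=dict(payload["discordant"]),
            fever_temp_mean_c=payload["fever_temp_mean_c"],
            fever_temp_sd_c=payload["fever_temp_sd_c"],
        )


@dataclass(frozen=True)
class RaterModel:
    """One simulated rater: a mental model or an algorithm user.

    ``heuristic`` mode scores perceived-present cues by ``weights`` and
    calls CA-UTI at ``score >= threshold``; ``algorithm_aided`` mode runs
    the rule engine on the perceived case (weights and threshold unused).
    ``extraction_error`` ε is the per-cue misreading probability.
    """

    name: str
    mode: Literal["heuristic", "algorithm_aided"]
    weights: dict[str, float] = field(default_factory=dict)
    threshold: float = 1.0
    extraction_error: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.extraction_error <= 1.0:
            raise InvalidInputError("extraction_error must lie in [0, 1]")
        for cue, w in self.weights.items():
            if cue not in ALL_CUES:
                raise InvalidInputError(f"unknown cue {cue!r} in weights")
            if w < 0:
                raise InvalidInputError("cue weights must be non-negative")


@dataclass(frozen=True)
class ExperimentConfig:
    n_cases: int
    prevalence: float
    raters: tuple[RaterModel, ...]
    seed: int
    cue_distribution: CueDistribution = field(default_factory=CueDistribution.default)
    algorithm_config: AlgorithmConfig = field(default_factory=AlgorithmConfig)

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise InvalidInputError("n_cases must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidInputError("prevalence must lie in [0, 1]")


def _draw_case(
    rng: np.random.Generator,
    case_id: str,
    is_uti: bool,
    dist: CueDistribution,
    config: AlgorithmConfig,
) -> BacteriuriaCase:
    for _ in range(_RESAMPLE_BUDGET):
        removed = rng.random() < 0.25
        catheter = CatheterStatus(
            in_place=not removed,
            removed_within_48h=removed,
            chronic=bool(not removed and rng.random() < 0.3),
        )
        cue_kwargs: dict = {}
        febrile = False
        for cue, (p_uti, p_abu) in dist.concordant.items():
            present = rng.random() < (p_uti if is_uti else p_abu)
            if cue == "fever":
                febrile = present
            else:
                cue_kwargs[cue] = present
        if febrile:
            temp = float(
                np.clip(
                    rng.normal(dist.fever_temp_mean_c, dist.fever_temp_sd_c), 38.0, 41.0
                )
            )
            cue_kwargs["fever_temp_c"] = temp
        for cue, p in dist.discordant.items():
            cue_kwargs[cue] = rng.random() < p
        n_isolates = 1 + int(rng.random() < 0.3)
        isolates = []
        for _ in range(n_isolates):
            name, cls = _ORGANISMS[rng.integers(len(_ORGANISMS))]
            lower, upper = _CULTURE_PATTERNS[rng.integers(len(_CULTURE_PATTERNS))]
            isolates.append(
                OrganismIsolate(
                    name=name, organism_class=cls, cfu=CfuCount(lower=lower, upper=upper)
                )
            )
        case = BacteriuriaCase(
            case_id=case_id,
            isolates=isolates,
            catheter=catheter,
            cues=ClinicalCues(**cue_kwargs),
        )
        if not is_uti:
            # the true label is the guideline diagnosis: in a true CA-ABU
            # case every present concordant cue has a non-urinary
            # explanation, asserted as an attribution
            present = [c for c in CONCORDANT_CUES if case.cues.cue_flag(c)]
            if present:
                case = case.model_copy(
                    update={
                        "cues": case.cues.model_copy(
                            update={"alternative_source": {c: True for c in present}}
                        )
                    }
                )
            return case
        qualifying, _ = qualifying_symptoms(case, config)
        if qualifying:
            return case
    raise ConfigurationError(
        "could not generate a true CA-UTI case with an admissible qualifying "
        f"cue within {_RESAMPLE_BUDGET} attempts; concordant-cue probabilities "
        "are too small"
    )


def generate_cases(
    config: ExperimentConfig,
) -> list[tuple[BacteriuriaCase, Diagnosis]]:
    """Draw ``n_cases`` synthetic positive-culture cases with true labels.

    True CA-UTI cases are rejection-resampled until they carry at least one
    admissible, unattributed concordant cue; true CA-ABU cases have every
    present concordant cue attributed to an alternative source. All cases
    have significant growth. Pure function of ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    out = []
    for i in range(config.n_cases):
        is_uti = rng.random() < config.prevalence
        case = _draw_case(
            rng, f"sim-{i + 1}", is_uti, config.cue_distribution, config.algorithm_config
        )
        out.append((case, Diagnosis.CA_UTI if is_uti else Diagnosis.CA_ABU))
    return out


def _perceive(
    case: BacteriuriaCase, epsilon: float, rng: np.random.Generator
) -> BacteriuriaCase:
    """Flip each of the 20 cue flags independently with probability ε."""
    if epsilon == 0.0:
        return case
    updates: dict = {}
    for cue in ALL_CUES:
        flip = rng.random() < epsilon
        if not flip:
            continue
        if cue == "fever":
            updates["fever_temp_c"] = None if case.cues.fever_temp_c is not None else 39.0
        else:
            updates[cue] = not getattr(case.cues, cue)
    if not updates:
        return case
    return case.model_copy(update={"cues": case.cues.model_copy(update=updates)})


def simulate_rater(
    case: BacteriuriaCase,
    rater: RaterModel,
    rng: np.random.Generator,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> Diagnosis:
    """One rater's diagnosis of one case, through their noisy perception."""
    perceived = _perceive(case, rater.extraction_error, rng)
    if rater.mode == "algorithm_aided":
        return classify_case(perceived, config).diagnosis
    score = sum(
        w for cue, w in rater.weights.items() if perceived.cues.cue_flag(cue)
    )
    return Diagnosis.CA_UTI if score >= rater.threshold else Diagnosis.CA_ABU


@dataclass(frozen=True)
class RaterSummary:
    name: str
    mode: str
    accuracy: float
    concordance_with_algorithm: float


@dataclass(frozen=True)
class ExperimentSummary:
    """Results of one simulated multi-rater experiment."""

    seed: int
    n_cases: int
    prevalence: float
    true_uti_fraction: float
    raters: tuple[RaterSummary, ...]
    pairwise_cohen: dict[tuple[str, str], KappaResult]
    fleiss: KappaResult
    rating_matrix: RatingMatrix

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_cases": self.n_cases,
            "prevalence": self.prevalence,
            "true_uti_fraction": self.true_uti_fraction,
            "raters": [
                {
                    "name": r.name,
                    "mode": r.mode,
                    "accuracy": r.accuracy,
                    "concordance_with_algorithm": r.concordance_with_algorithm,
                }
                for r in self.raters
            ],
            "pairwise_cohen": {
                f"{a}|{b}": k.to_dict() for (a, b), k in self.pairwise_cohen.items()
            },
            "fleiss": self.fleiss.to_dict(),
        }


def run_experiment(config: ExperimentConfig) -> ExperimentSummary:
    """Generate cases, collect every rater's diagnoses, and score agreement.

    Reports per-rater accuracy against the true labels, concordance with
    the rule engine's own classification, all pairwise Cohen kappas, and
    the overall Fleiss kappa across raters. Degenerate marginals (every
    rating in one category, possible at extreme prevalence) raise
    ``DegenerateMarginalsError`` from the agreement layer.
    """
    if len(config.raters) < 2:
        raise InvalidInputError("need at least 2 raters")
    names = [r.name for r in config.raters]
    if len(set(names)) != len(names):
        raise InvalidInputError("rater names must be unique")
    cases = generate_cases(config)
    truth = [label for _, label in cases]
    engine = [classify_case(case, config.algorithm_config).diagnosis for case, _ in cases]

    ratings: dict[str, list[Diagnosis]] = {}
    for r_idx, rater in enumerate(config.raters):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, r_idx]))
        ratings[rater.name] = [
            simulate_rater(case, rater, rng, config.algorithm_config)
            for case, _ in cases
        ]

    rater_summaries = tuple(
        RaterSummary(
            name=rater.name,
            mode=rater.mode,
            accuracy=float(
                np.mean([d == t for d, t in zip(ratings[rater.name], truth)])
            ),
            concordance_with_algorithm=float(
                np.mean([d == e for d, e in zip(ratings[rater.name], engine)])
            ),
        )
        for rater in config.raters
    )

    pairwise: dict[tuple[str, str], KappaResult] = {}
    for a, b in itertools.combinations(names, 2):
        pairwise[(a, b)] = cohen_kappa(
            [d.value for d in ratings[a]], [d.value for d in ratings[b]]
        )

    per_subject = [
        [ratings[name][i].value for name in names] for i in range(config.n_cases)
    ]
    matrix = RatingMatrix.from_labels(
        per_subject,
        subject_ids=[case.case_id for case, _ in cases],
        categories=sorted([Diagnosis.CA_ABU.value, Diagnosis.CA_UTI.value]),
    )
    fleiss = fleiss_kappa(matrix)

    return ExperimentSummary(
        seed=config.seed,
        n_cases=config.n_cases,
        prevalence=config.prevalence,
        true_uti_fraction=float(np.mean([t == Diagnosis.CA_UTI for t in truth])),
        raters=rater_summaries,
        pairwise_cohen=pairwise,
        fleiss=fleiss,
        rating_matrix=matrix,
    )
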