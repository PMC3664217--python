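"""Chance-corrected agreement statistics for categorical ratings.

Implements the statistics used to validate the diagnostic algorithm:

* **Fleiss' generalized kappa** for N subjects each rated by n raters into
  k categories, from the subjects × categories count matrix ``n_ij``:

  .. math::

      P_i = \\frac{\\sum_j n_{ij}^2 - n}{n(n-1)}, \\qquad
      \\bar P = \\frac{1}{N}\\sum_i P_i, \\qquad
      p_j = \\frac{\\sum_i n_{ij}}{Nn}, \\qquad
      P_e = \\sum_j p_j^2, \\qquad
      \\kappa = \\frac{\\bar P - P_e}{1 - P_e}

  with the Fleiss–Nee–Landis standard error for the overall kappa
  (the formula implemented by the classic SAS MAGREE macro):

  .. math::

      SE = \\frac{\\sqrt{2}}{\\sum_j p_j q_j \\sqrt{Nn(n-1)}}
           \\sqrt{\\Bigl(\\sum_j p_j q_j\\Bigr)^2
                  - \\sum_j p_j q_j (q_j - p_j)}, \\quad q_j = 1 - p_j.

* **Cohen's simple (unweighted) kappa** for two raters, with the standard
  large-sample asymptotic variance of Fleiss, Cohen & Everitt.

* Concordance rates against a reference standard, Landis–Koch verbal
  interpretation bands, and whole-percent category tallies.

Confidence intervals use z = 1.96 and are clipped to [−1, 1]. Display
rounding is half-away-from-zero: two decimals for kappa and CI bounds,
whole percent for rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import DegenerateMarginalsError, InvalidInputError

_Z95 = 1.96


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of most printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def interpretation_band(kappa: float) -> str:
    """Landis–Koch verbal band for a kappa value in [−1, 1]."""
    if not -1.0 <= kappa <= 1.0:
        raise InvalidInputError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass
class RatingMatrix:
    """Subjects × categories rating counts with a constant rater count.

    ``counts[i, j]`` is the number of raters assigning subject ``i`` to
    category ``j``; every row sums to the common number of raters ``n``.
    """

    counts: np.ndarray
    category_labels: list[str]
    subject_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2:
            raise InvalidInputError("counts must be a 2-D array")
        n_subjects, n_categories = self.counts.shape
        if n_subjects < 1 or n_categories < 2:
            raise InvalidInputError("need at least 1 subject and 2 categories")
        if (self.counts < 0).any():
            raise InvalidInputError("rating counts must be non-negative")
        if len(self.category_labels) != n_categories:
            raise InvalidInputError("category_labels length mismatch")
        row_sums = self.counts.sum(axis=1)
        if not (row_sums == row_sums[0]).all():
            raise InvalidInputError(
                "every subject must be rated by the same number of raters"
            )
        if row_sums[0] < 2:
            raise InvalidInputError("need at least 2 raters per subject")
        if self.subject_ids is not None and len(self.subject_ids) != n_subjects:
            raise InvalidInputError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_categories(self) -> int:
        return self.counts.shape[1]

    @property
    def raters_per_subject(self) -> int:
        return int(self.counts[0].sum())

    @classmethod
    def from_labels(
        cls,
        labels: Sequence[Sequence[str]],
        subject_ids: Optional[Sequence[str]] = None,
        categories: Optional[Sequence[str]] = None,
    ) -> "RatingMatrix":
        """Build a count matrix from per-subject lists of rater labels."""
        if not labels:
            raise InvalidInputError("no ratings supplied")
        cats = (
            list(categories)
            if categories is not None
            else sorted({str(l) for row in labels for l in row})
        )
        index = {c: j for j, c in enumerate(cats)}
        counts = np.zeros((len(labels), len(cats)), dtype=int)
        for i, row in enumerate(labels):
            for label in row:
                counts[i, index[str(label)]] += 1
        return cls(
            counts=counts,
            category_labels=cats,
            subject_ids=list(subject_ids) if subject_ids is not None else None,
        )


@dataclass(frozen=True)
class KappaResult:
    """A kappa point estimate with its asymptotic 95% interval."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_bar: float
    p_e: float
    band: str

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """(kappa, ci_low, ci_high) at display precision."""
        return (
            round_half_away(self.estimate, ndigits),
            round_half_away(self.ci_low, ndigits),
            round_half_away(self.ci_high, ndigits),
        )

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_bar": self.p_bar,
            "p_e": self.p_e,
            "band": self.band,
        }


def _make_result(kappa: float, se: float, p_bar: float, p_e: float) -> KappaResult:
    kappa = float(np.clip(kappa, -1.0, 1.0))
    ci_low = float(np.clip(kappa - _Z95 * se, -1.0, 1.0))
    ci_high = float(np.clip(kappa + _Z95 * se, -1.0, 1.0))
    return KappaResult(
        estimate=kappa,
        se=float(se),
        ci_low=ci_low,
        ci_high=ci_high,
        p_bar=float(p_bar),
        p_e=float(p_e),
        band=interpretation_band(kappa),
    )


def fleiss_kappa(matrix: RatingMatrix) -> KappaResult:
    """Fleiss' generalized kappa with the Fleiss–Nee–Landis 95% CI."""
    counts = matrix.counts.astype(float)
    n_subjects = matrix.n_subjects
    n = matrix.raters_per_subject
    p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
    p_bar = float(p_i.mean())
    p_j = counts.sum(axis=0) / (n_subjects * n)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0 - 1e-12:
        raise DegenerateMarginalsError(
            "all ratings fall in a single category; expected agreement is 1 "
            "and kappa is undefined"
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    q_j = 1.0 - p_j
    pq_sum = float((p_j * q_j).sum())
    se = (math.sqrt(2.0) / (pq_sum * math.sqrt(n_subjects * n * (n - 1)))) * math.sqrt(
        pq_sum**2 - float((p_j * q_j * (q_j - p_j)).sum())
    )
    return _make_result(kappa, se, p_bar, p_e)


def _cohen_from_table(table: np.ndarray) -> KappaResult:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise InvalidInputError("contingency table must be square")
    total = table.sum()
    if total < 2:
        raise InvalidInputError("need at least 2 paired ratings")
    p = table / total
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float((row * col).sum())
    if p_e >= 1.0 - 1e-12:
        raise DegenerateMarginalsError(
            "both raters use a single shared category; kappa is undefined"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss–Cohen–Everitt large-sample variance of the kappa estimate
    k_categories = table.shape[0]
    a = 0.0
    for i in range(k_categories):
        a += p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
    b = 0.0
    for i in range(k_categories):
        for j in range(k_categories):
            if i != j:
                b += p[i, j] * (col[i] + row[j]) ** 2
    b *= (1.0 - kappa) ** 2
    c = (kappa - p_e * (1.0 - kappa)) ** 2
    var = (a + b - c) / (total * (1.0 - p_e) ** 2)
    se = math.sqrt(max(var, 0.0))
    return _make_result(kappa, se, p_o, p_e)


def cohen_kappa(
    ratings_a: Sequence[str], ratings_b: Sequence[str]
) -> KappaResult:
    """Cohen's simple (unweighted) kappa between two raters' label lists."""
    if len(ratings_a) != len(ratings_b):
        raise InvalidInputError(
            f"rating lists differ in length: {len(ratings_a)} vs {len(ratings_b)}"
        )
    if len(ratings_a) < 2:
        raise InvalidInputError("need at least 2 paired ratings")
    labels = sorted({str(l) for l in ratings_a} | {str(l) for l in ratings_b})
    index = {l: i for i, l in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for a, b in zip(ratings_a, ratings_b):
        table[index[str(a)], index[str(b)]] += 1
    return _cohen_from_table(table)


def cohen_kappa_from_table(table) -> KappaResult:
    """Cohen's kappa directly from a square contingency table."""
    return _cohen_from_table(np.asarray(table))


@dataclass(frozen=True)
class ConcordanceResult:
    count: int
    total: int
    proportion: float

    @property
    def percent(self) -> int:
        """Whole-percent display value (half away from zero)."""
        return int(round_half_away(100.0 * self.proportion))


def concordance_rate(
    ratings: Sequence[Sequence[str]], reference: Sequence[str]
) -> ConcordanceResult:
    """Count individual ratings agreeing with their subject's reference label."""
    if not ratings or any(len(row) == 0 for row in ratings):
        raise InvalidInputError("every subject needs at least one rating")
    if len(reference) != len(ratings):
        raise InvalidInputError("reference must cover every subject")
    count = sum(
        sum(1 for label in row if str(label) == str(ref))
        for row, ref in zip(ratings, reference)
    )
    total = sum(len(row) for row in ratings)
    return ConcordanceResult(count=count, total=total, proportion=count / total)


def concordance_from_matrix(
    matrix: RatingMatrix, reference: Sequence[str]
) -> ConcordanceResult:
    """Concordance of a count matrix against per-subject reference labels."""
    if len(reference) != matrix.n_subjects:
        raise InvalidInputError("reference must cover every subject")
    index = {c: j for j, c in enumerate(matrix.category_labels)}
    count = 0
    for i, ref in enumerate(reference):
        if str(ref) not in index:
            raise InvalidInputError(f"reference label {ref!r} not a rating category")
        count += int(matrix.counts[i, index[str(ref)]])
    total = int(matrix.counts.sum())
    return ConcordanceResult(count=count, total=total, proportion=count / total)


def tally_categories(counts: Mapping[str, int]) -> dict[str, tuple[int, int]]:
    """Per-category counts with whole-percent shares of the total."""
    if any(v < 0 for v in counts.values()):
        raise InvalidInputError("category counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise InvalidInputError("all category counts are zero")
    return {
        cat: (int(v), int(round_half_away(100.0 * v / total)))
        for cat, v in counts.items()
    }
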