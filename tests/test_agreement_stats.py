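"""Kappa statistics, concordance, bands, tallies — checked against
independently coded direct-formula oracles and statsmodels."""

import math

import numpy as np
import pytest
from statsmodels.stats.inter_rater import cohens_kappa as sm_cohens_kappa
from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss_kappa

from cautikit import (
    DegenerateMarginalsError,
    InvalidInputError,
    RatingMatrix,
    cohen_kappa,
    cohen_kappa_from_table,
    concordance_from_matrix,
    concordance_rate,
    fleiss_kappa,
    interpretation_band,
    tally_categories,
)
from cautikit.agreement_stats import round_half_away


def _oracle_fleiss(counts):
    """Direct re-evaluation of the published multi-rater kappa formulas."""
    counts = np.asarray(counts, dtype=float)
    n_subjects, _ = counts.shape
    n = counts[0].sum()
    p_i = [(sum(c * c for c in row) - n) / (n * (n - 1)) for row in counts]
    p_bar = sum(p_i) / n_subjects
    p_j = counts.sum(axis=0) / (n_subjects * n)
    p_e = sum(p * p for p in p_j)
    kappa = (p_bar - p_e) / (1 - p_e)
    pq = [p * (1 - p) for p in p_j]
    se = (
        math.sqrt(2)
        / (sum(pq) * math.sqrt(n_subjects * n * (n - 1)))
        * math.sqrt(
            sum(pq) ** 2 - sum(x * ((1 - p) - p) for x, p in zip(pq, p_j))
        )
    )
    return kappa, se


def _random_count_matrix(rng, n_subjects, n_categories, n_raters):
    counts = rng.multinomial(
        n_raters, rng.dirichlet(np.ones(n_categories)), size=n_subjects
    )
    return counts


class TestFleissKappa:
    def test_unaided_matrix_reproduces_printed_values(self, unaided_matrix):
        result = fleiss_kappa(unaided_matrix)
        # frozen values from the direct-formula oracle on this matrix
        assert result.estimate == pytest.approx(0.3520886615515772, abs=1e-12)
        assert result.se == pytest.approx(0.07453559924999298, abs=1e-12)
        assert result.rounded(2) == (0.35, 0.21, 0.50)
        assert result.band == "fair"

    def test_perfect_agreement(self):
        matrix = RatingMatrix(
            counts=[[10, 0], [0, 10]], category_labels=["a", "b"]
        )
        assert fleiss_kappa(matrix).estimate == pytest.approx(1.0)

    def test_single_category_marginals_degenerate(self):
        matrix = RatingMatrix(
            counts=[[10, 0], [10, 0], [10, 0]], category_labels=["a", "b"]
        )
        with pytest.raises(DegenerateMarginalsError):
            fleiss_kappa(matrix)

    def test_matches_oracle_and_statsmodels_on_random_matrices(self):
        rng = np.random.default_rng(13)
        checked = 0
        while checked < 100:
            counts = _random_count_matrix(
                rng,
                n_subjects=int(rng.integers(2, 9)),
                n_categories=int(rng.integers(2, 5)),
                n_raters=int(rng.integers(2, 8)),
            )
            p_j = counts.sum(axis=0) / counts.sum()
            if (p_j**2).sum() >= 1 - 1e-9:
                continue
            matrix = RatingMatrix(
                counts=counts,
                category_labels=[f"c{j}" for j in range(counts.shape[1])],
            )
            result = fleiss_kappa(matrix)
            kappa_oracle, se_oracle = _oracle_fleiss(counts)
            assert result.estimate == pytest.approx(kappa_oracle, abs=1e-12)
            assert result.se == pytest.approx(se_oracle, abs=1e-12)
            assert result.estimate == pytest.approx(
                sm_fleiss_kappa(counts), abs=1e-10
            )
            checked += 1

    def test_category_and_subject_permutation_invariance(self, unaided_matrix):
        base = fleiss_kappa(unaided_matrix)
        swapped = RatingMatrix(
            counts=unaided_matrix.counts[:, ::-1],
            category_labels=list(reversed(unaided_matrix.category_labels)),
        )
        shuffled = RatingMatrix(
            counts=unaided_matrix.counts[[3, 1, 0, 2]],
            category_labels=unaided_matrix.category_labels,
        )
        for other in (fleiss_kappa(swapped), fleiss_kappa(shuffled)):
            assert other.estimate == pytest.approx(base.estimate, abs=1e-14)
            assert other.se == pytest.approx(base.se, abs=1e-14)

    def test_estimate_within_bounds_and_ci_ordered(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            counts = _random_count_matrix(rng, 5, 3, 6)
            p_j = counts.sum(axis=0) / counts.sum()
            if (p_j**2).sum() >= 1 - 1e-9:
                continue
            result = fleiss_kappa(
                RatingMatrix(counts=counts, category_labels=["a", "b", "c"])
            )
            assert -1.0 <= result.ci_low <= result.estimate <= result.ci_high <= 1.0
            assert 0.0 <= result.p_bar <= 1.0 and 0.0 <= result.p_e <= 1.0


class TestCohenKappa:
    def test_identical_ratings_give_one(self):
        labels = ["u", "a", "u", "a", "a", "u"]
        assert cohen_kappa(labels, labels).estimate == pytest.approx(1.0)

    def test_independent_marginals_give_zero(self):
        # contingency [[9, 1], [81, 9]]: p_o = p_e = 0.18
        result = cohen_kappa_from_table([[9, 1], [81, 9]])
        assert result.estimate == pytest.approx(0.0, abs=1e-12)

    def test_worked_contingency_example(self):
        result = cohen_kappa_from_table([[20, 5], [10, 15]])
        assert result.p_bar == pytest.approx(0.7)
        assert result.p_e == pytest.approx(0.5)
        assert result.estimate == pytest.approx(0.4, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            cohen_kappa(["a", "b"], ["a"])

    def test_single_shared_label_degenerate(self):
        with pytest.raises(DegenerateMarginalsError):
            cohen_kappa(["a", "a", "a"], ["a", "a", "a"])

    def test_matches_statsmodels_estimate_and_variance(self):
        rng = np.random.default_rng(29)
        checked = 0
        while checked < 100:
            k = int(rng.integers(2, 4))
            table = rng.integers(0, 12, size=(k, k))
            if table.sum() < 4:
                continue
            p = table / table.sum()
            p_e = float((p.sum(1) * p.sum(0)).sum())
            if p_e >= 1 - 1e-9 or p_e == 0:
                continue
            sm = sm_cohens_kappa(table, return_results=True)
            if not np.isfinite(sm.var_kappa) or sm.var_kappa < 0:
                continue  # degenerate table: asymptotic variance undefined
            ours = cohen_kappa_from_table(table)
            assert ours.estimate == pytest.approx(float(sm.kappa), abs=1e-12)
            assert ours.se == pytest.approx(float(np.sqrt(sm.var_kappa)), abs=1e-12)
            checked += 1

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(31)
        a = list(rng.choice(["x", "y", "z"], size=60))
        b = list(rng.choice(["x", "y", "z"], size=60))
        relabel = {"x": "q", "y": "r", "z": "p"}
        base = cohen_kappa(a, b)
        renamed = cohen_kappa([relabel[l] for l in a], [relabel[l] for l in b])
        assert renamed.estimate == pytest.approx(base.estimate, abs=1e-14)
        assert renamed.se == pytest.approx(base.se, abs=1e-14)


class TestConcordance:
    def test_unaided_ratings_counts(self, unaided_matrix):
        result = concordance_from_matrix(
            unaided_matrix, ["CA-ABU", "CA-UTI", "CA-ABU", "CA-ABU"]
        )
        assert (result.count, result.total) == (21, 40)
        assert result.percent == 53

    def test_all_concordant(self):
        result = concordance_rate([["u", "u"], ["a", "a"]], ["u", "a"])
        assert result.proportion == 1.0

    def test_partial_concordance_display(self):
        result = concordance_rate([["u", "a", "a"]], ["u"])
        assert result.proportion == pytest.approx(1 / 3)
        assert result.percent == 33

    def test_subject_order_invariance(self):
        ratings = [["u", "a"], ["a", "a"], ["u", "u"]]
        reference = ["u", "a", "a"]
        base = concordance_rate(ratings, reference)
        perm = [2, 0, 1]
        permuted = concordance_rate(
            [ratings[i] for i in perm], [reference[i] for i in perm]
        )
        assert permuted.count == base.count

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            concordance_rate([], [])


class TestInterpretationBand:
    @pytest.mark.parametrize(
        "kappa, band",
        [
            (-0.2, "poor"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.35, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.60, "moderate"),
            (0.63, "substantial"),
            (0.72, "substantial"),
            (0.80, "substantial"),
            (0.88, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_landis_koch_boundaries(self, kappa, band):
        assert interpretation_band(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            interpretation_band(1.5)


class TestTally:
    def test_face_validity_comment_categories(self):
        tally = tally_categories(
            {"correct": 123, "incorrect": 18, "over": 13, "misunderstood": 7, "off_topic": 3}
        )
        assert {cat: pct for cat, (_, pct) in tally.items()} == {
            "correct": 75,
            "incorrect": 11,
            "over": 8,
            "misunderstood": 4,
            "off_topic": 2,
        }

    def test_single_category_is_total(self):
        assert tally_categories({"only": 9}) == {"only": (9, 100)}

    def test_even_split(self):
        tally = tally_categories({"a": 1, "b": 1})
        assert tally["a"][1] == 50 and tally["b"][1] == 50

    def test_all_zero_rejected(self):
        with pytest.raises(InvalidInputError):
            tally_categories({"a": 0, "b": 0})


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [(0.525, 2, 0.53), (2.5, 0, 3.0), (-2.5, 0, -3.0), (0.205, 2, 0.21)],
    )
    def test_half_away_from_zero(self, value, ndigits, expected):
        assert round_half_away(value, ndigits) == expected
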