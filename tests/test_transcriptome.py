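"""Canonical mapping and hierarchical zero-rank filling."""

import numpy as np
import pytest

from cortodeconv import (
    CanonicalDistribution,
    ClassHierarchy,
    RankAssignment,
    TranscriptomeMatrix,
    apply_canonical,
    assign_zero_ranks,
    default_canonical,
    flat_hierarchy,
)
from cortodeconv.synth import make_transcriptomes
from cortodeconv.types import OBSERVED


def matrix(values, type_ids=None):
    values = np.asarray(values, dtype=float)
    return TranscriptomeMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        type_ids=type_ids or [f"t{j}" for j in range(values.shape[1])],
    )


class TestDefaultCanonical:
    def test_single_type_returns_own_sorted_values(self):
        T = matrix([[3.0], [1.0], [2.0]])
        assert np.array_equal(default_canonical(T).values, [1.0, 2.0, 3.0])

    def test_fewest_zeros_wins(self):
        T = matrix(np.array([[0, 1], [0, 2], [0, 0], [1, 3], [2, 0], [3, 4]], float))
        # zeros: type0 has 3, type1 has 2 -> type1
        assert np.array_equal(default_canonical(T).values, np.sort(T.values[:, 1]))

    def test_matches_brute_force_scan(self):
        T = make_transcriptomes(80, 10, completeness=(0.4, 0.95), seed=5)
        zeros = [(T.values[:, t] == 0).sum() for t in range(10)]
        best = int(np.argmin(zeros))  # generator makes ties impossible in practice
        assert zeros.count(min(zeros)) == 1
        assert np.array_equal(default_canonical(T).values, np.sort(T.values[:, best]))

    def test_tie_broken_by_larger_total(self):
        T = matrix(np.array([[1, 5], [2, 6], [0, 0]], float))
        assert np.array_equal(default_canonical(T).values, [0.0, 5.0, 6.0])


def two_level_hierarchy():
    return ClassHierarchy(levels=[{"fine": ["A", "B"]}, {"all": ["A", "B"]}])


class TestAssignZeroRanks:
    def test_complete_type_keeps_own_order(self):
        T = matrix(np.array([[3, 1], [1, 2], [2, 0]], float), type_ids=["A", "B"])
        ranks = assign_zero_ranks(T, two_level_hierarchy())
        assert np.array_equal(ranks.rank[:, 0], [2, 0, 1])
        assert (ranks.provenance[:, 0] == OBSERVED).all()

    def test_borrowed_key_straddles_observed_values(self):
        """A zero gene borrowing a class average of 4 ranks strictly
        between observed values 1 and 5 (hand-computed 4-gene case)."""
        T = matrix(
            np.array([[1, 2], [0, 4], [5, 6], [10, 12]], float), type_ids=["A", "B"]
        )
        ranks = assign_zero_ranks(T, two_level_hierarchy())
        col = ranks.rank[:, 0]
        assert col[0] < col[1] < col[2] < col[3]
        assert list(col) == [0, 1, 2, 3]
        assert ranks.provenance[1, 0] == 0  # filled at the finest level

    def test_tie_between_borrowed_and_observed_favors_observed(self):
        T = matrix(np.array([[4, 0], [0, 4], [9, 9]], float), type_ids=["A", "B"])
        ranks = assign_zero_ranks(T, two_level_hierarchy())
        # type A: g1 borrows key 4 (B's value); observed g0 also 4
        assert ranks.rank[0, 0] < ranks.rank[1, 0]

    def test_globally_missing_gene_sinks_to_lowest_ranks(self):
        T = matrix(np.array([[0, 0], [0, 0], [5, 6]], float), type_ids=["A", "B"])
        H = two_level_hierarchy()
        ranks = assign_zero_ranks(T, H)
        for t in range(2):
            assert ranks.rank[0, t] == 0 and ranks.rank[1, t] == 1  # gene-order ties
            assert (ranks.provenance[:2, t] == H.n_levels).all()

    def test_every_column_is_a_permutation(self):
        T = make_transcriptomes(60, 6, completeness=(0.3, 0.9), seed=8)
        ranks = assign_zero_ranks(T, flat_hierarchy(T.type_ids))
        for t in range(6):
            assert np.array_equal(np.sort(ranks.rank[:, t]), np.arange(60))

    def test_observed_ranks_respect_value_order(self):
        T = make_transcriptomes(60, 4, completeness=(0.5, 0.9), seed=9)
        ranks = assign_zero_ranks(T, flat_hierarchy(T.type_ids))
        for t in range(4):
            obs = np.flatnonzero(T.values[:, t] > 0)
            order = obs[np.argsort(T.values[obs, t], kind="stable")]
            assert (np.diff(ranks.rank[order, t]) > 0).all()

    def test_provenance_level_is_minimal(self):
        """A borrowed rank at level l implies every finer class average was 0."""
        H = ClassHierarchy(
            levels=[
                {"a": ["A"], "b": ["B", "C"]},
                {"all": ["A", "B", "C"]},
            ]
        )
        T = matrix(
            np.array([[0, 0, 0], [0, 3, 0], [2, 1, 4]], float), type_ids=["A", "B", "C"]
        )
        ranks = assign_zero_ranks(T, H)
        # g0 zero everywhere -> degenerate (level 2); g1 zero in A: fine
        # class {A} has no value, so it must come from level 1, not 0
        assert ranks.provenance[0, 0] == H.n_levels
        assert ranks.provenance[1, 0] == 1
        # g1 zero in C borrows from its own fine class {B, C} -> level 0
        assert ranks.provenance[1, 2] == 0

    def test_missing_type_in_hierarchy_rejected(self):
        T = matrix(np.ones((3, 2)), type_ids=["A", "B"])
        H = ClassHierarchy(levels=[{"all": ["A"]}])
        with pytest.raises(ValueError, match="B"):
            assign_zero_ranks(T, H)


class TestApplyCanonical:
    def test_identity_mapping_preserves_column(self):
        T = matrix(np.array([[3.0], [1.0], [2.0]]))
        ranks = assign_zero_ranks(T, ClassHierarchy(levels=[{"all": ["t0"]}]))
        canon = default_canonical(T)
        out = apply_canonical(T, ranks, canon)
        assert np.array_equal(out.values[:, 0], T.values[:, 0])

    def test_constant_canonical_gives_constant_matrix(self):
        T = make_transcriptomes(20, 3, seed=0)
        ranks = assign_zero_ranks(T, flat_hierarchy(T.type_ids))
        canon = CanonicalDistribution(values=np.ones(20))
        out = apply_canonical(T, ranks, canon)
        assert (out.values == 1.0).all()

    def test_every_sorted_column_equals_canonical_exactly(self, rng):
        """The "same shape" property: sorting any corrected column
        reproduces the canonical distribution bit-for-bit."""
        T = make_transcriptomes(100, 6, completeness=(0.4, 0.9), seed=3)
        ranks = assign_zero_ranks(T, flat_hierarchy(T.type_ids))
        canon = CanonicalDistribution(values=np.sort(rng.uniform(0, 50, 100)))
        out = apply_canonical(T, ranks, canon)
        for t in range(6):
            assert np.array_equal(np.sort(out.values[:, t]), canon.values)

    def test_monotone_on_observed_values(self):
        T = make_transcriptomes(80, 4, completeness=(0.5, 0.9), seed=4)
        ranks = assign_zero_ranks(T, flat_hierarchy(T.type_ids))
        out = apply_canonical(T, ranks, default_canonical(T))
        for t in range(4):
            obs = T.values[:, t] > 0
            order = np.argsort(T.values[obs, t], kind="stable")
            corrected = out.values[obs, t][order]
            assert (np.diff(corrected) >= 0).all()

    def test_non_permutation_rank_rejected(self):
        T = matrix(np.ones((3, 1)))
        with pytest.raises(ValueError, match="permutation"):
            RankAssignment(
                rank=np.array([[0], [0], [2]]),
                provenance=np.full((3, 1), OBSERVED),
                gene_ids=T.gene_ids,
                type_ids=T.type_ids,
            )

    def test_wrong_canonical_length_rejected(self):
        T = matrix(np.ones((3, 1)))
        ranks = assign_zero_ranks(T, ClassHierarchy(levels=[{"all": ["t0"]}]))
        with pytest.raises(ValueError, match="canonical"):
            apply_canonical(T, ranks, CanonicalDistribution(values=np.arange(5.0)))
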