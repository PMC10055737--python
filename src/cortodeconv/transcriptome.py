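"""Canonical-distribution standardization of cell-type transcriptomes.

scRNA-seq median transcriptomes differ in completeness (fraction of
genes with non-zero values) and in the shape of their sorted-value
curves, which would bias a linear fit against incompletely sampled
types.  The correction maps every type's sorted values onto one shared
canonical distribution: genes observed non-zero keep their own rank
order, genes missing from a type borrow a rank key — the class mean
over members with non-zero values — from the finest cell class that
has one, and the resulting full permutation indexes into the canonical
value template.  After mapping, every type's sorted transcriptome is
identical to the canonical distribution.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    OBSERVED,
    CanonicalDistribution,
    ClassHierarchy,
    RankAssignment,
    TranscriptomeMatrix,
)

logger = logging.getLogger(__name__)


def default_canonical(T: TranscriptomeMatrix) -> CanonicalDistribution:
    """Sorted values of the most complete type (fewest zero entries).

    Ties on the zero count go to the type with larger total expression.
    """
    zeros = (T.values == 0).sum(axis=0)
    totals = T.values.sum(axis=0)
    # lexicographic argmin: fewest zeros, then largest total, then first id
    order = np.lexsort((np.arange(T.n_types), -totals, zeros))
    best = order[0]
    logger.debug("canonical seeded from type %s (%d zeros)", T.type_ids[best], zeros[best])
    return CanonicalDistribution(values=np.sort(T.values[:, best]))


def _class_averages(T: TranscriptomeMatrix, H: ClassHierarchy) -> list[dict[str, np.ndarray]]:
    """Per level, per class: gene-wise mean over members' non-zero values."""
    type_index = {tid: i for i, tid in enumerate(T.type_ids)}
    out: list[dict[str, np.ndarray]] = []
    for level in H.levels:
        level_avg: dict[str, np.ndarray] = {}
        for cls, members in level.items():
            cols = [type_index[m] for m in members if m in type_index]
            if not cols:
                level_avg[cls] = np.zeros(T.n_genes)
                continue
            vals = T.values[:, cols]
            nz = vals > 0
            count = nz.sum(axis=1)
            total = np.where(nz, vals, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                avg = np.where(count > 0, total / np.maximum(count, 1), 0.0)
            level_avg[cls] = avg
        out.append(level_avg)
    return out


def assign_zero_ranks(T: TranscriptomeMatrix, H: ClassHierarchy) -> RankAssignment:
    """Build a full rank permutation per type, filling zeros hierarchically.

    Per type: non-zero genes are keyed by their own values; each zero
    gene takes, as key, the class average over non-zero member values
    from the finest hierarchy level whose average is non-zero
    (provenance records that level).  Genes zero in every class at
    every level keep key 0 and sink to the lowest ranks.  The joint
    ordering is deterministic: ties between an observed value and a
    borrowed key break toward the observed gene; remaining ties break
    by gene order.
    """
    H.validate_types(T.type_ids)
    averages = _class_averages(T, H)

    n_genes, n_types = T.values.shape
    rank = np.empty((n_genes, n_types), dtype=int)
    provenance = np.empty((n_genes, n_types), dtype=int)
    gene_order = np.arange(n_genes)

    for t, tid in enumerate(T.type_ids):
        observed = T.values[:, t]
        key = observed.copy()
        prov = np.full(n_genes, OBSERVED)
        unfilled = observed == 0
        prov[unfilled] = H.n_levels  # degenerate fallback unless a class supplies a key
        for level_idx in range(H.n_levels):
            if not unfilled.any():
                break
            cls = H.class_of(tid, level_idx)
            avg = averages[level_idx][cls]
            take = unfilled & (avg > 0)
            key[take] = avg[take]
            prov[take] = level_idx
            unfilled &= ~take
        borrowed = (prov != OBSERVED).astype(int)
        order = np.lexsort((gene_order, borrowed, key))
        rank[order, t] = np.arange(n_genes)
        provenance[:, t] = prov

    return RankAssignment(
        rank=rank, provenance=provenance,
        gene_ids=list(T.gene_ids), type_ids=list(T.type_ids),
    )


def apply_canonical(
    T: TranscriptomeMatrix,
    ranks: RankAssignment,
    canon: CanonicalDistribution,
) -> TranscriptomeMatrix:
    """Map each type onto the canonical distribution via its rank permutation.

    ``corrected[i, t] = canon[rank[i, t]]`` — so the sorted value vector
    of every corrected type equals the canonical distribution exactly.
    """
    if ranks.gene_ids != T.gene_ids or ranks.type_ids != T.type_ids:
        raise ValueError("rank assignment does not match the transcriptome matrix")
    if canon.n_genes != T.n_genes:
        raise ValueError(
            f"canonical distribution has {canon.n_genes} values for {T.n_genes} genes"
        )
    corrected = canon.values[ranks.rank]
    return TranscriptomeMatrix(
        values=corrected, gene_ids=list(T.gene_ids), type_ids=list(T.type_ids)
    )


def correct_transcriptome(
    T: TranscriptomeMatrix,
    H: ClassHierarchy,
    canon: CanonicalDistribution | None = None,
) -> tuple[TranscriptomeMatrix, RankAssignment, CanonicalDistribution]:
    """Convenience wrapper: ranks + canonical + corrected matrix in one call."""
    if canon is None:
        canon = default_canonical(T)
    ranks = assign_zero_ranks(T, H)
    return apply_canonical(T, ranks, canon), ranks, canon


def flat_hierarchy(type_ids: list[str]) -> ClassHierarchy:
    """Minimal two-level hierarchy: each type alone, then all cells.

    Useful for synthetic data where no biological taxonomy exists.
    """
    return ClassHierarchy(
        levels=[
            {tid: [tid] for tid in type_ids},
            {"all_cells": list(type_ids)},
        ]
    )
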