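"""Stochastic refinement of the canonical distribution.

The canonical distribution is perturbed with Gaussian noise, re-sorted,
and the whole correct-solve-predict-error chain is re-evaluated;
perturbations that strictly reduce the squared prediction error are
kept.  The loop stops after a fixed number of consecutive
non-improvements (patience) or a hard iteration cap.  A second,
optional local search re-orders the borrowed ranks of selected
non-neuronal classes (astrocytes, oligodendrocytes, microglia) to
reduce the RMSE of their predicted expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .solve import fit_error, predict_expression, solve_all
from .transcriptome import apply_canonical, assign_zero_ranks, default_canonical
from .types import (
    OBSERVED,
    CanonicalDistribution,
    ClassHierarchy,
    ExpressionTensor,
    RankAssignment,
    TranscriptomeMatrix,
)

logger = logging.getLogger(__name__)

DEFAULT_PATIENCE = 100
DEFAULT_MAX_ITER = 10_000


def perturb(
    canon: CanonicalDistribution, scale: float, rng: np.random.Generator
) -> CanonicalDistribution:
    """Add scale * N(0, 1) noise per entry, clip at 0, re-sort."""
    if scale < 0:
        raise ValueError("perturbation scale must be non-negative")
    values = canon.values + scale * rng.standard_normal(canon.n_genes)
    return CanonicalDistribution(values=np.sort(np.clip(values, 0.0, None)))


@dataclass
class RefinementTrace:
    """Per-iteration record of the accept-if-improved loop."""

    seed: int
    scale: float
    iterations: list[int] = field(default_factory=list)
    errors: list[float] = field(default_factory=list)
    accepted: list[bool] = field(default_factory=list)
    best_errors: list[float] = field(default_factory=list)

    def record(self, iteration: int, error: float, accepted: bool, best: float) -> None:
        self.iterations.append(iteration)
        self.errors.append(error)
        self.accepted.append(accepted)
        self.best_errors.append(best)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def n_accepted(self) -> int:
        return sum(self.accepted)

    @property
    def final_error(self) -> float:
        return self.best_errors[-1] if self.best_errors else float("nan")


def stratified_bin_subsample(E: ExpressionTensor, n_bins: int) -> np.ndarray:
    """Evenly spaced flat indices over the bins with any signal.

    Deterministic: the occupied bins are enumerated in grid order and
    every (len/n)-th one is taken, so the subsample covers all depths.
    """
    J, K = E.bins.n_depth_bins, E.bins.n_area_bins
    occupied = np.flatnonzero(E.values.reshape(E.values.shape[0], J * K).any(axis=0))
    if occupied.size == 0:
        return occupied
    if n_bins >= occupied.size:
        return occupied
    picks = np.linspace(0, occupied.size - 1, n_bins).round().astype(int)
    return occupied[np.unique(picks)]


def _masked_expression(E: ExpressionTensor, bin_indices: np.ndarray | None) -> ExpressionTensor:
    if bin_indices is None:
        return E
    J, K = E.bins.n_depth_bins, E.bins.n_area_bins
    flat = np.zeros_like(E.values.reshape(E.values.shape[0], J * K))
    flat[:, bin_indices] = E.values.reshape(E.values.shape[0], J * K)[:, bin_indices]
    return ExpressionTensor(
        values=flat.reshape(E.values.shape), gene_ids=list(E.gene_ids), bins=E.bins
    )


def _evaluate(
    T: TranscriptomeMatrix,
    ranks: RankAssignment,
    canon: CanonicalDistribution,
    E_masked: ExpressionTensor,
    bin_indices: np.ndarray | None,
) -> float:
    T_corr = apply_canonical(T, ranks, canon)
    C = solve_all(T_corr, E_masked, bin_indices=bin_indices)
    E_pred = predict_expression(T_corr, C)
    err, _ = fit_error(E_pred, E_masked)
    return err


def refine_canonical(
    T: TranscriptomeMatrix,
    H: ClassHierarchy,
    E: ExpressionTensor,
    canon0: CanonicalDistribution | None = None,
    scale: float | None = None,
    patience: int = DEFAULT_PATIENCE,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    subsample_bins: int | None = None,
) -> tuple[CanonicalDistribution, TranscriptomeMatrix, RefinementTrace]:
    """Accept-if-improved refinement of the canonical distribution.

    Starting from ``canon0`` (default: the most complete type's sorted
    transcriptome), repeatedly perturb, rebuild the corrected matrix,
    re-solve the deconvolution and keep the candidate iff the squared
    prediction error strictly decreases.  Convergence is declared after
    ``patience`` consecutive non-improvements; ``max_iter`` caps the
    loop.  ``subsample_bins`` evaluates candidates on a stratified bin
    subsample for speed; the returned corrected matrix always comes
    from the best canonical found.

    The default perturbation scale is 1% of the canonical maximum.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if canon0 is None:
        canon0 = default_canonical(T)
    if scale is None:
        scale = 0.01 * float(canon0.values.max())

    rng = np.random.default_rng(seed)
    ranks = assign_zero_ranks(T, H)
    bin_indices = (
        stratified_bin_subsample(E, subsample_bins) if subsample_bins is not None else None
    )
    E_masked = _masked_expression(E, bin_indices)

    best = canon0
    best_err = _evaluate(T, ranks, best, E_masked, bin_indices)
    trace = RefinementTrace(seed=seed, scale=scale)

    # The fit error is invariant to a global rescaling of the canonical
    # (NNLS absorbs it into the compositions), so that direction is an
    # unconstrained random walk.  Fix the gauge: every candidate is
    # rescaled to the starting canonical's mean, which the error cannot
    # distinguish from the un-rescaled candidate.
    gauge = float(canon0.values.mean())

    stale = 0
    for it in range(1, max_iter + 1):
        cand = perturb(best, scale, rng)
        cand_mean = float(cand.values.mean())
        if gauge > 0 and cand_mean > 0:
            cand = CanonicalDistribution(values=cand.values * (gauge / cand_mean))
        err = _evaluate(T, ranks, cand, E_masked, bin_indices)
        accepted = err < best_err
        if accepted:
            best, best_err = cand, err
            stale = 0
        else:
            stale += 1
        trace.record(it, err, accepted, best_err)
        if stale >= patience:
            break
    logger.info(
        "refinement: %d iterations, %d accepted, final error %.6g",
        trace.n_iterations, trace.n_accepted, best_err,
    )

    T_corr = apply_canonical(T, ranks, best)
    return best, T_corr, trace


# --------------------------------------------------------------------------
# non-neuronal rank adjustment


def _class_rmse(
    T_corr: TranscriptomeMatrix,
    E: ExpressionTensor,
    gene_rows: np.ndarray,
    bin_indices: np.ndarray | None,
) -> float:
    C = solve_all(T_corr, E, bin_indices=bin_indices)
    E_pred = predict_expression(T_corr, C)
    p = E_pred.values.sum(axis=(1, 2))[gene_rows]
    o = E.values.sum(axis=(1, 2))[gene_rows]
    return float(np.sqrt(((p - o) ** 2).mean()))


def adjust_nonneuronal_ranks(
    T: TranscriptomeMatrix,
    H: ClassHierarchy,
    E: ExpressionTensor,
    classes: list[str],
    class_rank_floor: dict[str, int],
    canon: CanonicalDistribution | None = None,
    ranks: RankAssignment | None = None,
    seed: int = 0,
    max_iter: int = 200,
    subsample_bins: int | None = None,
) -> RankAssignment:
    """Locally re-order borrowed ranks of selected classes.

    For each listed class (typically astrocytes, oligodendrocytes and
    microglia, whose transcriptomes are least complete), the zero-valued
    genes of every member type whose current rank exceeds the class's
    rank floor are subjected to pairwise-swap hill climbing: a random
    pair of those genes exchanges ranks, and the swap is kept iff the
    RMSE between predicted and observed summed expression over those
    genes decreases.  Observed ranks and all other classes are
    untouched.
    """
    if canon is None:
        canon = default_canonical(T)
    if ranks is None:
        ranks = assign_zero_ranks(T, H)
    for cls in classes:
        H.find_class(cls)  # raises for unknown names
        if cls not in class_rank_floor:
            raise ValueError(f"no rank floor given for class {cls!r}")

    rng = np.random.default_rng(seed)
    rank = ranks.rank.copy()
    type_index = {tid: i for i, tid in enumerate(T.type_ids)}
    bin_indices = (
        stratified_bin_subsample(E, subsample_bins) if subsample_bins is not None else None
    )
    E_eval = _masked_expression(E, bin_indices)

    for cls in classes:
        floor = class_rank_floor[cls]
        _, members = H.find_class(cls)
        for tid in members:
            if tid not in type_index:
                continue
            t = type_index[tid]
            zero = ranks.provenance[:, t] != OBSERVED
            movable = np.flatnonzero(zero & (rank[:, t] > floor))
            if movable.size < 2:
                continue
            gene_rows = movable

            def rebuild() -> TranscriptomeMatrix:
                working = RankAssignment(
                    rank=rank, provenance=ranks.provenance,
                    gene_ids=ranks.gene_ids, type_ids=ranks.type_ids,
                )
                return apply_canonical(T, working, canon)

            best_rmse = _class_rmse(rebuild(), E_eval, gene_rows, bin_indices)
            for _ in range(max_iter):
                a, b = rng.choice(movable, size=2, replace=False)
                rank[[a, b], t] = rank[[b, a], t]
                rmse = _class_rmse(rebuild(), E_eval, gene_rows, bin_indices)
                if rmse < best_rmse:
                    best_rmse = rmse
                else:
                    rank[[a, b], t] = rank[[b, a], t]  # revert

    return RankAssignment(
        rank=rank, provenance=ranks.provenance.copy(),
        gene_ids=list(ranks.gene_ids), type_ids=list(ranks.type_ids),
    )
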