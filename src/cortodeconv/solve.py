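"""Per-bin non-negative least-squares deconvolution.

Within each depth-area bin the ISH intensity vector over genes is
modelled as the corrected transcriptome matrix times a non-negative
cell-composition vector, ``e_jk = T c_jk``; NNLS solves each bin
independently.  Because the design matrix is shared across all bins,
a thin QR factorization reduces every bin to a tiny
``n_types x n_types`` problem with the same minimizer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .types import CompositionSolution, ExpressionTensor, TranscriptomeMatrix

logger = logging.getLogger(__name__)


def solve_bin(T_values: np.ndarray, e: np.ndarray) -> np.ndarray:
    """NNLS composition for one bin: argmin_{c >= 0} ||T c - e||_2."""
    T_values = np.asarray(T_values, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.isnan(T_values).any() or np.isnan(e).any():
        raise ValueError("NaN in NNLS inputs")
    if e.shape[0] != T_values.shape[0]:
        raise ValueError(f"intensity vector length {e.shape[0]} != {T_values.shape[0]} genes")
    c, _ = nnls(T_values, e)
    return c


@dataclass
class _SharedDesign:
    """QR-compressed design shared by every bin."""

    A: np.ndarray
    Q: np.ndarray | None
    R: np.ndarray | None

    @classmethod
    def build(cls, A: np.ndarray) -> "_SharedDesign":
        Q, R = np.linalg.qr(A)
        # ||A c - e||^2 = ||R c - Q^T e||^2 + const, valid when A has
        # full column rank; otherwise fall back to the full problem.
        if np.abs(np.diag(R)).min() > 1e-10 * max(1.0, np.abs(R).max()):
            return cls(A=A, Q=Q, R=R)
        return cls(A=A, Q=None, R=None)

    def solve(self, e: np.ndarray) -> np.ndarray:
        if self.R is not None:
            c, _ = nnls(self.R, self.Q.T @ e)
            return c
        return solve_bin(self.A, e)


def align_genes(
    T_corr: TranscriptomeMatrix,
    E: ExpressionTensor,
    min_gene_overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Inner-join gene sets by id, ordered by the transcriptome matrix.

    Returns (T values, E values, common gene ids) restricted to the
    shared genes.  Errors out when the overlap fraction relative to
    either side falls below ``min_gene_overlap``.
    """
    e_index = {g: i for i, g in enumerate(E.gene_ids)}
    common = [g for g in T_corr.gene_ids if g in e_index]
    frac = len(common) / max(1, min(len(T_corr.gene_ids), len(E.gene_ids)))
    if frac < min_gene_overlap:
        raise ValueError(
            f"gene overlap {frac:.1%} below the {min_gene_overlap:.0%} threshold "
            f"({len(common)} shared genes)"
        )
    dropped = (len(T_corr.gene_ids) - len(common)) + (len(E.gene_ids) - len(common))
    if dropped:
        logger.info("align_genes: dropped %d unshared gene entries", dropped)
    t_rows = [T_corr.gene_ids.index(g) for g in common] if common != T_corr.gene_ids else None
    A = T_corr.values if t_rows is None else T_corr.values[t_rows]
    e_rows = [e_index[g] for g in common]
    Evals = E.values if common == E.gene_ids else E.values[e_rows]
    return A, Evals, common


def solve_all(
    T_corr: TranscriptomeMatrix,
    E: ExpressionTensor,
    min_gene_overlap: float = 0.5,
    bin_indices: np.ndarray | None = None,
) -> CompositionSolution:
    """Solve the NNLS deconvolution independently in every bin.

    Bins with an all-zero intensity vector yield zero compositions.
    ``bin_indices`` (flat indices into the depth x area grid) restricts
    the solve to a subset of bins, leaving the rest zero — used by the
    refinement loop to evaluate candidate canonical distributions on a
    stratified subsample.
    """
    A, Evals, _ = align_genes(T_corr, E, min_gene_overlap)
    J, K = E.bins.n_depth_bins, E.bins.n_area_bins
    flat = Evals.reshape(Evals.shape[0], J * K)
    design = _SharedDesign.build(A)

    C = np.zeros((T_corr.n_types, J * K))
    if bin_indices is None:
        bin_indices = np.arange(J * K)
    for b in np.asarray(bin_indices, dtype=int):
        e = flat[:, b]
        if e.any():
            C[:, b] = design.solve(e)
    return CompositionSolution(
        values=C.reshape(T_corr.n_types, J, K),
        type_ids=list(T_corr.type_ids),
        bins=E.bins,
    )


def predict_expression(T_corr: TranscriptomeMatrix, C: CompositionSolution) -> ExpressionTensor:
    """Forward model: E_pred[., j, k] = T_corr @ C[., j, k]."""
    if T_corr.type_ids != C.type_ids:
        raise ValueError("transcriptome and composition type sets differ")
    values = np.einsum("gt,tjk->gjk", T_corr.values, C.values)
    return ExpressionTensor(values=values, gene_ids=list(T_corr.gene_ids), bins=C.bins)


@dataclass
class FitReport:
    """Prediction-quality summary for a solved composition.

    ``per_gene_predicted`` / ``per_gene_observed`` are each gene's
    expression summed over all bins (the scatter data of a
    predicted-vs-actual plot); ``total_squared_error`` is the sum over
    genes of the squared difference of those sums.
    """

    gene_ids: list[str]
    per_gene_predicted: np.ndarray
    per_gene_observed: np.ndarray
    total_squared_error: float
    per_bin_residual_norm: np.ndarray


def fit_error(E_pred: ExpressionTensor, E: ExpressionTensor) -> tuple[float, FitReport]:
    """Squared error between predicted and observed per-gene summed expression."""
    if E_pred.values.shape != E.values.shape:
        raise ValueError("predicted and observed tensors differ in shape")
    p = E_pred.values.sum(axis=(1, 2))
    o = E.values.sum(axis=(1, 2))
    err = float(((p - o) ** 2).sum())
    residual_norm = np.sqrt(((E_pred.values - E.values) ** 2).sum(axis=0))
    report = FitReport(
        gene_ids=list(E.gene_ids),
        per_gene_predicted=p,
        per_gene_observed=o,
        total_squared_error=err,
        per_bin_residual_norm=residual_norm,
    )
    return err, report
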