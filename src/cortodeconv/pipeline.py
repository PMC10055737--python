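"""End-to-end pipeline driver.

Runs normalize -> canonical mapping -> (optional) refinement -> solve
-> anchoring on an expression tensor, Nissl density map, transcriptome
table and class hierarchy, writing every intermediate plus a manifest
recording the config hash, seed and library versions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import density, io, normalize, refine, solve, transcriptome
from .types import (
    CanonicalDistribution,
    ClassHierarchy,
    CompositionSolution,
    DensityMap,
    DepthProfile,
    ExpressionTensor,
    LayerBounds,
    SizeKernel,
    TranscriptomeMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    composition: CompositionSolution
    profiles: dict[str, DepthProfile]
    kernels: dict[str, SizeKernel]
    canonical: CanonicalDistribution
    T_corr: TranscriptomeMatrix
    trace: refine.RefinementTrace | None


def _stage(name: str, path: str | None, reader, what: str):
    if path is None:
        raise ValueError(f"stage {name!r}: no {what} path configured")
    try:
        return reader(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage {name!r} failed on {path}: {exc}") from exc


def run_pipeline(config: io.PipelineConfig) -> PipelineResult:
    """Execute the full deconvolution pipeline from a validated config."""
    E = _stage("load", config.expression, io.read_expression, "expression tensor")
    nissl = _stage("load", config.nissl, io.read_density_map, "Nissl density map")
    T = _stage("load", config.transcriptome, io.read_transcriptome_tsv, "transcriptome")
    H = _stage("load", config.hierarchy, io.read_hierarchy_json, "class hierarchy")

    if config.type_filter:
        keep = [t for t in T.type_ids if t in set(config.type_filter)]
        if not keep:
            raise ValueError("type_filter removed every type")
        cols = [T.type_ids.index(t) for t in keep]
        T = TranscriptomeMatrix(values=T.values[:, cols], gene_ids=T.gene_ids, type_ids=keep)

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    # -- normalization (per-bin median first, then depth rescaling)
    logger.info("stage normalize")
    if config.median_first:
        E_norm = normalize.depth_rescale(normalize.median_normalize(E), nissl)
    else:
        E_norm = normalize.median_normalize(normalize.depth_rescale(E, nissl))
    io.write_expression(E_norm, out / "expression_normalized.npz")

    # -- canonical mapping (+ optional stochastic refinement)
    trace = None
    if config.refine:
        logger.info("stage refine")
        canon, T_corr, trace = refine.refine_canonical(
            T, H, E_norm,
            scale=config.scale,
            patience=config.patience,
            max_iter=config.max_iter,
            seed=config.seed,
            subsample_bins=config.subsample_bins,
        )
        _write_trace(trace, out / "refinement_trace.csv")
    else:
        logger.info("stage canonical")
        T_corr, _, canon = transcriptome.correct_transcriptome(T, H)
    io.write_transcriptome_tsv(T_corr, out / "transcriptome_corrected.tsv")

    # -- per-bin NNLS solve
    logger.info("stage solve")
    C = solve.solve_all(T_corr, E_norm)
    E_pred = solve.predict_expression(T_corr, C)
    err, _ = solve.fit_error(E_pred, E_norm)
    logger.info("fit squared error: %.6g", err)

    # -- anchoring and marginals
    logger.info("stage density")
    C_vol = density.areal_to_volumetric(C, config.slice_thickness_um)
    neuron_types = config.neuron_types or list(C.type_ids)
    C_anchored = density.anchor_densities(
        C_vol,
        neuron_types=neuron_types,
        layers=LayerBounds(tuple(config.layer_bounds)),
        target=config.anchor_target,
    )
    profiles = density.depth_profiles(C_anchored)
    kernels = density.size_kernels(C_anchored)

    io.write_composition(C_anchored, out / "composition.npz")
    io.write_profiles_tsv(profiles, out / "depth_profiles.tsv")
    io.write_kernels_tsv(kernels, out / "size_kernels.tsv")
    io.write_manifest(
        out / "manifest.json", config, extra={"fit_squared_error": err}
    )
    return PipelineResult(
        composition=C_anchored,
        profiles=profiles,
        kernels=kernels,
        canonical=canon,
        T_corr=T_corr,
        trace=trace,
    )


def _write_trace(trace: refine.RefinementTrace, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "iteration": trace.iterations,
            "error": trace.errors,
            "accepted": trace.accepted,
            "best_error": trace.best_errors,
        }
    ).to_csv(path, index=False)
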