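"""Anchored densities, depth profiles and soma-size kernels.

The NNLS compositions are relative: the ISH intensity scale is
arbitrary after normalization.  Densities are therefore anchored by a
single global scalar chosen so the mean neuron density over the depth
window from the top of layer 2 to the bottom of layer 6b equals a
literature value (120,000 cells/mm^3 by default).  Depth profiles and
per-type soma-size kernels are marginals of the anchored composition.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    ClassHierarchy,
    CompositionSolution,
    DepthProfile,
    LayerBounds,
    SizeKernel,
)

logger = logging.getLogger(__name__)

NEURON_DENSITY_TARGET = 120_000.0  # cells/mm^3, mean over L2-L6
DEFAULT_SLICE_THICKNESS_UM = 25.0


def areal_to_volumetric(
    C: CompositionSolution, slice_thickness_um: float = DEFAULT_SLICE_THICKNESS_UM
) -> CompositionSolution:
    """Convert cells/mm^2 to cells/mm^3 by dividing by slice thickness.

    The anchoring scalar absorbs this constant, so the choice of
    thickness does not affect anchored results; it only makes
    un-anchored intermediates dimensionally sensible.
    """
    if slice_thickness_um <= 0:
        raise ValueError("slice_thickness_um must be positive")
    return CompositionSolution(
        values=C.values / (slice_thickness_um * 1e-3),
        type_ids=list(C.type_ids),
        bins=C.bins,
    )


def anchor_densities(
    C: CompositionSolution,
    neuron_types: list[str],
    layers: LayerBounds = LayerBounds(),
    target: float = NEURON_DENSITY_TARGET,
) -> CompositionSolution:
    """Globally rescale so mean neuron density over L2-L6 hits the target.

    The anchor window is the set of depth bins whose midpoint lies in
    (L1 bottom, 100%].  One scalar multiplies ALL types (neuronal and
    not), so relative compositions are preserved.
    """
    if not neuron_types:
        raise ValueError("neuron_types must be non-empty")
    if target <= 0:
        raise ValueError("anchor target must be positive")
    missing = [t for t in neuron_types if t not in C.type_ids]
    if missing:
        raise ValueError(f"neuron types absent from the composition: {missing}")

    midpoints = C.bins.depth_bin_midpoints_percent()
    window = midpoints > layers.boundaries[0]
    rows = [C.type_ids.index(t) for t in neuron_types]
    neuron_profile = C.values[rows].sum(axis=(0, 2))  # per depth bin
    mean_density = neuron_profile[window].mean()
    if mean_density == 0:
        raise ValueError("zero neuron density in the anchoring window")
    factor = target / mean_density
    logger.info("anchoring: factor %.4g (pre-anchor mean %.4g)", factor, mean_density)
    return CompositionSolution(
        values=C.values * factor, type_ids=list(C.type_ids), bins=C.bins
    )


def depth_profiles(C: CompositionSolution) -> dict[str, DepthProfile]:
    """Per-type density vs depth: sum over the soma-area bins."""
    return {
        tid: DepthProfile(values=C.values[t].sum(axis=1))
        for t, tid in enumerate(C.type_ids)
    }


def size_kernels(C: CompositionSolution) -> dict[str, SizeKernel]:
    """Per-type soma-size distribution: sum over depth, normalized to 1.

    Types with zero total density yield an all-zero kernel and a log
    entry.
    """
    kernels: dict[str, SizeKernel] = {}
    for t, tid in enumerate(C.type_ids):
        by_area = C.values[t].sum(axis=0)
        total = by_area.sum()
        if total == 0:
            logger.info("size_kernels: type %s has zero density; kernel left zero", tid)
            kernels[tid] = SizeKernel(weights=by_area)
        else:
            kernels[tid] = SizeKernel(weights=by_area / total)
    return kernels


def class_profiles(
    profiles: dict[str, DepthProfile], H: ClassHierarchy, class_name: str
) -> DepthProfile:
    """Sum member-type depth profiles into a broad-class profile."""
    _, members = H.find_class(class_name)
    present = [m for m in members if m in profiles]
    if not present:
        raise ValueError(f"class {class_name!r} has no member with a profile")
    n_bins = profiles[present[0]].n_bins
    total = np.zeros(n_bins)
    for m in present:
        total += profiles[m].values
    return DepthProfile(values=total)
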