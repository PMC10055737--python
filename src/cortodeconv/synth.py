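"""Ground-truthed synthetic inputs for every pipeline stage.

The generators emulate the statistical structure the pipeline assumes:
cell-type transcriptomes with variable completeness and sorted-curve
shape, layered depth profiles with type-specific soma-size kernels, the
linear ISH forward model with multiplicative per-slice intensity noise,
and planted-disk raster images for the soma detector.  Every generator
is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .types import (
    BinSpec,
    CanonicalDistribution,
    CompositionSolution,
    ExpressionTensor,
    LayerBounds,
    SizeKernel,
    TranscriptomeMatrix,
)

logger = logging.getLogger(__name__)

#: factor by which a type's own marker-gene block is boosted; keeps the
#: column-normalized matrix well-conditioned at small type counts.
MARKER_BOOST = 10.0

#: default multiplicative ISH noise level (coefficient of variation).
DEFAULT_NOISE_CV = 0.1


@dataclass
class GroundTruth:
    """Planted truth bundle used by recovery tests."""

    transcriptomes: TranscriptomeMatrix
    densities: CompositionSolution
    kernels: dict[str, SizeKernel]
    canonical: CanonicalDistribution
    seed: int


# --------------------------------------------------------------------------
# transcriptomes


def make_transcriptomes(
    n_genes: int,
    n_types: int,
    completeness: tuple[float, float] = (0.5, 0.9),
    shape_spread: float = 0.5,
    seed: int = 0,
) -> TranscriptomeMatrix:
    """Generate a gene x type median-expression matrix with dropout.

    Each type's value vector is lognormal with a type-specific sigma
    (so sorted-value curves differ in shape), and each type has a
    distinct block of boosted marker genes (so columns are linearly
    well-separated).  A per-type fraction of entries, drawn uniformly
    from ``1 - completeness``, is zeroed; the zeros are placed in the
    lowest-value entries, mimicking dropout of weakly expressed genes
    while preserving sortability.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    if n_types < 1:
        raise ValueError(f"n_types must be >= 1, got {n_types}")
    if n_genes < n_types:
        raise ValueError(f"n_genes ({n_genes}) must be >= n_types ({n_types})")
    lo, hi = completeness
    if not (0 < lo <= hi <= 1):
        raise ValueError(f"completeness must satisfy 0 < lo <= hi <= 1, got {completeness}")
    if shape_spread < 0:
        raise ValueError(f"shape_spread must be non-negative, got {shape_spread}")

    rng = np.random.default_rng(seed)
    values = np.empty((n_genes, n_types))
    # marker block for type t: genes [t*block, (t+1)*block)
    block = n_genes // n_types
    for t in range(n_types):
        sigma = 1.0 + shape_spread * rng.uniform(-0.8, 0.8)
        col = rng.lognormal(mean=0.0, sigma=sigma, size=n_genes)
        start = t * block
        stop = (t + 1) * block if t < n_types - 1 else n_genes
        col[start:stop] *= MARKER_BOOST
        values[:, t] = col

    for t in range(n_types):
        frac_zero = 1.0 - rng.uniform(lo, hi)
        n_zero = int(round(frac_zero * n_genes))
        if n_zero:
            lowest = np.argsort(values[:, t], kind="stable")[:n_zero]
            values[lowest, t] = 0.0

    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    type_ids = [f"x{t + 1}_Type{t + 1}" for t in range(n_types)]
    return TranscriptomeMatrix(values=values, gene_ids=gene_ids, type_ids=type_ids)


# --------------------------------------------------------------------------
# planted densities


def make_density_truth(
    n_types: int,
    layer_bounds: LayerBounds | tuple[float, ...] = LayerBounds(),
    mean_density: float = 120_000.0,
    seed: int = 0,
    bins: BinSpec = BinSpec(),
) -> tuple[CompositionSolution, dict[str, SizeKernel]]:
    """Plant layered per-type densities and unimodal soma-size kernels.

    Each type's depth profile is a Gaussian bump centred in one layer
    (cycled over layers 2..6b so the anchoring window is populated);
    its size kernel is a discretized Gaussian over the area bins.  The
    density array is ``profile x kernel`` (separable by construction)
    and is scaled so the mean total density over depth bins whose
    midpoint lies in the window from the first boundary to 100% depth
    equals ``mean_density`` (cells/mm^3).
    """
    if n_types < 1:
        raise ValueError(f"n_types must be >= 1, got {n_types}")
    if not isinstance(layer_bounds, LayerBounds):
        layer_bounds = LayerBounds(tuple(layer_bounds))
    if mean_density <= 0:
        raise ValueError("mean_density must be positive")

    rng = np.random.default_rng(seed)
    intervals = layer_bounds.intervals()
    # skip L1 so planted mass sits inside the anchoring window
    usable = intervals[1:] if len(intervals) > 1 else intervals
    midpoints = bins.depth_bin_midpoints_percent()

    profiles = np.empty((n_types, bins.n_depth_bins))
    kernels = np.empty((n_types, bins.n_area_bins))
    for t in range(n_types):
        top, bottom = usable[t % len(usable)]
        center = 0.5 * (top + bottom) + rng.uniform(-0.1, 0.1) * (bottom - top)
        sd = (bottom - top) / 5.0
        amp = rng.uniform(0.5, 1.5)
        bump = amp * np.exp(-0.5 * ((midpoints - center) / sd) ** 2)
        # layer confinement: real layer-specific types vanish outside
        # their layer rather than trailing off as infinite Gaussian tails
        bump[(midpoints < top) | (midpoints > bottom)] = 0.0
        bump[bump < 1e-3 * amp] = 0.0
        profiles[t] = bump

        k_center = rng.uniform(2.0, 15.0)
        k_sd = rng.uniform(1.0, 3.0)
        k = np.exp(-0.5 * ((np.arange(bins.n_area_bins) - k_center) / k_sd) ** 2)
        kernels[t] = k / k.sum()

    values = profiles[:, :, None] * kernels[:, None, :]

    window = midpoints > layer_bounds.boundaries[0]
    window_mean = values.sum(axis=(0, 2))[window].mean()
    values *= mean_density / window_mean

    type_ids = [f"x{t + 1}_Type{t + 1}" for t in range(n_types)]
    comp = CompositionSolution(values=values, type_ids=type_ids, bins=bins)
    kernel_map = {tid: SizeKernel(weights=kernels[t]) for t, tid in enumerate(type_ids)}
    return comp, kernel_map


# --------------------------------------------------------------------------
# forward model


def make_expression(
    T: TranscriptomeMatrix,
    C: CompositionSolution,
    intensity_per_area: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> ExpressionTensor:
    """Simulate the ISH intensity tensor E from planted T and C.

    ``E[i,j,k] = (sum_t T[i,t] C[t,j,k]) * areaScale(k) * noise(i,j)``
    where ``areaScale(k) = 1 + intensity_per_area * midpoint_px(k)``
    (soma intensity integrates over soma area, so larger-soma bins are
    brighter per cell) and the noise is mean-1 lognormal with the
    requested coefficient of variation, drawn independently per
    (gene, depth bin) to mimic per-slice labelling variability.
    """
    if T.type_ids != C.type_ids:
        raise ValueError("transcriptome and composition type sets differ")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")

    base = np.einsum("gt,tjk->gjk", T.values, C.values)
    scale = 1.0 + intensity_per_area * C.bins.area_bin_midpoints_px()
    values = base * scale[None, None, :]

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma2 = np.log1p(noise_cv**2)
        noise = rng.lognormal(
            mean=-sigma2 / 2.0,
            sigma=np.sqrt(sigma2),
            size=(T.n_genes, C.bins.n_depth_bins),
        )
        values = values * noise[:, :, None]

    return ExpressionTensor(values=values, gene_ids=list(T.gene_ids), bins=C.bins)


# --------------------------------------------------------------------------
# raster images


@dataclass
class PlantedSpot:
    """Ground truth for one planted disk."""

    center: tuple[float, float]  # (row, col)
    radius_px: float
    peak_intensity: float
    area_px: int = 0
    integrated_intensity: float = 0.0
    merged: bool = False


@dataclass
class SyntheticImage:
    image: np.ndarray
    spots: list[PlantedSpot] = field(default_factory=list)
    baseline: float = 0.0


def make_image(
    spots: list[tuple[tuple[float, float], float, float]],
    canvas: tuple[int, int] = (256, 256),
    baseline: float = 100.0,
    seed: int = 0,
) -> SyntheticImage:
    """Render filled disks on a constant baseline, with planted truth.

    ``spots`` is a list of ``((row, col), radius_px, peak_intensity)``.
    A pixel belongs to a disk when its centre lies within the radius
    (no anti-aliasing).  Overlapping disks are rendered as the maximum
    of their contributions and flagged ``merged`` in the ground truth,
    since a connected-component detector will see them as one object.
    The ``seed`` argument is accepted for interface symmetry; the
    renderer itself is noise-free.
    """
    h, w = canvas
    if h < 1 or w < 1:
        raise ValueError("canvas must be positive")
    image = np.full((h, w), float(baseline))
    rows, cols = np.mgrid[0:h, 0:w]

    planted: list[PlantedSpot] = []
    pixel_sets: list[np.ndarray] = []
    for (cy, cx), radius, peak in spots:
        if radius < 1:
            raise ValueError(f"spot radius must be >= 1 px, got {radius}")
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"spot centre {(cy, cx)} outside canvas {canvas}")
        inside = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius**2
        area = int(inside.sum())
        image[inside] = np.maximum(image[inside], baseline + peak)
        planted.append(
            PlantedSpot(
                center=(cy, cx),
                radius_px=radius,
                peak_intensity=peak,
                area_px=area,
                integrated_intensity=area * peak,
            )
        )
        pixel_sets.append(inside)

    for a in range(len(planted)):
        for b in range(a + 1, len(planted)):
            if (pixel_sets[a] & pixel_sets[b]).any():
                planted[a].merged = True
                planted[b].merged = True

    return SyntheticImage(image=image, spots=planted, baseline=float(baseline))


# --------------------------------------------------------------------------
# full bundle


def make_ground_truth(
    n_genes: int = 500,
    n_types: int = 5,
    completeness: tuple[float, float] = (0.5, 0.9),
    shape_spread: float = 0.5,
    mean_density: float = 120_000.0,
    seed: int = 0,
    bins: BinSpec = BinSpec(),
) -> GroundTruth:
    """Generate a consistent (T, C, kernels, canonical) truth bundle."""
    T = make_transcriptomes(n_genes, n_types, completeness, shape_spread, seed=seed)
    C, kernels = make_density_truth(
        n_types, mean_density=mean_density, seed=seed + 1, bins=bins
    )
    canonical = CanonicalDistribution(values=np.sort(T.values.max(axis=1)))
    return GroundTruth(
        transcriptomes=T, densities=C, kernels=kernels, canonical=canonical, seed=seed
    )
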