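"""Soma detection and area-depth binning of ISH / Nissl images.

Detection runs on an annotated cortical cross-section: estimate the
image baseline as the modal intensity of the annotated region, subtract
it, threshold, label connected components, and keep the compact
("circular") ones as putative cell somas.  Each retained soma is then
assigned to one of 100 normalized-depth bins and 40 soma-area bins
(20 px each), and counts / integrated intensities are divided by the
annotated slice area at that depth to give densities per mm^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .types import AnnotatedRegion, BinSpec, DensityMap, Spot, SpotSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Detector configuration.

    threshold_k: spots must exceed baseline + k * MAD of the annotated
        pixels; the median absolute deviation resists bright outliers.
    min_spot_area: components smaller than this (px) are discarded.
    min_circularity: 4*pi*area/perimeter^2 cut that removes elongated
        artifacts such as dendrite fragments.
    float_bin_width: histogram bin width used for the baseline mode of
        floating-point images (integer images use unit bins).
    """

    threshold_k: float = 3.0
    min_spot_area: int = 4
    min_circularity: float = 0.6
    float_bin_width: float = 1.0


def estimate_baseline(region: AnnotatedRegion, float_bin_width: float = 1.0) -> float:
    """Modal intensity of the annotated pixels.

    Integer images use exact value counts; floating-point images are
    histogrammed at ``float_bin_width`` and the modal bin centre is
    returned.  Ties go to the lowest intensity.
    """
    pixels = region.image[region.mask]
    if pixels.size == 0:
        raise ValueError(f"region {region.source_id!r}: mask is empty")
    if np.issubdtype(region.image.dtype, np.integer):
        values, counts = np.unique(pixels, return_counts=True)
        return float(values[np.argmax(counts)])
    if float_bin_width <= 0:
        raise ValueError("float_bin_width must be positive")
    lo = float(pixels.min())
    idx = np.floor((pixels - lo) / float_bin_width).astype(int)
    counts = np.bincount(idx)
    return lo + (np.argmax(counts) + 0.5) * float_bin_width


def region_area_by_depth(region: AnnotatedRegion, bins: BinSpec) -> np.ndarray:
    """Annotated slice area (mm^2) in each normalized-depth bin."""
    depths = region.depth_of_pixel[region.mask]
    j = bins.depth_bin(depths)
    counts = np.bincount(j, minlength=bins.n_depth_bins)
    return counts * region.pixel_area_um2 * 1e-6


def detect_spots(
    region: AnnotatedRegion,
    baseline: float | None = None,
    params: DetectionParams = DetectionParams(),
    bins: BinSpec = BinSpec(),
) -> SpotSet:
    """Detect putative cell somas in an annotated region.

    Pixels above ``baseline + threshold_k * MAD`` inside the mask are
    labelled with 8-connectivity; components passing the minimum-area
    and circularity filters become spots.  A spot's depth is the mean
    normalized depth of its pixels; its intensity is the sum of the
    baseline-subtracted (floored at 0) pixel values.
    """
    if baseline is None:
        baseline = estimate_baseline(region, params.float_bin_width)
    if baseline < 0:
        raise ValueError("baseline must be non-negative")

    img = region.image.astype(float)
    masked = img[region.mask]
    mad = float(np.median(np.abs(masked - np.median(masked))))
    threshold = baseline + params.threshold_k * mad

    above = (img > threshold) & region.mask
    labels = measure.label(above, connectivity=2)
    residual = np.clip(img - baseline, 0.0, None)

    spots: list[Spot] = []
    for prop in measure.regionprops(labels, intensity_image=residual):
        area = int(prop.area)
        if area < params.min_spot_area:
            continue
        perimeter = prop.perimeter
        circularity = 1.0 if perimeter == 0 else min(1.0, 4 * np.pi * area / perimeter**2)
        if circularity < params.min_circularity:
            continue
        coords = prop.coords
        depth = float(np.clip(region.depth_of_pixel[coords[:, 0], coords[:, 1]].mean(), 0, 1))
        intensity = float(residual[coords[:, 0], coords[:, 1]].sum())
        spots.append(
            Spot(
                centroid_depth=depth,
                area_px=area,
                integrated_intensity=intensity,
                circularity=circularity,
            )
        )

    logger.debug("region %s: %d spots retained", region.source_id, len(spots))
    return SpotSet(
        spots=spots,
        source_id=region.source_id,
        region_area_by_depth=region_area_by_depth(region, bins),
    )


def bin_spots(spotset: SpotSet, bins: BinSpec = BinSpec()) -> tuple[DensityMap, DensityMap]:
    """Bin spots into (cell density, intensity density) maps per mm^2.

    ``density[j, k]`` is the spot count with centroid depth in bin j and
    area in bin k, divided by the annotated slice area (mm^2) of depth
    bin j; intensity density sums integrated spot intensity instead of
    counts.  Oversized somas are clamped into the last area bin.
    """
    area_mm2 = np.asarray(spotset.region_area_by_depth, dtype=float)
    if area_mm2.shape != (bins.n_depth_bins,):
        raise ValueError("region_area_by_depth length does not match the bin spec")

    counts = np.zeros((bins.n_depth_bins, bins.n_area_bins))
    intensity = np.zeros_like(counts)
    for spot in spotset.spots:
        if not (0 <= spot.centroid_depth <= 1):
            raise ValueError(f"spot depth {spot.centroid_depth} outside [0, 1]")
        if spot.area_px <= 0:
            raise ValueError("spot area must be positive")
        j = int(bins.depth_bin(spot.centroid_depth))
        k = int(bins.area_bin(spot.area_px))
        if area_mm2[j] == 0:
            raise ValueError(
                f"depth bin {j} of region {spotset.source_id!r} has zero annotated "
                "area but contains spots"
            )
        counts[j, k] += 1.0
        intensity[j, k] += spot.integrated_intensity

    nonzero = area_mm2 > 0
    counts[nonzero] /= area_mm2[nonzero, None]
    intensity[nonzero] /= area_mm2[nonzero, None]
    return DensityMap(values=counts, bins=bins), DensityMap(values=intensity, bins=bins)


def nissl_density(
    regions: list[AnnotatedRegion],
    params: DetectionParams = DetectionParams(),
    bins: BinSpec = BinSpec(),
) -> DensityMap:
    """Average per-region cell-density maps from Nissl slices.

    Runs baseline estimation, detection and binning on every region and
    averages the density maps; intensity densities from Nissl are not
    used (Nissl stains all cells, so only counts are meaningful).
    """
    if not regions:
        raise ValueError("nissl_density needs at least one region")
    acc = np.zeros((bins.n_depth_bins, bins.n_area_bins))
    for region in regions:
        spotset = detect_spots(region, params=params, bins=bins)
        density, _ = bin_spots(spotset, bins=bins)
        acc += density.values
    return DensityMap(values=acc / len(regions), bins=bins)
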