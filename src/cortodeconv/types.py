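"""Shared domain containers for the deconvolution pipeline.

The pipeline works on a fixed depth x soma-area grid: 100 bins of
normalized cortical depth (0 = top of layer 1, 1 = bottom of layer 6)
by 40 soma-area bins of 20 px each (1 px = 1 um^2).  Everything that
moves between stages is one of the small dataclasses below.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


# --------------------------------------------------------------------------
# binning


@dataclass(frozen=True)
class BinSpec:
    """Depth x soma-area grid definition.

    Area bin ``k`` covers ``[k*width, (k+1)*width)`` px, half-open,
    0-based; oversized somas are clamped into the last bin.  Depth bin
    ``j`` covers ``[j/n, (j+1)/n)`` of normalized depth, with depth
    exactly 1.0 clamped into the last bin.
    """

    n_depth_bins: int = 100
    n_area_bins: int = 40
    area_bin_width_px: int = 20

    def __post_init__(self) -> None:
        for name in ("n_depth_bins", "n_area_bins", "area_bin_width_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    def depth_bin(self, depth: np.ndarray | float) -> np.ndarray:
        d = np.asarray(depth, dtype=float)
        j = np.floor(d * self.n_depth_bins).astype(int)
        return np.clip(j, 0, self.n_depth_bins - 1)

    def area_bin(self, area_px: np.ndarray | int) -> np.ndarray:
        a = np.asarray(area_px)
        k = a // self.area_bin_width_px
        return np.clip(k.astype(int), 0, self.n_area_bins - 1)

    def area_bin_midpoints_px(self) -> np.ndarray:
        """Midpoint soma area (px = um^2) of each area bin."""
        return (np.arange(self.n_area_bins) + 0.5) * self.area_bin_width_px

    def depth_bin_midpoints_percent(self) -> np.ndarray:
        return (np.arange(self.n_depth_bins) + 0.5) * 100.0 / self.n_depth_bins

    def to_dict(self) -> dict:
        return {
            "n_depth_bins": self.n_depth_bins,
            "n_area_bins": self.n_area_bins,
            "area_bin_width_px": self.area_bin_width_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinSpec":
        return cls(**d)


# --------------------------------------------------------------------------
# imaging-side containers


@dataclass
class AnnotatedRegion:
    """An annotated cortical cross-section on a grayscale raster.

    ``depth_of_pixel`` gives normalized cortical depth in [0, 1] for
    every pixel (only consulted where ``mask`` is true).  The default
    pixel area is 1 um^2.
    """

    image: np.ndarray
    mask: np.ndarray
    depth_of_pixel: np.ndarray
    pixel_area_um2: float = 1.0
    source_id: str = "region"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.depth_of_pixel = np.asarray(self.depth_of_pixel, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("image must be 2-D")
        if self.mask.shape != self.image.shape or self.depth_of_pixel.shape != self.image.shape:
            raise ValueError("image, mask and depth map must share a shape")
        if not self.mask.any():
            raise ValueError(f"region {self.source_id!r}: mask is empty")
        if self.pixel_area_um2 <= 0:
            raise ValueError("pixel_area_um2 must be positive")


@dataclass
class Spot:
    """One detected putative soma."""

    centroid_depth: float
    area_px: int
    integrated_intensity: float
    circularity: float


@dataclass
class SpotSet:
    spots: list[Spot]
    source_id: str
    region_area_by_depth: np.ndarray  # mm^2 per depth bin

    def __len__(self) -> int:
        return len(self.spots)


@dataclass
class DensityMap:
    """Per depth x area bin density (cells or intensity per mm^2)."""

    values: np.ndarray
    bins: BinSpec = field(default_factory=BinSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.bins.n_depth_bins, self.bins.n_area_bins)
        if self.values.shape != expected:
            raise ValueError(f"DensityMap shape {self.values.shape} != {expected}")
        if (self.values < 0).any():
            raise ValueError("DensityMap values must be non-negative")

    def depth_profile(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class DepthProfile:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("DepthProfile must be 1-D")

    @property
    def n_bins(self) -> int:
        return self.values.size


@dataclass
class SizeKernel:
    """A cell type's probability distribution over soma-area bins."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("kernel weights must be non-negative")


# --------------------------------------------------------------------------
# expression-side containers


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} ids must be unique")
    return ids


@dataclass
class TranscriptomeMatrix:
    """Gene x cell-type matrix of median scRNA-seq expression."""

    values: np.ndarray
    gene_ids: list[str]
    type_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.type_ids = _check_unique(self.type_ids, "type")
        if self.values.shape != (len(self.gene_ids), len(self.type_ids)):
            raise ValueError(
                f"transcriptome shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.type_ids)} types"
            )
        if (self.values < 0).any():
            raise ValueError("transcriptome values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_types(self) -> int:
        return len(self.type_ids)


@dataclass
class ExpressionTensor:
    """Per-gene ISH intensity density over depth x area bins (E)."""

    values: np.ndarray
    gene_ids: list[str]
    bins: BinSpec = field(default_factory=BinSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        expected = (len(self.gene_ids), self.bins.n_depth_bins, self.bins.n_area_bins)
        if self.values.shape != expected:
            raise ValueError(f"expression tensor shape {self.values.shape} != {expected}")
        if (self.values < 0).any():
            raise ValueError("expression tensor must be non-negative")


@dataclass
class CompositionSolution:
    """Non-negative cell density per type x depth x area bin (C)."""

    values: np.ndarray
    type_ids: list[str]
    bins: BinSpec = field(default_factory=BinSpec)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.type_ids = _check_unique(self.type_ids, "type")
        expected = (len(self.type_ids), self.bins.n_depth_bins, self.bins.n_area_bins)
        if self.values.shape != expected:
            raise ValueError(f"composition shape {self.values.shape} != {expected}")
        if (self.values < 0).any():
            raise ValueError("composition must be non-negative")


@dataclass
class CanonicalDistribution:
    """Sorted non-decreasing template all transcriptomes are mapped onto."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("canonical distribution must be 1-D")
        if (np.diff(self.values) < 0).any():
            raise ValueError("canonical distribution must be monotone non-decreasing")
        if (self.values < 0).any():
            raise ValueError("canonical distribution must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.size


# --------------------------------------------------------------------------
# class hierarchy and rank assignment


@dataclass
class ClassHierarchy:
    """Ordered partitions of the cell types, finest level first.

    ``levels[l]`` maps class name -> member type ids.  The last level
    must be a single all-encompassing class so every gene can borrow a
    rank key from somewhere.
    """

    levels: list[dict[str, list[str]]]

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("hierarchy needs at least one level")
        if len(self.levels[-1]) != 1:
            raise ValueError("last hierarchy level must be a single class of all cells")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def validate_types(self, type_ids: Sequence[str]) -> None:
        for level_idx, level in enumerate(self.levels):
            seen: dict[str, str] = {}
            for cls, members in level.items():
                for t in members:
                    if t in seen:
                        raise ValueError(
                            f"type {t!r} in classes {seen[t]!r} and {cls!r} at level {level_idx}"
                        )
                    seen[t] = cls
            for t in type_ids:
                if t not in seen:
                    raise ValueError(f"hierarchy level {level_idx} missing type {t!r}")

    def class_of(self, type_id: str, level: int) -> str:
        for cls, members in self.levels[level].items():
            if type_id in members:
                return cls
        raise ValueError(f"hierarchy level {level} missing type {type_id!r}")

    def find_class(self, class_name: str) -> tuple[int, list[str]]:
        """Return (level index, member types) of a named class."""
        for level_idx, level in enumerate(self.levels):
            if class_name in level:
                return level_idx, list(level[class_name])
        raise ValueError(f"unknown class {class_name!r}")

    def to_json(self) -> str:
        return json.dumps({"levels": self.levels}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ClassHierarchy":
        data = json.loads(text)
        return cls(levels=[dict(level) for level in data["levels"]])


#: provenance code for a rank key taken from the type's own non-zero value
OBSERVED = -1


@dataclass
class RankAssignment:
    """Full per-type rank permutation of the genes plus rank provenance.

    ``rank[i, t]`` is gene i's sort position (0 = lowest) within type t.
    ``provenance[i, t]`` is OBSERVED (-1) for a non-zero entry, the
    hierarchy level index whose class average supplied the key for a
    zero entry, or ``n_levels`` when no class had a non-zero average.
    """

    rank: np.ndarray
    provenance: np.ndarray
    gene_ids: list[str]
    type_ids: list[str]

    def __post_init__(self) -> None:
        self.rank = np.asarray(self.rank, dtype=int)
        self.provenance = np.asarray(self.provenance, dtype=int)
        n = len(self.gene_ids)
        expected = np.arange(n)
        for t in range(self.rank.shape[1]):
            if not np.array_equal(np.sort(self.rank[:, t]), expected):
                raise ValueError(f"rank column {t} is not a permutation of 0..{n - 1}")


# --------------------------------------------------------------------------
# layers


@dataclass(frozen=True)
class LayerBounds:
    """Layer bottom boundaries (L1..L6b) in percent of cortical depth."""

    boundaries: tuple[float, ...] = (8.0, 20.0, 35.0, 45.0, 70.0, 95.0, 100.0)

    def __post_init__(self) -> None:
        b = self.boundaries
        if not b:
            raise ValueError("layer boundary list is empty")
        if any(x <= 0 or x > 100 for x in b) or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("layer boundaries must be strictly increasing within (0, 100]")
        if b[-1] != 100:
            raise ValueError("last layer boundary must be 100")

    def intervals(self) -> list[tuple[float, float]]:
        """(top, bottom) percent of every layer, L1 first."""
        tops = (0.0,) + self.boundaries[:-1]
        return list(zip(tops, self.boundaries))
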