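"""File formats, configuration and run manifests.

Text tables are TSV with header rows; gene and type ids are always
carried explicitly, never positional.  Multi-dimensional arrays travel
in one ``.npz`` container per object with a JSON sidecar holding the
bin definitions and id lists.  Images are 16-bit grayscale TIFF.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    BinSpec,
    ClassHierarchy,
    CompositionSolution,
    DensityMap,
    DepthProfile,
    ExpressionTensor,
    SizeKernel,
    SpotSet,
    TranscriptomeMatrix,
)

logger = logging.getLogger(__name__)


def _require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"{what} not found: {p}")
    return p


# --------------------------------------------------------------------------
# TSV tables


def write_transcriptome_tsv(T: TranscriptomeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(T.values, index=T.gene_ids, columns=T.type_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_transcriptome_tsv(path: str | Path) -> TranscriptomeMatrix:
    p = _require(path, "transcriptome table")
    df = pd.read_csv(p, sep="\t", index_col=0)
    return TranscriptomeMatrix(
        values=df.to_numpy(dtype=float),
        gene_ids=[str(g) for g in df.index],
        type_ids=[str(t) for t in df.columns],
    )


def write_profiles_tsv(profiles: dict[str, DepthProfile], path: str | Path) -> None:
    df = pd.DataFrame({tid: prof.values for tid, prof in profiles.items()})
    df.index.name = "depth_bin"
    df.to_csv(path, sep="\t")


def read_profiles_tsv(path: str | Path) -> dict[str, DepthProfile]:
    df = pd.read_csv(_require(path, "profiles table"), sep="\t", index_col=0)
    return {str(c): DepthProfile(values=df[c].to_numpy(dtype=float)) for c in df.columns}


def write_kernels_tsv(kernels: dict[str, SizeKernel], path: str | Path) -> None:
    df = pd.DataFrame({tid: k.weights for tid, k in kernels.items()})
    df.index.name = "area_bin"
    df.to_csv(path, sep="\t")


def read_kernels_tsv(path: str | Path) -> dict[str, SizeKernel]:
    df = pd.read_csv(_require(path, "kernels table"), sep="\t", index_col=0)
    return {str(c): SizeKernel(weights=df[c].to_numpy(dtype=float)) for c in df.columns}


def write_spots_csv(spotset: SpotSet, path: str | Path) -> None:
    rows = [
        {
            "spot_id": i,
            "depth_fraction": s.centroid_depth,
            "area_px": s.area_px,
            "intensity": s.integrated_intensity,
            "circularity": s.circularity,
        }
        for i, s in enumerate(spotset.spots)
    ]
    pd.DataFrame(
        rows, columns=["spot_id", "depth_fraction", "area_px", "intensity", "circularity"]
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# hierarchy JSON


def write_hierarchy_json(H: ClassHierarchy, path: str | Path) -> None:
    Path(path).write_text(H.to_json())


def read_hierarchy_json(path: str | Path) -> ClassHierarchy:
    return ClassHierarchy.from_json(_require(path, "class hierarchy").read_text())


# --------------------------------------------------------------------------
# npz containers with JSON sidecars


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _save_container(path: str | Path, arrays: dict[str, np.ndarray], meta: dict) -> None:
    path = Path(path)
    np.savez(path, **arrays)
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _load_container(path: str | Path, what: str) -> tuple[dict[str, np.ndarray], dict]:
    path = _require(path, what)
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(_require(_sidecar(path), f"{what} sidecar").read_text())
    return arrays, meta


def write_expression(E: ExpressionTensor, path: str | Path) -> None:
    _save_container(
        path,
        {"values": E.values},
        {"kind": "expression", "gene_ids": E.gene_ids, "bins": E.bins.to_dict()},
    )


def read_expression(path: str | Path) -> ExpressionTensor:
    arrays, meta = _load_container(path, "expression tensor")
    return ExpressionTensor(
        values=arrays["values"],
        gene_ids=list(meta["gene_ids"]),
        bins=BinSpec.from_dict(meta["bins"]),
    )


def write_composition(C: CompositionSolution, path: str | Path) -> None:
    _save_container(
        path,
        {"values": C.values},
        {"kind": "composition", "type_ids": C.type_ids, "bins": C.bins.to_dict()},
    )


def read_composition(path: str | Path) -> CompositionSolution:
    arrays, meta = _load_container(path, "composition solution")
    return CompositionSolution(
        values=arrays["values"],
        type_ids=list(meta["type_ids"]),
        bins=BinSpec.from_dict(meta["bins"]),
    )


def write_density_map(D: DensityMap, path: str | Path) -> None:
    _save_container(
        path, {"values": D.values}, {"kind": "density", "bins": D.bins.to_dict()}
    )


def read_density_map(path: str | Path) -> DensityMap:
    arrays, meta = _load_container(path, "density map")
    return DensityMap(values=arrays["values"], bins=BinSpec.from_dict(meta["bins"]))


# --------------------------------------------------------------------------
# images


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(image), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_image(path: str | Path) -> np.ndarray:
    p = _require(path, "image")
    if p.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(p)
    import imageio.v3 as iio

    return iio.imread(p)


# --------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration.

    Every field has a documented default; unknown keys in a config
    file are rejected so typos cannot silently fall back to defaults.
    """

    # binning
    n_depth_bins: int = 100
    n_area_bins: int = 40
    area_bin_width_px: int = 20
    # detection
    threshold_k: float = 3.0
    min_spot_area: int = 4
    min_circularity: float = 0.6
    # normalization: per-bin median first, then depth rescale
    median_first: bool = True
    # refinement
    refine: bool = True
    seed: int = 0
    scale: float | None = None  # None -> 1% of canonical max
    patience: int = 100
    max_iter: int = 10_000
    subsample_bins: int | None = 200
    # anchoring
    anchor_target: float = 120_000.0
    slice_thickness_um: float = 25.0
    layer_bounds: tuple[float, ...] = (8.0, 20.0, 35.0, 45.0, 70.0, 95.0, 100.0)
    # type filter: restrict the transcriptome to these types (None = all)
    type_filter: list[str] | None = None
    neuron_types: list[str] | None = None  # None -> all types
    # paths
    expression: str | None = None
    nissl: str | None = None
    transcriptome: str | None = None
    hierarchy: str | None = None
    out: str = "out"

    def bins(self) -> BinSpec:
        return BinSpec(self.n_depth_bins, self.n_area_bins, self.area_bin_width_px)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(_require(path, "config file").read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "layer_bounds" in data:
            data["layer_bounds"] = tuple(data["layer_bounds"])
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["layer_bounds"] = list(d["layer_bounds"])
        return d


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: PipelineConfig, extra: dict | None = None) -> None:
    import scipy

    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "cortodeconv": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
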