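"""File formats: NIfTI volumes, CSV tables/curves, JSON trees and reports.

Volumes are written as NIfTI with a diagonal affine built from the voxel
spacing (the pipeline assumes axis-aligned, co-registered grids). Tables are
plain CSV with a header row; the coronary tree uses a small JSON schema:

    {"branches": [{"id", "vessel", "parent", "attach_index",
                   "points": [[x, y, z], ...]}],
     "seeds":    [{"branch", "index", "stenosis_percent", "assessable"}]}

with coordinates in world millimetres.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import Branch, CoronaryTree, DynamicSeries, InputError, ScalarMap, Seed, VesselRecord
from .perfusion import DeconvolutionConfig
from .synthetic import AIFParams, GroupDistributions

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_series",
    "load_series",
    "save_tree",
    "load_tree",
    "save_vessel_table",
    "load_vessel_table",
    "save_curve",
    "load_curve",
    "RunConfig",
]

VESSEL_COLUMNS = ["vessel_id", "qca_percent", "ffr", "mbf", "qpr", "cta_significant"]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_nifti(values: np.ndarray, spacing, path) -> None:
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def save_series(series: DynamicSeries, nifti_path, times_path) -> None:
    """4-D volume as NIfTI (x, y, z, t on disk) plus a frame-time CSV."""
    vol = np.moveaxis(series.frames, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(series.spacing)), str(nifti_path))
    pd.DataFrame({"frame": np.arange(series.n_frames), "time_s": series.times}).to_csv(
        times_path, index=False
    )


def load_series(nifti_path, times_path) -> DynamicSeries:
    data, spacing = load_nifti(nifti_path)
    if data.ndim != 4:
        raise InputError("dynamic series NIfTI must be 4-D")
    times = pd.read_csv(times_path)["time_s"].to_numpy(dtype=float)
    return DynamicSeries(np.moveaxis(data, -1, 0), times, spacing)


def save_tree(tree: CoronaryTree, path) -> None:
    obj = {
        "branches": [
            {
                "id": b.id,
                "vessel": b.vessel,
                "parent": b.parent,
                "attach_index": b.attach_index,
                "points": np.asarray(b.points).tolist(),
            }
            for b in tree.branches
        ],
        "seeds": [
            {
                "branch": s.branch,
                "index": s.index,
                "stenosis_percent": s.stenosis_percent,
                "assessable": s.assessable,
            }
            for s in tree.seeds
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def load_tree(path) -> CoronaryTree:
    obj = json.loads(Path(path).read_text())
    branches = [
        Branch(
            id=int(b["id"]),
            vessel=b["vessel"],
            points=np.asarray(b["points"], dtype=float),
            parent=b.get("parent"),
            attach_index=b.get("attach_index"),
        )
        for b in obj["branches"]
    ]
    seeds = [
        Seed(
            branch=int(s["branch"]),
            index=int(s["index"]),
            stenosis_percent=s.get("stenosis_percent"),
            assessable=bool(s.get("assessable", True)),
        )
        for s in obj.get("seeds", [])
    ]
    return CoronaryTree(branches=branches, seeds=seeds)


def save_vessel_table(records: list[VesselRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "vessel_id": r.vessel_id,
                "qca_percent": r.qca_percent,
                "ffr": r.ffr,
                "mbf": r.mbf,
                "qpr": r.qpr,
                "cta_significant": r.cta_significant,
            }
            for r in records
        ],
        columns=VESSEL_COLUMNS,
    ).to_csv(path, index=False)


def load_vessel_table(path) -> list[VesselRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(VESSEL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"vessel table missing columns: {sorted(missing)}")
    return [
        VesselRecord(
            vessel_id=str(row.vessel_id),
            qca_percent=float(row.qca_percent),
            ffr=float(row.ffr),
            mbf=float(row.mbf),
            qpr=float(row.qpr),
            cta_significant=bool(row.cta_significant),
        )
        for row in df.itertuples()
    ]


def save_curve(times: np.ndarray, values: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": times, "value_hu": values}).to_csv(path, index=False)


def load_curve(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(dtype=float), df["value_hu"].to_numpy(dtype=float)


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters in one structured, serializable object.

    Threshold defaults are the clinical decision rules: FFR <= 0.80 defines
    hemodynamic significance, >= 50% luminal reduction defines CTA
    significance, and the 30-69% QCA band triggers FFR interrogation.
    """

    seed: int = 0
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    frame_interval: float = 0.73
    n_frames: int = 30
    noise_sd: float = 0.0
    mtt: float = 8.0
    aif: AIFParams = dataclasses.field(default_factory=AIFParams)
    deconvolution: DeconvolutionConfig = dataclasses.field(
        default_factory=DeconvolutionConfig
    )
    group_dist: GroupDistributions = dataclasses.field(
        default_factory=GroupDistributions
    )
    n_sig: int = 20
    n_nonsig: int = 19
    ffr_cutoff: float = 0.80
    cta_cutoff: float = 50.0
    qca_band: tuple[float, float] = (30.0, 69.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.ffr_cutoff <= 1.0):
            raise InputError("ffr_cutoff must be in (0, 1]")
        if not (0.0 <= self.cta_cutoff <= 100.0):
            raise InputError("cta_cutoff must be a percentage")
        if not (0.0 <= self.qca_band[0] < self.qca_band[1] <= 100.0):
            raise InputError("qca_band must be an increasing percentage pair")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing"] = list(self.spacing)
        d["qca_band"] = list(self.qca_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "aif" in d and isinstance(d["aif"], dict):
            d["aif"] = AIFParams(**d["aif"])
        if "deconvolution" in d and isinstance(d["deconvolution"], dict):
            d["deconvolution"] = DeconvolutionConfig(**d["deconvolution"])
        if "group_dist" in d and isinstance(d["group_dist"], dict):
            g = d["group_dist"]
            for key in ("mbf_sig", "mbf_nonsig", "qpr_sig", "qpr_nonsig"):
                if key in g:
                    g[key] = tuple(g[key])
            d["group_dist"] = GroupDistributions(**g)
        for key in ("grid_shape", "spacing", "qca_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
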