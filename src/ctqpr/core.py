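"""Shared domain types for the CT-QPR pipeline.

The pipeline estimates voxel-wise myocardial blood flow (MBF, mL/g/min) from a
dynamic contrast-enhanced CT series, partitions the left-ventricular (LV)
myocardium into coronary perfusion territories with a Voronoi (nearest-branch)
rule, and summarises perfusion distal to each stenosis as an absolute MBF and
as a quantitative perfusion ratio (QPR = MBF / reference MBF).

Containers here are deliberately thin: numpy arrays plus the metadata needed to
keep world coordinates (mm), acquisition times (s) and units unambiguous.
Conventions used throughout the package:

* voxel indices are 0-based; a voxel's world position is ``index * spacing``
  (voxel-center convention, axis-aligned grid, no affine rotation);
* dynamic series are stored time-first, ``frames[t, i, j, k]``;
* branch polyline coordinates are world millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("ctqpr")

# Physiological / protocol constants (package-wide defaults)
TISSUE_DENSITY_G_PER_ML = 1.05     # myocardial tissue density rho
FFR_CUTOFF = 0.80                  # FFR <= cutoff -> hemodynamically significant
CTA_STENOSIS_CUTOFF_PERCENT = 50.0  # >= 50% luminal reduction -> CTA-significant
QCA_FFR_BAND = (30.0, 69.0)        # QCA band in which FFR is interrogated
DOSE_COEFF_MSV_PER_MGY_CM = 0.014  # DLP -> effective dose conversion


class InputError(ValueError):
    """Raised when an operation's preconditions on its inputs are violated."""


@dataclass
class ScalarMap:
    """A 3-D per-voxel scalar field defined on a voxel mask.

    Used for MBF maps (mL/g/min), QPR maps (ratio) and territory label maps
    (integer branch ids). ``values`` outside ``mask`` are undefined (kept as 0
    by convention but never read).
    """

    values: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    units: str = "mL/g/min"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise InputError("values and mask shapes differ")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass
class DynamicSeries:
    """Time-stamped 4-D attenuation data: ``frames[t]`` is a 3-D HU volume."""

    frames: np.ndarray
    times: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 4:
            raise InputError("frames must be 4-D (time, x, y, z)")
        if self.times.ndim != 1 or len(self.times) != self.frames.shape[0]:
            raise InputError("times must match the number of frames")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("acquisition times must be strictly increasing")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]


@dataclass
class Branch:
    """One coronary branch: an ordered centerline polyline in world mm."""

    id: int
    vessel: str                      # LAD | LCX | RCA
    points: np.ndarray               # (n, 3) mm
    parent: Optional[int] = None
    attach_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InputError(f"branch {self.id}: points must be (n, 3)")
        if len(self.points) < 2:
            raise InputError(f"branch {self.id}: polyline needs >= 2 points")

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length (mm) at each polyline point, 0 at the origin."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Seed:
    """A stenosis seed point: a location on a branch polyline."""

    branch: int
    index: int
    stenosis_percent: Optional[float] = None
    assessable: bool = True


@dataclass
class CoronaryTree:
    """A labeled coronary-tree skeleton with stenosis seed points."""

    branches: list[Branch]
    seeds: list[Seed] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise InputError("duplicate branch ids")
        by_id = {b.id: b for b in self.branches}
        for b in self.branches:
            if b.parent is not None:
                if b.parent not in by_id:
                    raise InputError(f"branch {b.id}: unknown parent {b.parent}")
                if b.attach_index is None or not (
                    0 <= b.attach_index < len(by_id[b.parent].points)
                ):
                    raise InputError(f"branch {b.id}: invalid attach_index")
        for s in self.seeds:
            if s.branch not in by_id:
                raise InputError(f"seed references unknown branch {s.branch}")
            if not (0 <= s.index < len(by_id[s.branch].points)):
                raise InputError(f"seed index {s.index} off branch {s.branch}")

    def branch_by_id(self, branch_id: int) -> Branch:
        for b in self.branches:
            if b.id == branch_id:
                return b
        raise InputError(f"no branch with id {branch_id}")

    def children_of(self, branch_id: int) -> list[Branch]:
        return [b for b in self.branches if b.parent == branch_id]

    def root_of(self, branch_id: int) -> Branch:
        """Walk parent links to the vessel root of a branch."""
        b = self.branch_by_id(branch_id)
        while b.parent is not None:
            b = self.branch_by_id(b.parent)
        return b

    @property
    def branch_ids(self) -> list[int]:
        return sorted(b.id for b in self.branches)


@dataclass
class VesselRecord:
    """One FFR-interrogated vessel with its CT indices."""

    vessel_id: str
    qca_percent: float
    ffr: float
    mbf: float
    qpr: float
    cta_significant: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.ffr <= 1.0):
            raise InputError(f"ffr {self.ffr} outside (0, 1]")
        if self.mbf < 0 or self.qpr < 0:
            raise InputError("mbf and qpr must be non-negative")


@dataclass
class DiagnosticReport:
    """Diagnostic performance of one index against the FFR reference standard.

    Proportions and their truncated 95% Wald confidence intervals are in
    percent; the AUC and its CI are on [0, 1].
    """

    index_name: str
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: Optional[float]
    ppv_ci: Optional[tuple[float, float]]
    npv: Optional[float]
    npv_ci: Optional[tuple[float, float]]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        def pair(x):
            return None if x is None else [float(x[0]), float(x[1])]

        return {
            "index": self.index_name,
            "auc": float(self.auc),
            "auc_ci": pair(self.auc_ci),
            "cutoff": float(self.cutoff),
            "sensitivity_percent": float(self.sensitivity),
            "sensitivity_ci": pair(self.sensitivity_ci),
            "specificity_percent": float(self.specificity),
            "specificity_ci": pair(self.specificity_ci),
            "ppv_percent": None if self.ppv is None else float(self.ppv),
            "ppv_ci": pair(self.ppv_ci),
            "npv_percent": None if self.npv is None else float(self.npv),
            "npv_ci": pair(self.npv_ci),
            "n_pos": int(self.n_pos),
            "n_neg": int(self.n_neg),
        }


def voxel_centers_mm(
    shape: Sequence[int], spacing: Sequence[float], mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """World-mm coordinates of voxel centers, optionally restricted to a mask.

    Returns an (n, 3) array in the same order as ``np.argwhere(mask)``.
    """
    if mask is None:
        idx = np.indices(tuple(shape)).reshape(3, -1).T
    else:
        idx = np.argwhere(np.asarray(mask, dtype=bool))
    return idx * np.asarray(spacing, dtype=float)
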