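"""Voronoi coronary perfusion territories and stenosis-related (distal) regions.

Every voxel of the LV myocardium is allocated to the spatially nearest coronary
branch centerline — a Voronoi partition of the myocardium generated by the
branch polylines. The myocardium "related" to a stenosis is the subset of that
partition supplied by the coronary subtree distal to the stenosis seed point:
the seed's own branch from the seed onward plus every side branch taking off at
or beyond it.

Distances are Euclidean in world millimetres from voxel centers to branch
polylines; polylines are resampled densely (step <= half the smallest voxel
spacing) so the point-sampled distance approximates the continuous curve
distance. Exact distance ties are broken toward the lowest branch id so the
partition is deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    Branch,
    CoronaryTree,
    CTA_STENOSIS_CUTOFF_PERCENT,
    InputError,
    ScalarMap,
    Seed,
    voxel_centers_mm,
)

__all__ = [
    "resample_polyline",
    "voronoi_territories",
    "distal_subtree",
    "stenosis_territory",
    "select_culprit",
    "classify_cta",
    "branch_arc_length_from_root",
]


def resample_polyline(
    points: np.ndarray, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at arc-length intervals <= ``step`` mm.

    Returns ``(samples, params)`` where ``params[i]`` is the fractional
    original-vertex index of sample i (0 at the first vertex, n-1 at the last),
    used to test whether a sample lies distal to a seed at a given vertex.
    Original vertices are always included.
    """
    points = np.asarray(points, dtype=float)
    samples = [points[0]]
    params = [0.0]
    for i in range(len(points) - 1):
        seg = points[i + 1] - points[i]
        length = float(np.linalg.norm(seg))
        n_sub = max(1, int(np.ceil(length / step))) if length > 0 else 1
        for k in range(1, n_sub + 1):
            f = k / n_sub
            samples.append(points[i] + f * seg)
            params.append(i + f)
    return np.asarray(samples), np.asarray(params)


def _branch_samples(branch: Branch, spacing) -> tuple[np.ndarray, np.ndarray]:
    step = 0.5 * float(min(spacing))
    return resample_polyline(branch.points, step)


def voronoi_territories(
    tree: CoronaryTree, lv_mask: np.ndarray, spacing
) -> ScalarMap:
    """Label every LV-mask voxel with the id of its nearest coronary branch.

    One KD-tree query per branch gives each voxel its distance to that branch's
    resampled polyline; the argmin over branches (iterated in ascending-id
    order, so exact ties resolve to the lowest id) is the territory label.
    """
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not tree.branches:
        raise InputError("empty coronary tree")
    if not lv_mask.any():
        raise InputError("empty LV mask")

    centers = voxel_centers_mm(lv_mask.shape, spacing, lv_mask)
    branch_ids = tree.branch_ids
    dists = np.empty((len(branch_ids), len(centers)))
    for row, bid in enumerate(branch_ids):
        samples, _ = _branch_samples(tree.branch_by_id(bid), spacing)
        dists[row], _ = cKDTree(samples).query(centers)
    nearest = np.argmin(dists, axis=0)  # first (lowest id) wins ties

    labels = np.zeros(lv_mask.shape, dtype=int)
    labels[lv_mask] = np.asarray(branch_ids)[nearest]
    return ScalarMap(labels, lv_mask, spacing, units="label")


def distal_subtree(tree: CoronaryTree, seed: Seed) -> dict[int, tuple[int, int]]:
    """Branch segments supplied distal to a stenosis seed.

    Returns ``{branch_id: (start_index, end_index)}`` (inclusive vertex range):
    the seed's branch from the seed vertex to its tip, plus — recursively — all
    descendant branches attached at or beyond the included range.
    """
    branch = tree.branch_by_id(seed.branch)  # raises for dangling seed
    if not (0 <= seed.index < len(branch.points)):
        raise InputError(f"seed index {seed.index} off branch {seed.branch}")

    ranges: dict[int, tuple[int, int]] = {}

    def include(b: Branch, start: int) -> None:
        ranges[b.id] = (start, len(b.points) - 1)
        for child in tree.children_of(b.id):
            if child.attach_index is not None and child.attach_index >= start:
                include(child, 0)

    include(branch, seed.index)
    return ranges


def stenosis_territory(
    tmap: ScalarMap, tree: CoronaryTree, seed: Seed
) -> np.ndarray:
    """Binary mask of the myocardium perfused distal to a stenosis seed.

    Within each labeled territory in the distal subtree, a voxel belongs to the
    stenosis-related region iff its nearest point on its own branch's polyline
    lies at or beyond the subtree's start vertex for that branch. Moving a seed
    distally can therefore only shrink the mask (nesting).
    """
    ranges = distal_subtree(tree, seed)
    labels = tmap.values
    if not np.isin(seed.branch, labels[tmap.mask]).any():
        raise InputError(f"seed branch {seed.branch} absent from territory map")

    out = np.zeros(tmap.mask.shape, dtype=bool)
    for bid, (start, _end) in ranges.items():
        vox = tmap.mask & (labels == bid)
        if not vox.any():
            continue
        if start == 0:
            out |= vox
            continue
        samples, params = _branch_samples(tree.branch_by_id(bid), tmap.spacing)
        centers = voxel_centers_mm(tmap.mask.shape, tmap.spacing, vox)
        _, idx = cKDTree(samples).query(centers)
        out[vox] = params[idx] >= start
    return out


def branch_arc_length_from_root(tree: CoronaryTree, branch_id: int) -> float:
    """Arc length (mm) along the tree from the vessel root to a branch origin."""
    b = tree.branch_by_id(branch_id)
    total = 0.0
    while b.parent is not None:
        parent = tree.branch_by_id(b.parent)
        total += float(parent.arc_lengths()[b.attach_index])
        b = parent
    return total


def select_culprit(tree: CoronaryTree, seeds: list[Seed]) -> Seed:
    """The culprit stenosis among several on one vessel: the most proximal seed.

    Proximality is arc length from the vessel root to the seed; ties resolve to
    the lowest branch id, then the lowest vertex index.
    """
    if not seeds:
        raise InputError("no seeds to select from")

    def key(s: Seed):
        arc = branch_arc_length_from_root(tree, s.branch) + float(
            tree.branch_by_id(s.branch).arc_lengths()[s.index]
        )
        return (arc, s.branch, s.index)

    return min(seeds, key=key)


def classify_cta(
    stenosis_percent: float | None, assessable: bool = True
) -> bool:
    """CTA significance: >= 50% luminal reduction, or an un-assessable
    (typically heavily calcified) segment, counts as significant."""
    if not assessable:
        return True
    if stenosis_percent is None or not (0.0 <= stenosis_percent <= 100.0):
        raise InputError("stenosis_percent must be in [0, 100] when assessable")
    return stenosis_percent >= CTA_STENOSIS_CUTOFF_PERCENT
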