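"""Independent reference implementations used only as test oracles.

These deliberately share no code with the package: the matcher oracle
superposes with scipy's Rotation.align_vectors and enumerates assignments
itself; the clustering oracle is scipy.cluster.hierarchy; the RMSD oracle
is a direct per-pair loop over explicitly enumerated atom permutations.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.spatial.transform import Rotation


def brute_force_match(model, feature_points, heavy_coords) -> bool:
    """Exhaustive assignment + superposition matcher oracle.

    Enumerates every injective kind-compatible assignment of ligand
    feature points to the four model features, superposes the assigned
    points with scipy, and accepts when all deviations are within
    tolerance and no heavy atom falls strictly inside an excluded volume.
    """
    kinds = [f.kind for f in model.features]
    centers = np.array([f.center for f in model.features])
    tols = np.array([f.tolerance for f in model.features])
    pts_by_kind = {}
    for i, p in enumerate(feature_points):
        pts_by_kind.setdefault(p.kind, []).append(i)
    pools = [pts_by_kind.get(k, []) for k in kinds]
    positions = np.array([p.position for p in feature_points]) \
        if feature_points else np.zeros((0, 3))

    for combo in itertools.product(*pools):
        if len(set(combo)) != 4:
            continue
        P = positions[list(combo)]
        cp, cq = P.mean(axis=0), centers.mean(axis=0)
        rot, _ = Rotation.align_vectors(centers - cq, P - cp)
        moved = rot.apply(P - cp) + cq
        if np.any(np.linalg.norm(moved - centers, axis=1) > tols):
            continue
        moved_heavy = rot.apply(np.asarray(heavy_coords) - cp) + cq
        clash = False
        for v in model.volumes:
            d = np.linalg.norm(moved_heavy - np.asarray(v.center), axis=1)
            if np.any(d < v.radius - 1e-9):
                clash = True
                break
        if not clash:
            return True
    return False


def scipy_complete_linkage(matrix: np.ndarray, threshold: float) -> set[frozenset]:
    """Reference complete-linkage partition via scipy's hierarchy module."""
    n = matrix.shape[0]
    Z = linkage(squareform(matrix, checks=False), method="complete")
    # cut so that no merge at distance >= threshold is applied
    labels = fcluster(Z, t=threshold * (1 - 1e-12), criterion="distance")
    out: dict[int, set[int]] = {}
    for i in range(n):
        out.setdefault(labels[i], set()).add(i)
    return {frozenset(c) for c in out.values()}


def partition_to_sets(partition) -> set[frozenset]:
    return {frozenset(c) for c in partition}


def naive_symmetric_rmsd(coords_a, coords_b, permutations) -> float:
    """Minimum in-place RMSD over an explicit permutation list."""
    best = np.inf
    a = np.asarray(coords_a)
    b = np.asarray(coords_b)
    for perm in permutations:
        d = a - b[list(perm)]
        best = min(best, float(np.sqrt(np.mean(np.sum(d * d, axis=1)))))
    return best


def benzene_ring_permutations() -> list[tuple[int, ...]]:
    """All 12 dihedral relabelings of a 6-ring (rotations + reflections)."""
    perms = []
    base = list(range(6))
    for s in range(6):
        rot = tuple((i + s) % 6 for i in base)
        perms.append(rot)
        perms.append(tuple(reversed(rot)))
    return perms
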