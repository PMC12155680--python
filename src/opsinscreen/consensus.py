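"""Consensus-docking pose analysis.

Each docking engine contributes one best-scored pose per ligand, all in
the common receptor frame. Poses are compared by in-place heavy-atom
RMSD (no re-superposition: superposing would mask translational
disagreement between engines), optionally minimized over bond-graph
automorphisms so that chemically equivalent atom labelings — e.g. a
flipped phenyl ring — do not inflate the deviation.

The pairwise RMSD matrix is clustered by agglomerative complete linkage
at a 2.0 Angstrom threshold; every reported cluster therefore has all
intra-cluster pairs below the threshold. The *consensus level* of a
ligand is the size of the most populated cluster, and the consensus pose
is that cluster's medoid. The hierarchical screen keeps ligands reaching
level >= 4 of 6 fast engines, then requires full 11-of-11 consensus once
the five slower engines are added.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx
import numpy as np

from .geometry import in_place_rmsd

AUTOMORPHISM_CAP = 10_000

STAGE1_METHODS = ("vina", "fred", "plants", "rdock", "gold-chemscore", "gold-chemplp")
STAGE2_METHODS = ("gold-goldscore", "gold-asp", "dock", "autodock", "glamdock")


@dataclass
class Pose:
    """One docking pose: ligand heavy atoms in the receptor frame.

    All poses of a ligand share atom ordering, element sequence and bond
    graph; only coordinates differ.
    """

    ligand_id: str
    method_id: str
    coords: np.ndarray
    symbols: tuple[str, ...]
    bonds: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.symbols = tuple(self.symbols)
        self.bonds = tuple((int(i), int(j), float(o)) for i, j, o in self.bonds)
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("pose coordinates must be finite")


@dataclass
class PoseSet:
    """All poses of one ligand, one per docking method."""

    ligand_id: str
    poses: list[Pose]

    def __post_init__(self):
        methods = [p.method_id for p in self.poses]
        if len(set(methods)) != len(methods):
            raise ValueError("method ids must be unique within a pose set")
        for p in self.poses:
            if p.ligand_id != self.ligand_id:
                raise ValueError("mixed ligand ids in pose set")

    def sorted_by_method(self) -> "PoseSet":
        return PoseSet(self.ligand_id, sorted(self.poses, key=lambda p: p.method_id))


@lru_cache(maxsize=256)
def bond_graph_automorphisms(symbols: tuple[str, ...],
                             bonds: tuple[tuple[int, int, float], ...],
                             cap: int = AUTOMORPHISM_CAP) -> tuple[tuple[int, ...], ...]:
    """Enumerate automorphisms of the element/bond-order colored graph.

    Returns permutations ``p`` with ``p[i]`` the image of atom ``i``. The
    identity is always included. If more than ``cap`` automorphisms exist
    the enumeration falls back to the identity only, with a warning.
    """
    n = len(symbols)
    G = nx.Graph()
    for i, s in enumerate(symbols):
        G.add_node(i, element=s)
    for i, j, order in bonds:
        G.add_edge(i, j, order=order)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        G, G,
        node_match=lambda a, b: a["element"] == b["element"],
        edge_match=lambda a, b: a["order"] == b["order"])
    perms: list[tuple[int, ...]] = []
    for mapping in matcher.isomorphisms_iter():
        perms.append(tuple(mapping[i] for i in range(n)))
        if len(perms) > cap:
            warnings.warn(
                f"more than {cap} bond-graph automorphisms; "
                "falling back to identity mapping", RuntimeWarning)
            return (tuple(range(n)),)
    if not perms:  # disconnected trivial graphs still have the identity
        perms = [tuple(range(n))]
    return tuple(sorted(perms))


def pose_rmsd(a: Pose, b: Pose, symmetry: bool = True) -> float:
    """In-place heavy-atom RMSD between two poses of the same ligand.

    With ``symmetry=True`` (default) the RMSD is minimized over
    element- and bond-order-preserving graph automorphisms, so it never
    exceeds the uncorrected value. No superposition is performed.
    """
    if a.symbols != b.symbols or a.coords.shape != b.coords.shape:
        raise ValueError("poses not comparable")
    if a.bonds != b.bonds:
        raise ValueError("poses not comparable")
    if not symmetry:
        return in_place_rmsd(a.coords, b.coords)
    perms = bond_graph_automorphisms(a.symbols, a.bonds)
    P = np.array(perms)
    # b reindexed by each automorphism, vectorized over the group
    diff = a.coords[None, :, :] - b.coords[P, :]
    msd = np.mean(np.sum(diff * diff, axis=2), axis=1)
    return float(np.sqrt(msd.min()))


def rmsd_matrix(ps: PoseSet, symmetry: bool = True) -> np.ndarray:
    """Symmetric matrix of pairwise pose RMSDs (zero diagonal)."""
    n = len(ps.poses)
    if n < 2:
        raise ValueError("need at least 2 poses")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pose_rmsd(ps.poses[i], ps.poses[j], symmetry=symmetry)
    return m


def complete_linkage_cluster(m: np.ndarray, threshold: float = 2.0) -> list[list[int]]:
    """Agglomerative complete-linkage clustering cut strictly below ``threshold``.

    Merging proceeds while the smallest complete-linkage (maximum pairwise)
    distance between clusters is < threshold; consequently every reported
    cluster has all intra-cluster pairwise distances below the threshold.
    Ties on the minimal linkage distance are broken by the
    lexicographically smallest (min member of first, min member of second)
    index pair, which makes the partition deterministic.

    Returns the partition as a list of sorted index lists, ordered by
    smallest member.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(m, m.T, atol=1e-9):
        raise ValueError("RMSD matrix must be symmetric")
    if np.any(m < 0) or not np.all(np.isfinite(m)):
        raise ValueError("RMSD matrix entries must be finite and non-negative")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")

    n = m.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None  # (dist, min_i, min_j, a, b)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(m[i, j] for i in clusters[a] for j in clusters[b])
                key = (d, min(clusters[a][0], clusters[b][0]),
                       max(clusters[a][0], clusters[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        if d >= threshold:
            break
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted((sorted(c) for c in clusters), key=lambda c: c[0])


@dataclass
class ConsensusResult:
    """Clustering outcome for one ligand's pose set."""

    clusters: list[list[int]]
    level: int
    medoid_index: int
    threshold: float
    tied_largest: bool = False
    matrix: np.ndarray | None = field(default=None, repr=False)


def consensus_of(ps: PoseSet, threshold: float = 2.0, symmetry: bool = True,
                 matrix: np.ndarray | None = None) -> ConsensusResult:
    """Cluster a pose set and report consensus level and consensus pose.

    The consensus pose is the medoid (minimum summed RMSD to co-members)
    of the most populated cluster; when several clusters tie for largest,
    the one containing the smallest pose index is used and the result is
    flagged.
    """
    if matrix is None:
        matrix = rmsd_matrix(ps, symmetry=symmetry)
    clusters = complete_linkage_cluster(matrix, threshold)
    max_size = max(len(c) for c in clusters)
    largest = [c for c in clusters if len(c) == max_size]
    tied = len(largest) > 1
    chosen = min(largest, key=lambda c: c[0])
    sums = [sum(matrix[i, j] for j in chosen if j != i) for i in chosen]
    medoid = chosen[int(np.argmin(sums))]  # argmin takes the lowest index on ties
    return ConsensusResult(clusters, max_size, medoid, threshold, tied, matrix)


@dataclass
class ScreenDecision:
    """Decision record of the hierarchical two-stage consensus screen."""

    ligand_id: str
    stage1_level: int
    stage2_level: int | None
    passed: bool
    stage1_medoid_method: str
    stage2_medoid_method: str | None = None
    tied_largest: bool = False


def hierarchical_screen(stage1: PoseSet, stage2_extra: list[Pose],
                        threshold: float = 2.0, min_level: int = 4,
                        required_level: int | None = None,
                        symmetry: bool = True) -> ScreenDecision:
    """Two-stage consensus screen: >= min_level of 6, then full consensus of 11.

    Stage 1 clusters the six fast-engine poses; ligands below ``min_level``
    fail without evaluating stage 2. Survivors get the five extra poses
    appended and the full 11x11 matrix is recomputed (stage-1 entries are
    reused as a cache); passing requires the maximum consensus level
    (all poses in one cluster) unless ``required_level`` overrides it.
    """
    for p in stage2_extra:
        if p.ligand_id != stage1.ligand_id:
            raise ValueError("mixed ligand ids between stages")
    s1 = stage1.sorted_by_method()
    m1 = rmsd_matrix(s1, symmetry=symmetry)
    r1 = consensus_of(s1, threshold, symmetry=symmetry, matrix=m1)
    med1 = s1.poses[r1.medoid_index].method_id
    if r1.level < min_level:
        return ScreenDecision(stage1.ligand_id, r1.level, None, False, med1,
                              tied_largest=r1.tied_largest)

    full = PoseSet(stage1.ligand_id, list(s1.poses) + sorted(
        stage2_extra, key=lambda p: p.method_id))
    n1 = len(s1.poses)
    n = len(full.poses)
    m2 = np.zeros((n, n))
    m2[:n1, :n1] = m1  # cache: stage-1 pairs already computed
    for i in range(n):
        for j in range(max(i + 1, n1), n):
            m2[i, j] = m2[j, i] = pose_rmsd(full.poses[i], full.poses[j],
                                            symmetry=symmetry)
    r2 = consensus_of(full, threshold, symmetry=symmetry, matrix=m2)
    need = n if required_level is None else required_level
    med2 = full.poses[r2.medoid_index].method_id
    return ScreenDecision(stage1.ligand_id, r1.level, r2.level,
                          r2.level >= need, med1, med2,
                          tied_largest=r1.tied_largest or r2.tied_largest)
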