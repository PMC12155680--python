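"""MD-trajectory prioritization filter for ligand-opsin complexes.

Stage-2 consensus survivors are simulated in the receptor and kept only
when the predicted binding mode is stable: (i) the mean heavy-atom RMSD
of the ligand versus its initial (post-minimization) disposition stays
below 2.0 Angstrom, and (ii) the water-mediated hydrogen bond between a
ligand acceptor atom and the Y191 hydroxyl — bridged by a structural
water — persists for a sufficient fraction of frames. Ligands receive a
score of 2, 1 or 0 for satisfying both, one or neither criterion; only
score-2 ligands pass.

The ligand RMSD is computed in place, with no re-alignment: the
simulations these filters target restrain the protein alpha-carbons, so
the receptor frame is fixed. An optional alpha-carbon superposition mode
exists for unrestrained trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import in_place_rmsd, kabsch


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond definition plus persistence threshold.

    distance_cutoff: heavy-atom donor-acceptor distance, Angstrom.
    angle_cutoff_deg: donor-H-acceptor angle, applied only when hydrogen
        positions are labeled; distance-only otherwise.
    occupancy_threshold: fraction of analyzed frames the bridge must be
        present for the H-bond criterion to count as maintained.
    """

    distance_cutoff: float = 3.5
    angle_cutoff_deg: float = 135.0
    occupancy_threshold: float = 0.5

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")
        if not (0 < self.occupancy_threshold <= 1):
            raise ValueError("occupancy threshold must be in (0, 1]")


@dataclass
class TrajectoryRecord:
    """Multi-frame coordinates plus atom-role labels.

    frames: (n_frames, n_atoms, 3) Angstrom; frame 0 is the initial
        (post-minimization) disposition.
    ligand_heavy: indices of ligand heavy atoms.
    ligand_acceptor: indices of ligand H-bond acceptor atoms (subset of
        ligand heavy atoms by convention).
    water_oxygen: index (or candidate indices) of the bridging water O.
    tyr_oxygen: index of the Y191 hydroxyl oxygen.
    water_hydrogens: optional water H indices enabling the angle test.
    alpha_carbons: optional protein CA indices for the superposition mode.
    frame_interval_ns: time between frames; enables the equilibration cut.
    """

    frames: np.ndarray
    ligand_heavy: Sequence[int]
    ligand_acceptor: Sequence[int]
    water_oxygen: int | Sequence[int]
    tyr_oxygen: int
    water_hydrogens: Sequence[int] = field(default_factory=tuple)
    alpha_carbons: Sequence[int] = field(default_factory=tuple)
    frame_interval_ns: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 2:
            raise ValueError("trajectory needs at least 2 frames")
        self.ligand_heavy = tuple(int(i) for i in self.ligand_heavy)
        self.ligand_acceptor = tuple(int(i) for i in self.ligand_acceptor)
        for role, idx in (("ligand heavy atoms", self.ligand_heavy),
                          ("ligand acceptor", self.ligand_acceptor)):
            if len(idx) == 0:
                raise ValueError(f"missing labels for role: {role}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def water_candidates(self) -> tuple[int, ...]:
        if isinstance(self.water_oxygen, (int, np.integer)):
            return (int(self.water_oxygen),)
        w = tuple(int(i) for i in self.water_oxygen)
        if not w:
            raise ValueError("missing labels for role: water oxygen")
        return w

    def analysis_frames(self, equilibration_ns: float | None = 5.0) -> np.ndarray:
        """Frame indices analyzed: all after frame 0, minus the
        heating/equilibration span when frame times are known."""
        start = 1
        if equilibration_ns is not None and self.frame_interval_ns:
            start = max(1, int(np.ceil(equilibration_ns / self.frame_interval_ns)))
        return np.arange(start, self.n_frames)


def ligand_rmsd_series(t: TrajectoryRecord, superpose_ca: bool = False,
                       equilibration_ns: float | None = 5.0) -> np.ndarray:
    """Per-frame in-place ligand heavy-atom RMSD versus frame 0.

    With ``superpose_ca=True`` each frame is first rigidly superposed on
    frame 0 using the labeled alpha-carbons (for unrestrained inputs).
    """
    lig = list(t.ligand_heavy)
    ref = t.frames[0][lig]
    out = []
    for f in t.analysis_frames(equilibration_ns):
        frame = t.frames[f]
        if superpose_ca:
            if not t.alpha_carbons:
                raise ValueError("missing labels for role: alpha carbons")
            ca = list(t.alpha_carbons)
            R, tr, _ = kabsch(frame[ca], t.frames[0][ca])
            frame = frame @ R.T + tr
        out.append(in_place_rmsd(frame[lig], ref))
    return np.asarray(out)


def _bridge_present(frame: np.ndarray, acceptors: Sequence[int], w: int,
                    tyr: int, c: HBondCriterion,
                    water_h: Sequence[int]) -> bool:
    wo = frame[w]
    d_tyr = np.linalg.norm(wo - frame[tyr])
    if d_tyr > c.distance_cutoff:
        return False
    d_acc = min(np.linalg.norm(wo - frame[a]) for a in acceptors)
    if d_acc > c.distance_cutoff:
        return False
    if water_h:
        # water donates to the ligand acceptor: require at least one
        # O-H...A arrangement with angle >= cutoff for the closest acceptor
        acc = min(acceptors, key=lambda a: np.linalg.norm(wo - frame[a]))
        best = 0.0
        for h in water_h:
            v1 = wo - frame[h]
            v2 = frame[acc] - frame[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            best = max(best, ang)
        if best < c.angle_cutoff_deg:
            return False
    return True


def water_bridge_occupancy(t: TrajectoryRecord, c: HBondCriterion | None = None,
                           reselect_water: bool = False,
                           equilibration_ns: float | None = 5.0) -> float:
    """Fraction of frames with the ligand-water-Y191 bridge intact.

    A frame counts when both legs (ligand acceptor <-> water O and
    water O <-> Y191 O) are simultaneously within the distance cutoff
    (and the angle test passes when water hydrogens are labeled). With
    ``reselect_water=True`` the water minimizing the larger leg distance
    is chosen per frame, accommodating water exchange.
    """
    if c is None:
        c = HBondCriterion()
    waters = t.water_candidates()
    if t.tyr_oxygen is None:
        raise ValueError("missing labels for role: Y191 hydroxyl oxygen")
    frames = t.analysis_frames(equilibration_ns)
    hits = 0
    for f in frames:
        frame = t.frames[f]
        if reselect_water and len(waters) > 1:
            def worst_leg(w):
                d1 = min(np.linalg.norm(frame[w] - frame[a])
                         for a in t.ligand_acceptor)
                d2 = np.linalg.norm(frame[w] - frame[t.tyr_oxygen])
                return max(d1, d2)
            cand = [min(waters, key=worst_leg)]
        else:
            cand = list(waters)
        if any(_bridge_present(frame, t.ligand_acceptor, w, t.tyr_oxygen, c,
                               t.water_hydrogens) for w in cand):
            hits += 1
    return hits / len(frames)


@dataclass
class FilterScore:
    """Mean RMSD, bridge occupancy and the 0/1/2 prioritization score."""

    mean_rmsd: float
    occupancy: float
    score: int
    passed: bool
    rmsd_cutoff: float = 2.0
    occupancy_threshold: float = 0.5


def assign_score(mean_rmsd: float, occupancy: float,
                 c: HBondCriterion | None = None,
                 rmsd_cutoff: float = 2.0) -> FilterScore:
    """Score 2, 1 or 0 for meeting both, one or neither criterion.

    The RMSD criterion is mean RMSD strictly below the cutoff; the H-bond
    criterion is occupancy at or above the persistence threshold. Only
    score-2 ligands pass the filter.
    """
    if c is None:
        c = HBondCriterion()
    if not np.isfinite(mean_rmsd) or not np.isfinite(occupancy):
        raise ValueError("inputs must be finite")
    if not (0 <= occupancy <= 1):
        raise ValueError("occupancy must be in [0, 1]")
    rmsd_ok = mean_rmsd < rmsd_cutoff
    hbond_ok = occupancy >= c.occupancy_threshold
    score = int(rmsd_ok) + int(hbond_ok)
    return FilterScore(float(mean_rmsd), float(occupancy), score, score == 2,
                       rmsd_cutoff, c.occupancy_threshold)


def filter_trajectory(t: TrajectoryRecord, c: HBondCriterion | None = None,
                      rmsd_cutoff: float = 2.0,
                      equilibration_ns: float | None = 5.0) -> FilterScore:
    """Convenience: RMSD series + occupancy + score for one trajectory."""
    if c is None:
        c = HBondCriterion()
    series = ligand_rmsd_series(t, equilibration_ns=equilibration_ns)
    occ = water_bridge_occupancy(t, c, equilibration_ns=equilibration_ns)
    return assign_score(float(series.mean()), occ, c, rmsd_cutoff)
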