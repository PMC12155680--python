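"""Seed-deterministic synthetic inputs for every stage of the funnel.

The generators plant known ground truth with the statistical structure
each stage assumes, so the whole screen can be exercised and validated
without commercial libraries, docking engines, an MD engine or a
spectrophotometer:

* pose sets with a planted consensus cluster of controllable size,
* MD trajectories with a controllable mean ligand RMSD and a planted
  water-bridge occupancy,
* dark/light spectrum pairs whose difference is a Gaussian band with
  controllable amplitude suppression and noise (the structure of a
  retinal-competition assay: control normalized to 1, competitors below),
* conformer libraries with a controllable fraction of true pharmacophore
  matches.

All generators are deterministic per (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .consensus import STAGE1_METHODS, STAGE2_METHODS, Pose, PoseSet
from .geometry import apply_rigid, random_rigid, random_rotation
from .mdfilter import TrajectoryRecord
from .pharmacophore import (FeatureKind, LigandConformer, PharmacophoreFeature,
                            PharmacophoreModel, ExcludedVolume)
from .spectra import Spectrum

# Rigid fused-ring template ligand: a benzotriazole-like bicyclic with one
# clear acceptor nitrogen, stored with Kekule bond orders so it sanitizes
# cleanly in RDKit. The bond-order coloring makes its automorphism group
# trivial, keeping generated pose comparisons cheap and unambiguous.
TEMPLATE_SYMBOLS: tuple[str, ...] = ("C", "C", "C", "C", "N", "N", "N", "C", "C")
TEMPLATE_COORDS: np.ndarray = np.array([
    [-1.8407, -0.3896, 0.1030],
    [-1.5019, 0.9672, 0.0815],
    [-0.1675, 1.3857, 0.0066],
    [0.7953, 0.3766, -0.0449],
    [2.1593, 0.3821, -0.1207],
    [2.6672, -0.8610, -0.1465],
    [1.6466, -1.7083, -0.0881],
    [0.4899, -0.9776, -0.0253],
    [-0.8504, -1.3799, 0.0500],
])
TEMPLATE_BONDS: tuple[tuple[int, int, float], ...] = (
    (0, 1, 2.0), (1, 2, 1.0), (2, 3, 2.0), (3, 4, 1.0), (4, 5, 1.0),
    (5, 6, 2.0), (6, 7, 1.0), (7, 8, 2.0), (8, 0, 1.0), (7, 3, 1.0),
)
TEMPLATE_ACCEPTOR_INDEX = 5  # central triazole nitrogen


@dataclass
class PoseGenSpec:
    """Plant a consensus cluster of size k among n docking methods."""

    n_methods: int = 6
    consensus_size: int = 4
    jitter_sd: float = 0.3
    spacer: float = 10.0
    seed: int = 0
    clustering_threshold: float = 2.0  # only used to validate the spacer

    def __post_init__(self):
        if self.n_methods not in (6, 11):
            raise ValueError("n_methods must be 6 (stage 1) or 11 (stage 2)")
        if not (1 <= self.consensus_size <= self.n_methods):
            raise ValueError("consensus size must be in [1, n_methods]")
        if self.jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")
        if self.spacer <= 2 * self.clustering_threshold:
            raise ValueError("spacer must exceed twice the clustering threshold")


@dataclass
class TrajGenSpec:
    """Plant a mean ligand RMSD and a Bernoulli water-bridge occupancy."""

    n_frames: int = 100
    target_mean_rmsd: float = 1.0
    occupancy: float = 0.9
    seed: int = 0
    rmsd_rel_sd: float = 0.1  # frame-to-frame spread of displacements

    def __post_init__(self):
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        if not (0 <= self.occupancy <= 1):
            raise ValueError("occupancy must be in [0, 1]")
        if self.target_mean_rmsd < 0 or self.target_mean_rmsd > 8.0:
            raise ValueError("target mean RMSD must be in [0, 8] A "
                             "(acceptor orbit radius limit)")


@dataclass
class AssayGenSpec:
    """Plant a retinal-competition assay: Table-style suppression factors.

    noise_sd is the replicate-level relative SD of the band amplitude
    (the quantity that sets the control's normalized scatter, e.g. 0.07
    for a control of 1 +/- 0.07); a small proportional per-point
    absorbance noise (noise_sd * amplitude / 3) is added to both spectra
    unless overridden. noise_sd = 0 produces exactly noiseless spectra.
    """

    amplitude: float = 0.02
    center: float = 485.0
    sigma: float = 30.0
    factors: Mapping[str, float] = field(
        default_factory=lambda: {"VS1": 0.78, "VS3": 0.92, "VS5": 0.90,
                                 "beta-ionone": 0.73})
    noise_sd: float = 0.07
    point_noise_sd: float | None = None
    replicates: int = 3
    seed: int = 0
    control_label: str = "9cisRAL"
    baseline_amplitude: float = 0.2
    baseline_tau: float = 150.0

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        for name, f in self.factors.items():
            if not (0 < f <= 1):
                raise ValueError(f"suppression factor for {name!r} must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def template_pose(ligand_id: str, method_id: str,
                  coords: np.ndarray | None = None) -> Pose:
    return Pose(ligand_id, method_id,
                TEMPLATE_COORDS.copy() if coords is None else coords,
                TEMPLATE_SYMBOLS, TEMPLATE_BONDS)


def gen_pose_set(spec: PoseGenSpec, ligand_id: str = "LIG") -> PoseSet:
    """Pose set with exactly ``consensus_size`` mutually close poses.

    Consensus members are the rigid template plus Gaussian coordinate
    jitter; the remaining poses are displaced by distinct axis-aligned
    spacer translations, mutually and jointly more than ``spacer`` apart,
    so downstream complete-linkage clustering at the default threshold
    recovers the planted size. Which methods form the consensus is
    randomized per seed.
    """
    rng = np.random.default_rng(spec.seed)
    methods = list((STAGE1_METHODS + STAGE2_METHODS)[:spec.n_methods])
    members = rng.permutation(spec.n_methods)
    consensus_methods = {methods[i] for i in members[:spec.consensus_size]}
    poses = []
    spacer_count = 0
    axes = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
    for m in methods:
        jitter = rng.normal(0.0, spec.jitter_sd, size=TEMPLATE_COORDS.shape) \
            if spec.jitter_sd > 0 else 0.0
        if m in consensus_methods:
            coords = TEMPLATE_COORDS + jitter
        else:
            spacer_count += 1
            # distinct multiples along cycling axes: every spacer pair is
            # separated by >= spacer, and all sit >= spacer from the cluster
            axis = axes[spacer_count % 3]
            shift = axis * spec.spacer * (1 + (spacer_count - 1) // 3)
            coords = TEMPLATE_COORDS + shift + jitter
        poses.append(template_pose(ligand_id, m, coords))
    return PoseSet(ligand_id, poses)


def gen_trajectory(spec: TrajGenSpec, equilibrated: bool = True) -> TrajectoryRecord:
    """Trajectory with planted mean ligand RMSD and bridge occupancy.

    Frame 0 is the template. Each later frame translates the whole ligand
    rigidly so that its acceptor nitrogen stays on a fixed-radius shell
    around the (static) Y191 hydroxyl oxygen; a rigid translation makes
    the per-frame RMSD exactly the displacement length, and the constant
    acceptor-Y191 distance keeps bridge feasibility independent of the
    RMSD level. The bridging water oxygen sits midway between acceptor
    and Y191-O on planted-occupied frames and 10 A away otherwise.

    Atom layout: 0..8 ligand heavy atoms, 9 water O, 10 Y191 O.
    """
    rng = np.random.default_rng(spec.seed)
    n_lig = TEMPLATE_COORDS.shape[0]
    acc = TEMPLATE_COORDS[TEMPLATE_ACCEPTOR_INDEX]
    shell_radius = 4.5
    direction = np.array([1.0, 0.3, -0.2])
    direction /= np.linalg.norm(direction)
    tyr_o = acc + shell_radius * direction

    # per-frame displacement lengths with mean = target
    if spec.target_mean_rmsd == 0:
        lengths = np.zeros(spec.n_frames - 1)
    else:
        rel = rng.gamma(shape=1.0 / spec.rmsd_rel_sd ** 2,
                        scale=spec.rmsd_rel_sd ** 2, size=spec.n_frames - 1)
        lengths = np.clip(spec.target_mean_rmsd * rel, 0.0, 2 * shell_radius - 1e-6)
    occupied = rng.random(spec.n_frames - 1) < spec.occupancy

    frames = np.empty((spec.n_frames, n_lig + 2, 3))
    def build_frame(k, lig_coords, water_ok):
        frames[k, :n_lig] = lig_coords
        a = lig_coords[TEMPLATE_ACCEPTOR_INDEX]
        if water_ok:
            frames[k, n_lig] = 0.5 * (a + tyr_o)
        else:
            frames[k, n_lig] = tyr_o + np.array([10.0, 10.0, 10.0])
        frames[k, n_lig + 1] = tyr_o

    build_frame(0, TEMPLATE_COORDS, True)
    for k in range(1, spec.n_frames):
        L = lengths[k - 1]
        if L == 0:
            lig = TEMPLATE_COORDS
        else:
            # move the acceptor along a random great circle on the shell by
            # the chord length L; translate the whole ligand with it
            theta = 2.0 * np.arcsin(min(L / (2 * shell_radius), 1.0))
            # random unit axis orthogonal to (acc - tyr_o)
            radial = (acc - tyr_o) / shell_radius
            v = rng.normal(size=3)
            v -= v.dot(radial) * radial
            v /= np.linalg.norm(v)
            new_acc = tyr_o + shell_radius * (np.cos(theta) * radial
                                              + np.sin(theta) * v)
            lig = TEMPLATE_COORDS + (new_acc - acc)
        build_frame(k, lig, bool(occupied[k - 1]))

    return TrajectoryRecord(
        frames=frames,
        ligand_heavy=tuple(range(n_lig)),
        ligand_acceptor=(TEMPLATE_ACCEPTOR_INDEX,),
        water_oxygen=n_lig,
        tyr_oxygen=n_lig + 1,
        frame_interval_ns=None if equilibrated else 1.0,
    )


WAVELENGTH_GRID = np.arange(360.0, 601.0, 1.0)


def gen_assay(spec: AssayGenSpec) -> dict[str, list[tuple[Spectrum, Spectrum]]]:
    """Dark/light spectrum pairs per condition, control included.

    Dark spectrum: scattering-like exponential baseline plus the pigment
    Gaussian band scaled by the condition's suppression factor and a
    replicate-level amplitude factor (1 + N(0, noise_sd)); light spectrum:
    the same baseline with the band bleached away. Per-point Gaussian
    noise is added to both. 1 nm grid over 360-600 nm.
    """
    rng = np.random.default_rng(spec.seed)
    wl = WAVELENGTH_GRID
    baseline = spec.baseline_amplitude * np.exp(-(wl - wl[0]) / spec.baseline_tau)
    band = np.exp(-((wl - spec.center) ** 2) / (2.0 * spec.sigma ** 2))
    pt_sd = (spec.noise_sd * spec.amplitude / 3.0
             if spec.point_noise_sd is None else spec.point_noise_sd)

    conditions = {spec.control_label: 1.0, **dict(spec.factors)}
    out: dict[str, list[tuple[Spectrum, Spectrum]]] = {}
    for label, factor in conditions.items():
        pairs = []
        for _ in range(spec.replicates):
            amp = spec.amplitude * factor
            if spec.noise_sd > 0:
                amp *= max(1.0 + rng.normal(0.0, spec.noise_sd), 0.05)
            dark = baseline + amp * band
            light = baseline.copy()
            if pt_sd > 0:
                dark = dark + rng.normal(0.0, pt_sd, size=wl.shape)
                light = light + rng.normal(0.0, pt_sd, size=wl.shape)
            pairs.append((Spectrum(wl.copy(), dark), Spectrum(wl.copy(), light)))
        out[label] = pairs
    return out


# --- pharmacophore library generation -----------------------------------

_HEX_ANGLES = np.arange(6) * np.pi / 3.0
_BENZENE_LOCAL = np.stack([1.396 * np.cos(_HEX_ANGLES),
                           1.396 * np.sin(_HEX_ANGLES),
                           np.zeros(6)], axis=1)
_BENZENE_BONDS = tuple((i, (i + 1) % 6, 1.5) for i in range(6))


def fixture_model() -> PharmacophoreModel:
    """Illustrative receptor-frame pharmacophore model used for testing.

    The geometry is plausible for a GPCR retinal-binding pocket (feature
    separations 4-7 A, excluded volumes > 4 A from every feature center)
    but is synthetic, not a reconstruction of any published hypothesis.
    """
    # deliberately scalene constellation: permuting the hydrophobic
    # assignment forces a fitted deviation > 4 A, so assignments are
    # unambiguous at the default 1.5 A tolerance
    feats = [
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, (0.0, 0.0, 0.0), 1.5),
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, (-0.5, -3.8, 2.5), 1.5),
        PharmacophoreFeature(FeatureKind.HYDROPHOBIC, (-3.3, 3.1, -0.3), 1.5),
        PharmacophoreFeature(FeatureKind.HBOND_ACCEPTOR, (1.7, -2.2, 4.7), 1.5),
    ]
    vols = [
        ExcludedVolume((4.0, 2.5, 0.0), 1.2),
        ExcludedVolume((-4.5, -1.0, -2.5), 1.2),
        ExcludedVolume((0.5, 3.0, 3.5), 1.2),
    ]
    return PharmacophoreModel(feats, vols)


def _place_ring(center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    R = random_rotation(rng)
    return _BENZENE_LOCAL @ R.T + center


def _assignment_outcomes(model: PharmacophoreModel, feature_pos: np.ndarray,
                         heavy: np.ndarray) -> list[tuple[float, float]]:
    """Generator-side exhaustive feasibility check for decoy verification.

    ``feature_pos`` rows are the ligand feature positions ordered like the
    model features (3 hydrophobic then matched by kind). For each
    kind-compatible assignment, superposes the 4 points onto the model
    centers (scipy Rotation.align_vectors, a separate code path from the
    matcher) and returns (max feature deviation beyond tolerance, deepest
    excluded-volume penetration of any heavy atom) per assignment.
    """
    import itertools

    from scipy.spatial.transform import Rotation

    hydro_idx = [i for i, f in enumerate(model.features)
                 if f.kind == FeatureKind.HYDROPHOBIC]
    acc_idx = next(i for i, f in enumerate(model.features)
                   if f.kind == FeatureKind.HBOND_ACCEPTOR)
    centers = model.centers
    tol = np.array([f.tolerance for f in model.features])
    outcomes = []
    for perm in itertools.permutations(range(3)):
        # feature_pos rows follow model feature order; permute hydrophobics
        P = feature_pos.copy()
        P[hydro_idx] = feature_pos[[hydro_idx[p] for p in perm]]
        cp, cq = P.mean(axis=0), centers.mean(axis=0)
        rot, _ = Rotation.align_vectors(centers - cq, P - cp)
        moved = rot.apply(P - cp) + cq
        over = float(np.max(np.linalg.norm(moved - centers, axis=1) - tol))
        moved_heavy = rot.apply(heavy - cp) + cq
        # signed penetration: positive = an atom inside a volume, negative
        # = clearance of the closest approach
        pen = -np.inf
        for v in model.volumes:
            d = np.linalg.norm(moved_heavy - np.asarray(v.center), axis=1)
            pen = max(pen, float(v.radius - d.min()))
        outcomes.append((over, pen))
    return outcomes


def _build_conformer(identifier: str, model: PharmacophoreModel,
                     rng: np.random.Generator, matching: bool,
                     placement_jitter: float = 0.1) -> LigandConformer:
    """Multi-fragment conformer with a guaranteed match/no-match label.

    Matching ligands place three benzene rings at the hydrophobic centers
    and a carbonyl oxygen at the acceptor center (small jitter, well
    inside tolerance). Non-matchers either displace the acceptor outward
    or plant a carbon inside an excluded volume. Because a least-squares
    fit of four points can partially absorb a single displaced point, the
    label of every candidate is *verified* by an exhaustive assignment
    check with safety margins, resampling until the label is guaranteed;
    the verifier shares no code with the matcher. The final conformer is
    returned in a random rigid frame the matcher must recover.
    """
    hydro = [np.asarray(f.center) for f in model.features
             if f.kind == FeatureKind.HYDROPHOBIC]
    acc_feature = next(f for f in model.features
                       if f.kind == FeatureKind.HBOND_ACCEPTOR)
    acc_center = np.asarray(acc_feature.center)
    hydro_idx = [i for i, f in enumerate(model.features)
                 if f.kind == FeatureKind.HYDROPHOBIC]
    acc_idx = next(i for i, f in enumerate(model.features)
                   if f.kind == FeatureKind.HBOND_ACCEPTOR)
    centroid = np.mean(hydro + [acc_center], axis=0)
    margin = 0.3

    want_volume_decoy = (not matching and bool(model.volumes)
                         and rng.random() < 0.5)
    displacement = 2.0 * acc_feature.tolerance + 0.5

    for attempt in range(200):
        if want_volume_decoy and attempt >= 60:
            # near-symmetric user models can make a volume decoy genuinely
            # ambiguous under permuted assignments; fall back
            want_volume_decoy = False
        rings = [_place_ring(c + rng.normal(0, placement_jitter, 3), rng)
                 for c in hydro]
        if matching or want_volume_decoy:
            acc_pos = acc_center + rng.normal(0, placement_jitter, 3)
        else:
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            acc_pos = acc_center + d * displacement
            displacement *= 1.2  # widen until the decoy label certifies

        symbols: list[str] = []
        coords_list: list[np.ndarray] = []
        bonds: list[tuple[int, int, float]] = []
        ring_centroids = []
        for ring in rings:
            base = len(symbols)
            symbols.extend(["C"] * 6)
            coords_list.append(ring)
            bonds.extend((base + i, base + j, o) for i, j, o in _BENZENE_BONDS)
            ring_centroids.append(ring.mean(axis=0))
        away = acc_pos - centroid
        away = away / (np.linalg.norm(away) + 1e-12)
        base = len(symbols)
        symbols.extend(["O", "C"])
        coords_list.append(np.stack([acc_pos, acc_pos + 1.22 * away]))
        bonds.append((base, base + 1, 2.0))
        if want_volume_decoy:
            vol = model.volumes[int(rng.integers(len(model.volumes)))]
            symbols.append("C")
            coords_list.append(np.asarray(vol.center, dtype=float)[None, :])
        heavy = np.vstack(coords_list)

        feature_pos = np.zeros((4, 3))
        for slot, rc in zip(hydro_idx, ring_centroids):
            feature_pos[slot] = rc
        feature_pos[acc_idx] = acc_pos
        outcomes = _assignment_outcomes(model, feature_pos, heavy)
        if matching:
            # identity assignment is first: must fit with clear margin
            over, pen = outcomes[0]
            ok = over <= -margin and pen <= -margin
        else:
            # no assignment may come close to fitting cleanly: each must
            # either overshoot a tolerance or bury an atom in a volume,
            # with margin against the construction jitter
            ok = all(over > margin or pen > margin for over, pen in outcomes)
        if ok:
            conf = LigandConformer(identifier, symbols, heavy, bonds)
            R, t = random_rigid(rng, max_translation=8.0)
            return conf.transformed(R, t)
    raise RuntimeError("could not construct a certified library conformer")


def gen_library(n_ligands: int, fraction_matching: float,
                model: PharmacophoreModel | None = None,
                seed: int = 0) -> tuple[list[LigandConformer], list[bool]]:
    """Conformer library with ground-truth match labels.

    Matching ligands carry feature points within a small jitter of the
    model centers (margin far inside tolerance); non-matching ligands
    either displace the acceptor by >= 2x its tolerance or plant a heavy
    atom at an excluded-volume center. Returns (conformers, labels).
    """
    if not (0 <= fraction_matching <= 1):
        raise ValueError("fraction must be in [0, 1]")
    if model is None:
        model = fixture_model()
    rng = np.random.default_rng(seed)
    n_match = int(round(fraction_matching * n_ligands))
    labels = [True] * n_match + [False] * (n_ligands - n_match)
    rng.shuffle(labels)
    confs = [_build_conformer(f"SYN{i:05d}", model, rng, matching=lab)
             for i, lab in enumerate(labels)]
    return confs, labels


# --- whole-funnel cohort --------------------------------------------------

@dataclass
class CohortLigand:
    """One synthetic ligand with its planted stage outcomes."""

    ligand_id: str
    conformer: LigandConformer
    pharmacophore_match: bool
    stage1_level: int | None
    stage2_level: int | None
    md_mean_rmsd: float | None
    md_occupancy: float | None
    pains_flagged: bool
    stage1_poses: PoseSet | None
    stage2_extra: list[Pose] | None
    trajectory: TrajectoryRecord | None


def gen_cohort(n_ligands: int, seed: int = 0,
               model: PharmacophoreModel | None = None,
               n_traj_frames: int = 200) -> list[CohortLigand]:
    """Mixed synthetic cohort exercising every funnel stage.

    Planted fates are drawn per ligand: fail the pharmacophore; fail
    stage-1 consensus (level 3); fail stage-2 (level 10); fail the MD
    filter (high RMSD and/or broken bridge); or pass everything. A small
    fraction of the full passers carries a rhodanine-like PAINS
    substructure and is removed at the alert screen. Deterministic per
    seed.
    """
    if model is None:
        model = fixture_model()
    rng = np.random.default_rng(seed)
    fates = rng.choice(
        ["pharm_fail", "stage1_fail", "stage2_fail", "md_fail", "pass", "pains"],
        size=n_ligands, p=[0.30, 0.25, 0.20, 0.12, 0.10, 0.03])
    cohort: list[CohortLigand] = []
    for i, fate in enumerate(fates):
        lid = f"SYN{i:05d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = np.random.default_rng(sub_seed)
        conf = _build_conformer(lid, model, sub, matching=(fate != "pharm_fail"))
        if fate == "pains":
            conf = _attach_pains_fragment(conf)
        entry = CohortLigand(lid, conf, fate != "pharm_fail", None, None,
                             None, None, fate == "pains", None, None, None)
        if fate == "pharm_fail":
            cohort.append(entry)
            continue
        # full 11-of-11 consensus downstream requires all six stage-1 poses
        # in the cluster, so passers plant k1 = 6
        if fate == "stage1_fail":
            k1 = 3
        elif fate == "stage2_fail":
            k1 = int(sub.integers(4, 7))
        else:
            k1 = 6
        ps1 = gen_pose_set(PoseGenSpec(6, k1, seed=sub_seed + 1), lid)
        entry.stage1_level = k1
        entry.stage1_poses = ps1
        if fate == "stage1_fail":
            cohort.append(entry)
            continue
        # stage 2: extend the stage-1 set so that the combined 11-pose set
        # has the planted level (11 for passers, k1 + 4 <= 10 otherwise)
        k2 = 11 if fate in ("pass", "md_fail", "pains") else k1 + 4
        entry.stage2_level = k2
        entry.stage2_extra = _extend_to_stage2(ps1, k1, k2, sub)
        if fate == "stage2_fail":
            cohort.append(entry)
            continue
        if fate == "md_fail":
            mode = sub.integers(3)  # 0: rmsd fail, 1: hbond fail, 2: both
            rmsd = 3.0 if mode in (0, 2) else 1.0
            occ = 0.2 if mode in (1, 2) else 0.9
        else:
            rmsd, occ = 1.0, 0.9
        entry.md_mean_rmsd = rmsd
        entry.md_occupancy = occ
        entry.trajectory = gen_trajectory(
            TrajGenSpec(n_traj_frames, rmsd, occ, seed=sub_seed + 2))
        cohort.append(entry)
    return cohort


def _extend_to_stage2(ps1: PoseSet, k1: int, k2: int,
                      rng: np.random.Generator) -> list[Pose]:
    """Five extra-method poses giving the combined set consensus level k2.

    The planted consensus cluster of the combined 11-pose set consists of
    the k1 stage-1 members plus (k2 - k1) of the five new poses, all near
    the template; the remaining new poses are displaced along negative
    axes so they stay far from both the cluster and the stage-1 spacers.
    Requires 0 <= k2 - k1 <= 5 (a level-11 plant needs k1 = 6).
    """
    n_extra = 5
    extra_close = k2 - k1
    if not (0 <= extra_close <= n_extra):
        raise ValueError("infeasible stage-2 consensus plant")
    methods = list(STAGE2_METHODS)
    close_methods = set(
        methods[i] for i in rng.permutation(n_extra)[:extra_close])
    poses = []
    spacer = 10.0
    count = 0
    for m in methods:
        jitter = rng.normal(0.0, 0.3, size=TEMPLATE_COORDS.shape)
        if m in close_methods:
            coords = TEMPLATE_COORDS + jitter
        else:
            count += 1
            # offsets distinct from stage-1 spacers (negative axis directions)
            axis = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])[count % 3]
            coords = TEMPLATE_COORDS + axis * spacer * (1 + (count - 1) // 3) + jitter
        poses.append(template_pose(ps1.ligand_id, m, coords))
    return poses


_PAINS_RING = np.array([  # planar rhodanine-like 5-ring + exocyclic S, O
    [0.000, 1.100, 0.0],   # S1 (ring)
    [1.046, 0.340, 0.0],   # C2
    [0.646, -0.990, 0.0],  # N3
    [-0.746, -0.990, 0.0],  # C4
    [-1.146, 0.340, 0.0],  # C5
    [2.300, 0.800, 0.0],   # S exocyclic (C2=S)
    [-1.500, -2.050, 0.0],  # O exocyclic (C4=O)
])
_PAINS_SYMBOLS = ("S", "C", "N", "C", "C", "S", "O")
_PAINS_BONDS = ((0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 4, 1.0),
                (4, 0, 1.0), (1, 5, 2.0), (3, 6, 2.0))


def _attach_pains_fragment(conf: LigandConformer) -> LigandConformer:
    """Append a rhodanine-like fragment (a classic PAINS motif) far from
    the pharmacophore so the match outcome is unaffected."""
    offset = conf.coords.mean(axis=0) + np.array([25.0, 0.0, 0.0])
    base = len(conf.symbols)
    symbols = list(conf.symbols) + list(_PAINS_SYMBOLS)
    coords = np.vstack([conf.coords, _PAINS_RING + offset])
    bonds = list(conf.bonds) + [(base + i, base + j, o)
                                for i, j, o in _PAINS_BONDS]
    return LigandConformer(conf.identifier, symbols, coords, bonds)
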