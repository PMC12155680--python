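"""Funnel orchestration: pharmacophore -> consensus stages -> MD -> PAINS.

Each ligand is evaluated stage by stage and short-circuits at its first
failure, so per-stage counts are non-increasing along the funnel. The
report carries a full per-ligand decision trail plus run metadata (a
config hash and the seed), and the trail serialization is deterministic:
the same config and inputs reproduce it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from .consensus import Pose, PoseSet, consensus_of, hierarchical_screen
from .mdfilter import HBondCriterion, TrajectoryRecord, filter_trajectory
from .pharmacophore import LigandConformer, PharmacophoreModel, match

STAGES = ("pharmacophore", "consensus_stage1", "consensus_stage2",
          "md_filter", "pains")


@dataclass
class FunnelConfig:
    """Tunable thresholds of the screen; defaults are the protocol values."""

    clustering_threshold: float = 2.0
    stage1_min_level: int = 4
    stage2_required_level: int = 11
    md_rmsd_cutoff: float = 2.0
    hbond_distance_cutoff: float = 3.5
    hbond_occupancy_threshold: float = 0.5
    symmetry_rmsd: bool = True
    pains_catalog: str | None = None  # path; None = bundled mini-catalog
    seed: int = 0

    def __post_init__(self):
        for name in ("clustering_threshold", "md_rmsd_cutoff",
                     "hbond_distance_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (1 <= self.stage1_min_level <= 6):
            raise ValueError("stage1_min_level must be within the 6-pose set")
        if not (1 <= self.stage2_required_level <= 11):
            raise ValueError("stage2_required_level must be within the 11-pose set")

    def hbond_criterion(self) -> HBondCriterion:
        return HBondCriterion(self.hbond_distance_cutoff,
                              occupancy_threshold=self.hbond_occupancy_threshold)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_pains_catalog(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load a PAINS pattern catalog: lines of ``SMARTS<TAB>name``.

    Blank lines and ``#`` comments are skipped. Defaults to the bundled
    mini-catalog of ten representative interference motifs.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "pains_mini.smarts"
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smarts = parts[0].strip()
        name = parts[1].strip() if len(parts) > 1 else smarts
        entries.append((name, smarts))
    if not entries:
        raise ValueError(f"PAINS catalog {path} contains no patterns")
    return entries


def pains_screen(molecules: Mapping[str, LigandConformer] | Sequence[LigandConformer],
                 catalog: Sequence[tuple[str, str]] | None = None
                 ) -> dict[str, list[str]]:
    """Substructure alert screen: matched catalog pattern names per molecule.

    ``molecules`` may also be a mapping of id -> SMILES string. Molecules
    with at least one alert should be excluded from a final selection.
    Raises on an unparseable catalog pattern, naming it.
    """
    from rdkit import Chem

    if catalog is None:
        catalog = load_pains_catalog()
    patterns = []
    for name, smarts in catalog:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"unparseable PAINS pattern: {name} ({smarts})")
        patterns.append((name, patt))

    if not isinstance(molecules, Mapping):
        molecules = {m.identifier: m for m in molecules}
    alerts: dict[str, list[str]] = {}
    for mid, mol in molecules.items():
        if isinstance(mol, LigandConformer):
            rdmol = mol.to_rdkit()
        else:
            rdmol = Chem.MolFromSmiles(mol)
            if rdmol is None:
                raise ValueError(f"unparseable molecule: {mid}")
        alerts[mid] = [name for name, patt in patterns
                       if rdmol.HasSubstructMatch(patt)]
    return alerts


@dataclass
class LigandTrail:
    """Per-ligand decision record: how far it got and why it stopped."""

    ligand_id: str
    pharmacophore_matched: bool | None = None
    stage1_level: int | None = None
    stage2_level: int | None = None
    md_mean_rmsd: float | None = None
    md_occupancy: float | None = None
    md_score: int | None = None
    pains_alerts: list[str] | None = None
    failed_stage: str | None = None  # None = selected; "md_filter:not_evaluated"
    selected: bool = False


@dataclass
class FunnelReport:
    """Stage counts, per-ligand trails and run metadata."""

    config_hash: str
    seed: int
    counts: dict[str, dict[str, int]]
    trails: list[LigandTrail]
    timestamp: float = field(default_factory=time.time)

    def selected_ids(self) -> list[str]:
        return [t.ligand_id for t in self.trails if t.selected]

    def canonical_json(self) -> str:
        """Deterministic serialization of counts and trails (metadata other
        than the config hash and seed excluded); byte-identical across
        repeated runs with the same config, inputs and seed."""
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "counts": self.counts,
            "trails": [asdict(t) for t in sorted(self.trails,
                                                 key=lambda t: t.ligand_id)],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    def consistency_check(self) -> None:
        """Recompute stage counts from the trails; raise on mismatch."""
        recomputed = _counts_from_trails(self.trails)
        if recomputed != self.counts:
            raise AssertionError("stage counts do not match decision trails")


def _counts_from_trails(trails: list[LigandTrail]) -> dict[str, dict[str, int]]:
    counts: dict[str, dict[str, int]] = {}
    entered = {s: 0 for s in STAGES}
    survived = {s: 0 for s in STAGES}
    for t in trails:
        reached = True
        for stage in STAGES:
            if not reached:
                break
            entered[stage] += 1
            failed_here = (t.failed_stage or "").split(":")[0] == stage
            if failed_here:
                reached = False
            else:
                survived[stage] += 1
    for s in STAGES:
        counts[s] = {"in": entered[s], "out": survived[s]}
    return counts


def run_funnel(config: FunnelConfig,
               model: PharmacophoreModel,
               library: Mapping[str, LigandConformer],
               stage1_poses: Mapping[str, PoseSet],
               stage2_extra: Mapping[str, Sequence[Pose]],
               trajectories: Mapping[str, TrajectoryRecord],
               pains_catalog: Sequence[tuple[str, str]] | None = None
               ) -> FunnelReport:
    """Run the full screen and return the decision report.

    Stage inputs are looked up lazily: pose sets are required for every
    pharmacophore survivor (missing ones raise, listing the ligand ids),
    while ligands lacking a trajectory are reported as not evaluated at
    the MD stage rather than failed — mirroring a campaign where MD is
    run only on consensus survivors.
    """
    if pains_catalog is None:
        pains_catalog = load_pains_catalog(config.pains_catalog)
    hb = config.hbond_criterion()
    trails: list[LigandTrail] = []

    ids = sorted(library)
    survivors = []
    for lid in ids:
        trail = LigandTrail(lid)
        res = match(model, library[lid])
        trail.pharmacophore_matched = res.matched
        if not res.matched:
            trail.failed_stage = "pharmacophore"
            trails.append(trail)
        else:
            survivors.append((lid, trail))

    # pose sets are required only for ligands that actually reach the
    # consensus stages: stage-1 for every pharmacophore survivor, stage-2
    # extras for stage-1 survivors (stage-2 docking is run only on them)
    missing1 = [lid for lid, _ in survivors if lid not in stage1_poses]
    if missing1:
        raise ValueError("missing stage-1 pose sets for surviving ligands: "
                         + ", ".join(missing1))
    stage1_results = {}
    stage2_entrants = []
    for lid, trail in survivors:
        r1 = consensus_of(stage1_poses[lid].sorted_by_method(),
                          config.clustering_threshold,
                          symmetry=config.symmetry_rmsd)
        trail.stage1_level = r1.level
        stage1_results[lid] = r1
        if r1.level < config.stage1_min_level:
            trail.failed_stage = "consensus_stage1"
            trails.append(trail)
        else:
            stage2_entrants.append((lid, trail))
    missing2 = [lid for lid, _ in stage2_entrants if lid not in stage2_extra]
    if missing2:
        raise ValueError("missing stage-2 pose sets for surviving ligands: "
                         + ", ".join(missing2))

    md_candidates = []
    for lid, trail in stage2_entrants:
        decision = hierarchical_screen(
            stage1_poses[lid], list(stage2_extra[lid]),
            threshold=config.clustering_threshold,
            min_level=config.stage1_min_level,
            required_level=config.stage2_required_level,
            symmetry=config.symmetry_rmsd)
        trail.stage2_level = decision.stage2_level
        if not decision.passed:
            trail.failed_stage = "consensus_stage2"
            trails.append(trail)
            continue
        md_candidates.append((lid, trail))

    pains_candidates = []
    for lid, trail in md_candidates:
        traj = trajectories.get(lid)
        if traj is None:
            trail.failed_stage = "md_filter:not_evaluated"
            trails.append(trail)
            continue
        score = filter_trajectory(traj, hb, rmsd_cutoff=config.md_rmsd_cutoff)
        trail.md_mean_rmsd = score.mean_rmsd
        trail.md_occupancy = score.occupancy
        trail.md_score = score.score
        if not score.passed:
            trail.failed_stage = "md_filter"
            trails.append(trail)
            continue
        pains_candidates.append((lid, trail))

    if pains_candidates:
        alert_map = pains_screen(
            {lid: library[lid] for lid, _ in pains_candidates}, pains_catalog)
    else:
        alert_map = {}
    for lid, trail in pains_candidates:
        trail.pains_alerts = alert_map[lid]
        if trail.pains_alerts:
            trail.failed_stage = "pains"
        else:
            trail.selected = True
        trails.append(trail)

    report = FunnelReport(config.hash(), config.seed,
                          _counts_from_trails(trails), trails)
    report.consistency_check()
    return report


def report_to_tsv(report: FunnelReport) -> str:
    """Flat TSV rendering of the per-ligand decision trail."""
    cols = ["ligand_id", "pharmacophore_matched", "stage1_level",
            "stage2_level", "md_mean_rmsd", "md_occupancy", "md_score",
            "pains_alerts", "failed_stage", "selected"]
    lines = ["\t".join(cols)]
    for t in sorted(report.trails, key=lambda t: t.ligand_id):
        row = []
        for c in cols:
            v = getattr(t, c)
            if isinstance(v, float):
                v = f"{v:.4f}"
            elif isinstance(v, list):
                v = ";".join(v)
            row.append("" if v is None else str(v))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
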