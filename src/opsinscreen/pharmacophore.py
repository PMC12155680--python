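"""Receptor-based 3D pharmacophore model and conformer matching.

The model mirrors the retinal-binding-site hypothesis used for opsin
screening: three hydrophobic features plus one hydrogen-bond acceptor
feature (the acceptor stands for the interaction with the structural
water that bridges to Y191), surrounded by excluded-volume spheres
marking receptor-occupied space.

A conformer *matches* the model when an injective, kind-compatible
assignment of its detected feature points to all four model features
exists such that, after a single least-squares rigid superposition of
the four assigned points onto the model centers, every assigned point
lies within its feature's tolerance radius and no ligand heavy atom
penetrates an excluded volume.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import apply_rigid, kabsch

HALOGENS = {"F", "Cl", "Br", "I"}


class FeatureKind(str, Enum):
    HYDROPHOBIC = "hydrophobic"
    HBOND_ACCEPTOR = "hbond_acceptor"


@dataclass(frozen=True)
class PharmacophoreFeature:
    """One mandatory model feature: a sphere of radius ``tolerance`` at ``center``."""

    kind: FeatureKind
    center: tuple[float, float, float]
    tolerance: float = 1.5

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("feature tolerance must be > 0")
        if not isinstance(self.kind, FeatureKind):
            object.__setattr__(self, "kind", FeatureKind(self.kind))
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("feature center must be a finite 3D point")
        object.__setattr__(self, "center", tuple(float(x) for x in c))


@dataclass(frozen=True)
class ExcludedVolume:
    """Receptor-occupied sphere no ligand heavy atom may enter."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("excluded-volume radius must be > 0")
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("excluded-volume center must be a finite 3D point")
        object.__setattr__(self, "center", tuple(float(x) for x in c))


@dataclass
class PharmacophoreModel:
    """Exactly four mandatory features (3 hydrophobic + 1 acceptor) plus volumes."""

    features: list[PharmacophoreFeature]
    volumes: list[ExcludedVolume] = field(default_factory=list)

    def __post_init__(self):
        if len(self.features) != 4:
            raise ValueError("model must have exactly 4 features")
        counts = {k: 0 for k in FeatureKind}
        for f in self.features:
            counts[f.kind] += 1
        if counts[FeatureKind.HYDROPHOBIC] != 3 or counts[FeatureKind.HBOND_ACCEPTOR] != 1:
            raise ValueError("model must contain 3 hydrophobic features and 1 acceptor")

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center for f in self.features], dtype=float)

    def to_dict(self) -> dict:
        return {
            "features": [
                {"kind": f.kind.value, "center": list(f.center), "tolerance": f.tolerance}
                for f in self.features
            ],
            "volumes": [
                {"center": list(v.center), "radius": v.radius} for v in self.volumes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PharmacophoreModel":
        feats = [
            PharmacophoreFeature(FeatureKind(f["kind"]), tuple(f["center"]),
                                 float(f.get("tolerance", 1.5)))
            for f in d["features"]
        ]
        vols = [ExcludedVolume(tuple(v["center"]), float(v["radius"]))
                for v in d.get("volumes", [])]
        return cls(feats, vols)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PharmacophoreModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LigandConformer:
    """A 3D conformer: element symbols, coordinates (Angstrom), bond graph.

    ``bonds`` entries are ``(i, j, order)`` with order 1, 2, 3 or 1.5
    (aromatic). ``charges`` are formal charges, defaulting to neutral.
    """

    identifier: str
    symbols: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    charges: list[int] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.symbols) == 0:
            raise ValueError("no atoms")
        if self.coords.shape != (len(self.symbols), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.symbols)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError("bond indices out of range")
        if self.charges is None:
            self.charges = [0] * n
        elif len(self.charges) != n:
            raise ValueError("charges length must equal atom count")

    @property
    def heavy_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.symbols) if s != "H"]

    @property
    def heavy_coords(self) -> np.ndarray:
        return self.coords[self.heavy_indices]

    def to_rdkit(self):
        """Build a sanitized RDKit molecule carrying this conformer."""
        from rdkit import Chem
        from rdkit.Chem import AllChem  # noqa: F401  (registers conformer API)
        from rdkit.Geometry import Point3D

        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
                     3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}
        em = Chem.RWMol()
        for sym, q in zip(self.symbols, self.charges):
            a = Chem.Atom(sym)
            a.SetFormalCharge(int(q))
            a.SetNoImplicit(False)
            em.AddAtom(a)
        for i, j, order in self.bonds:
            idx = em.AddBond(int(i), int(j), order_map[float(order)]) - 1
            if float(order) == 1.5:
                em.GetBondWithIdx(idx).SetIsAromatic(True)
                em.GetAtomWithIdx(int(i)).SetIsAromatic(True)
                em.GetAtomWithIdx(int(j)).SetIsAromatic(True)
        mol = em.GetMol()
        Chem.SanitizeMol(mol)
        conf = Chem.Conformer(len(self.symbols))
        for i, (x, y, z) in enumerate(self.coords):
            conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
        mol.AddConformer(conf, assignId=True)
        return mol

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "LigandConformer":
        return LigandConformer(self.identifier, list(self.symbols),
                               apply_rigid(R, t, self.coords),
                               list(self.bonds), list(self.charges))


@dataclass(frozen=True)
class FeaturePoint:
    """A ligand-side feature: position plus the atoms it derives from."""

    kind: FeatureKind
    position: tuple[float, float, float]
    source_atoms: tuple[int, ...]


# SMARTS for acceptor typing: N or O bearing a lone pair and no positive
# charge, excluding amide and aniline nitrogens and pyrrole-type NH.
_ACCEPTOR_SMARTS = (
    "[$([OX1;!+]),$([OX2;!+]),"
    "$([N;!+;X1,X2]),"
    "$([NX3;!+;!$([NX3][CX3]=[OX1]);!$([NX3][a]);!$([nH])])]"
)


def detect_features(conformer: LigandConformer) -> list[FeaturePoint]:
    """Type ligand feature points with a fixed, documented rule set.

    Hydrophobic points: the centroid of each aromatic ring; the centroid
    of each maximal connected set of >= 3 sp3 carbons bonded only to C/H;
    each halogen atom bound to carbon. Acceptor points: every N or O with
    a lone pair and no positive formal charge, excluding amide and aniline
    nitrogens. Deterministic for a given conformer; duplicate positions of
    the same kind are merged.
    """
    from rdkit import Chem

    if len(conformer.symbols) == 0:  # defensive; constructor also rejects
        raise ValueError("no atoms")
    mol = conformer.to_rdkit()
    coords = conformer.coords
    points: list[FeaturePoint] = []

    ring_info = mol.GetRingInfo()
    for ring in ring_info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            centroid = coords[list(ring)].mean(axis=0)
            points.append(FeaturePoint(FeatureKind.HYDROPHOBIC,
                                       tuple(centroid), tuple(sorted(ring))))

    # maximal chains of sp3 carbons whose neighbours are only C or H
    sp3 = set()
    for atom in mol.GetAtoms():
        if (atom.GetSymbol() == "C"
                and atom.GetHybridization() == Chem.HybridizationType.SP3
                and all(nb.GetSymbol() in ("C", "H") for nb in atom.GetNeighbors())):
            sp3.add(atom.GetIdx())
    seen: set[int] = set()
    for start in sorted(sp3):
        if start in seen:
            continue
        comp, stack = [], [start]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            comp.append(i)
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                if nb.GetIdx() in sp3 and nb.GetIdx() not in seen:
                    stack.append(nb.GetIdx())
        if len(comp) >= 3:
            centroid = coords[comp].mean(axis=0)
            points.append(FeaturePoint(FeatureKind.HYDROPHOBIC,
                                       tuple(centroid), tuple(sorted(comp))))

    for atom in mol.GetAtoms():
        if atom.GetSymbol() in HALOGENS and any(
                nb.GetSymbol() == "C" for nb in atom.GetNeighbors()):
            i = atom.GetIdx()
            points.append(FeaturePoint(FeatureKind.HYDROPHOBIC,
                                       tuple(coords[i]), (i,)))

    patt = Chem.MolFromSmarts(_ACCEPTOR_SMARTS)
    for (i,) in mol.GetSubstructMatches(patt):
        points.append(FeaturePoint(FeatureKind.HBOND_ACCEPTOR,
                                   tuple(coords[i]), (i,)))

    # deduplicate near-coincident points of the same kind
    out: list[FeaturePoint] = []
    for p in points:
        dup = any(p.kind == q.kind
                  and np.linalg.norm(np.subtract(p.position, q.position)) < 1e-6
                  for q in out)
        if not dup:
            out.append(p)
    return out


@dataclass
class MatchResult:
    """Outcome of matching one conformer against the model."""

    matched: bool
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    assignment: tuple[int, ...] | None = None  # feature-point index per model feature
    residual: float = float("inf")


def _clashes(model: PharmacophoreModel, heavy: np.ndarray) -> bool:
    for v in model.volumes:
        d = np.linalg.norm(heavy - np.asarray(v.center), axis=1)
        if np.any(d < v.radius - 1e-9):  # strictly inside
            return True
    return False


def match(model: PharmacophoreModel, conformer: LigandConformer,
          feature_points: Sequence[FeaturePoint] | None = None) -> MatchResult:
    """Decide whether a conformer matches all four model features.

    Exhaustive over kind-compatible injective assignments of detected
    feature points to model features; each assignment is scored by a
    single least-squares rigid fit of the four assigned points onto the
    model centers. Among valid assignments the smallest-residual one is
    reported. The decision is invariant under rigid transforms of the
    input conformer.
    """
    if feature_points is None:
        feature_points = detect_features(conformer)
    by_kind: dict[FeatureKind, list[int]] = {k: [] for k in FeatureKind}
    for idx, p in enumerate(feature_points):
        by_kind[p.kind].append(idx)

    hydro_feats = [i for i, f in enumerate(model.features)
                   if f.kind == FeatureKind.HYDROPHOBIC]
    acc_feat = next(i for i, f in enumerate(model.features)
                    if f.kind == FeatureKind.HBOND_ACCEPTOR)

    if len(by_kind[FeatureKind.HYDROPHOBIC]) < 3 or not by_kind[FeatureKind.HBOND_ACCEPTOR]:
        return MatchResult(False)

    pos = np.array([p.position for p in feature_points], dtype=float)
    centers = model.centers
    tol = np.array([f.tolerance for f in model.features])
    heavy = conformer.heavy_coords

    best = MatchResult(False)
    for hydro_pick in itertools.permutations(by_kind[FeatureKind.HYDROPHOBIC], 3):
        for acc_pick in by_kind[FeatureKind.HBOND_ACCEPTOR]:
            assign = [0, 0, 0, 0]
            for feat_i, pt_i in zip(hydro_feats, hydro_pick):
                assign[feat_i] = pt_i
            assign[acc_feat] = acc_pick
            P = pos[assign]
            R, t, resid = kabsch(P, centers)
            dev = np.linalg.norm(apply_rigid(R, t, P) - centers, axis=1)
            if np.any(dev > tol):
                continue
            if _clashes(model, apply_rigid(R, t, heavy)):
                continue
            if resid < best.residual:
                best = MatchResult(True, R, t, tuple(assign), resid)
    return best
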