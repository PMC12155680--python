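"""File I/O for the screening pipeline.

Conformers and docking poses travel as SDF (V2000) or MOL2 through
RDKit; MD trajectories as multi-frame XYZ read through MDAnalysis with a
JSON sidecar assigning atom roles; spectra as two-column CSV/TSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import Pose, PoseSet
from .mdfilter import TrajectoryRecord
from .pharmacophore import LigandConformer
from .spectra import Spectrum


# --- conformers and poses (SDF / MOL2 via RDKit) --------------------------

def _rdkit_to_conformer(mol, identifier: str | None = None) -> LigandConformer:
    from rdkit import Chem  # noqa: F401

    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                        conf.GetAtomPosition(i).z] for i in range(mol.GetNumAtoms())])
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
             for b in mol.GetBonds()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    name = identifier or (mol.GetProp("_Name") if mol.HasProp("_Name") else "unnamed")
    return LigandConformer(name, symbols, coords, bonds, charges)


def read_sdf_conformers(path: str | Path) -> list[LigandConformer]:
    """All molecules of an SDF file as conformers (3D coordinates kept)."""
    from rdkit import Chem

    out = []
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise ValueError(f"unreadable SDF record #{i} in {path}")
        out.append(_rdkit_to_conformer(mol))
    return out


def write_sdf_conformers(conformers: Sequence[LigandConformer],
                         path: str | Path) -> None:
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    try:
        for c in conformers:
            mol = c.to_rdkit()
            mol.SetProp("_Name", c.identifier)
            writer.write(mol)
    finally:
        writer.close()


def read_mol2_conformer(path: str | Path) -> LigandConformer:
    """Single-molecule MOL2 reader."""
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), removeHs=False)
    if mol is None:
        raise ValueError(f"unreadable MOL2 file: {path}")
    return _rdkit_to_conformer(mol, Path(path).stem)


def conformer_to_pose(c: LigandConformer, method_id: str) -> Pose:
    """Heavy-atom pose from a conformer (hydrogens dropped)."""
    heavy = c.heavy_indices
    remap = {old: new for new, old in enumerate(heavy)}
    bonds = tuple((remap[i], remap[j], o) for i, j, o in c.bonds
                  if i in remap and j in remap)
    return Pose(c.identifier, method_id, c.coords[heavy],
                tuple(c.symbols[i] for i in heavy), bonds)


def write_pose_sdf(poses: Sequence[Pose], path: str | Path) -> None:
    """One SDF file holding all ligand poses of one docking method."""
    confs = [LigandConformer(p.ligand_id, list(p.symbols), p.coords,
                             list(p.bonds)) for p in poses]
    write_sdf_conformers(confs, path)


def read_pose_dir(directory: str | Path) -> dict[str, list[Pose]]:
    """Read a directory of per-method SDF files into poses per ligand.

    Each ``<method>.sdf`` file contributes one pose per molecule; poses
    are matched to ligands by the molecule title.
    """
    directory = Path(directory)
    by_ligand: dict[str, list[Pose]] = {}
    files = sorted(directory.glob("*.sdf"))
    if not files:
        raise ValueError(f"no SDF files in {directory}")
    for f in files:
        method = f.stem
        for conf in read_sdf_conformers(f):
            by_ligand.setdefault(conf.identifier, []).append(
                conformer_to_pose(conf, method))
    return by_ligand


def pose_sets_from_dir(directory: str | Path) -> dict[str, PoseSet]:
    return {lid: PoseSet(lid, poses)
            for lid, poses in read_pose_dir(directory).items()}


# --- trajectories (multi-frame XYZ + JSON role sidecar) -------------------

def write_xyz_trajectory(t: TrajectoryRecord, path: str | Path,
                         symbols: Sequence[str] | None = None) -> None:
    """Multi-frame XYZ; element symbols default to carbon placeholders."""
    n_atoms = t.frames.shape[1]
    if symbols is None:
        symbols = ["C"] * n_atoms
    with open(path, "w") as fh:
        for k in range(t.n_frames):
            fh.write(f"{n_atoms}\nframe {k}\n")
            for s, (x, y, z) in zip(symbols, t.frames[k]):
                fh.write(f"{s} {x:.6f} {y:.6f} {z:.6f}\n")


def write_trajectory_labels(t: TrajectoryRecord, path: str | Path) -> None:
    labels = {
        "ligand_heavy": list(t.ligand_heavy),
        "ligand_acceptor": list(t.ligand_acceptor),
        "water_oxygen": t.water_oxygen if isinstance(t.water_oxygen, int)
        else list(t.water_oxygen),
        "tyr_oxygen": int(t.tyr_oxygen),
        "water_hydrogens": list(t.water_hydrogens),
        "alpha_carbons": list(t.alpha_carbons),
        "frame_interval_ns": t.frame_interval_ns,
    }
    Path(path).write_text(json.dumps(labels, indent=1))


def read_xyz_trajectory(path: str | Path,
                        labels_path: str | Path) -> TrajectoryRecord:
    """Load a multi-frame XYZ trajectory plus its atom-role sidecar."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # XYZ has no topology information
        u = mda.Universe(str(path), format="XYZ")
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
    labels = json.loads(Path(labels_path).read_text())
    return TrajectoryRecord(
        frames=frames,
        ligand_heavy=labels["ligand_heavy"],
        ligand_acceptor=labels["ligand_acceptor"],
        water_oxygen=labels["water_oxygen"],
        tyr_oxygen=labels["tyr_oxygen"],
        water_hydrogens=labels.get("water_hydrogens", ()),
        alpha_carbons=labels.get("alpha_carbons", ()),
        frame_interval_ns=labels.get("frame_interval_ns"),
    )


# --- spectra (two-column CSV/TSV) -----------------------------------------

def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Two-column table: wavelength (nm), absorbance. Separator sniffed."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"spectrum file {path} needs two columns")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelengths,
                  "absorbance": s.absorbance}).to_csv(path, index=False)


def read_assay_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV with columns: condition, dark, light (file paths,
    relative to the manifest's directory unless absolute)."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "dark", "light"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    base = Path(path).parent
    for col in ("dark", "light"):
        df[col] = [str(p) if Path(p).is_absolute() else str(base / p)
                   for p in df[col]]
    return df
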