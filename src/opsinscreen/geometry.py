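"""Rigid-body geometry helpers shared across the screening modules.

All coordinates are in Angstrom, in whatever frame the caller defines
(for docking poses this is the common receptor frame).
"""

from __future__ import annotations

import numpy as np


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``P`` onto ``Q``.

    Returns ``(R, t, rmsd)`` such that ``P @ R.T + t`` minimizes the RMSD
    to ``Q`` over proper rotations (no reflection) and translations.

    Parameters
    ----------
    P, Q : (n, 3) arrays of paired points, n >= 1.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def apply_rigid(R: np.ndarray, t: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Apply the rigid transform ``x -> R x + t`` to rows of ``X``."""
    return np.asarray(X, dtype=float) @ np.asarray(R).T + np.asarray(t)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix (QR of a Gaussian matrix)."""
    A = rng.normal(size=(3, 3))
    Q, Rm = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(Rm)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def random_rigid(rng: np.random.Generator, max_translation: float = 10.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Random rigid transform: uniform rotation plus a bounded translation."""
    R = random_rotation(rng)
    t = rng.uniform(-max_translation, max_translation, size=3)
    return R, t


def in_place_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """RMSD of paired coordinates with no re-superposition."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("coordinate arrays must have identical shapes")
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))
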