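"""Coordinate-level math for backbones.

Local reference frames, frame projections, torsion angles, optimal rigid
superposition (Kabsch) RMSD, radius of gyration and CA distance maps.
Angles are degrees in the public API.

The local frame attached to a bonded triple (A, B, C) has its origin at B,
its z-axis along the normal of the A-B-C plane (AB x BC), its x-axis along
the B->C bond and y completing the right-handed set.  This is the standard
Gram-Schmidt-style construction used by frame-based structure losses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import BackboneConformation

__all__ = [
    "LocalFrame",
    "local_frame",
    "project_to_frame",
    "unproject_from_frame",
    "residue_frames",
    "dihedral",
    "backbone_dihedrals",
    "kabsch_rmsd",
    "radius_of_gyration",
    "ca_distance_map",
]

_COLLINEAR_TOL = 1e-10


class DegenerateGeometryError(ValueError):
    """Raised when points are collinear/coincident where a frame or torsion needs them not to be."""


@dataclass(frozen=True)
class LocalFrame:
    """Origin plus right-handed orthonormal axes (rows: n_x, n_y, n_z)."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=np.float64))


def local_frame(a, b, c) -> LocalFrame:
    """Build the local frame of center atom ``b`` with bonded partners ``a`` and ``c``."""
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    ab = b - a
    bc = c - b
    normal = np.cross(ab, bc)
    norm = np.linalg.norm(normal)
    if norm < _COLLINEAR_TOL or np.linalg.norm(bc) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("collinear or coincident atoms: frame undefined")
    n_z = normal / norm
    n_x = bc / np.linalg.norm(bc)
    n_y = np.cross(n_z, n_x)
    return LocalFrame(origin=b, axes=np.stack([n_x, n_y, n_z]))


def project_to_frame(frame: LocalFrame, point) -> np.ndarray:
    """Coordinates of ``point`` expressed in ``frame`` (axes @ (p - origin))."""
    return frame.axes @ (np.asarray(point, dtype=np.float64) - frame.origin)


def unproject_from_frame(frame: LocalFrame, local) -> np.ndarray:
    """Inverse of :func:`project_to_frame`."""
    return frame.axes.T @ np.asarray(local, dtype=np.float64) + frame.origin


def residue_frames(conf: BackboneConformation) -> list[LocalFrame]:
    """Per-residue frames built from (N_i, CA_i, C_i); origin at CA_i."""
    frames = []
    for r in range(conf.n_residues):
        n, ca, c = conf.coords[r]
        try:
            frames.append(local_frame(n, ca, c))
        except DegenerateGeometryError as err:
            raise DegenerateGeometryError(f"residue {r}: {err}") from None
    return frames


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle about the p2-p3 axis, degrees in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("three consecutive points are collinear")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if angle == -180.0 else float(angle)


def backbone_dihedrals(conf: BackboneConformation) -> dict[str, np.ndarray]:
    """phi (residues 2..L), psi (1..L-1) and omega (1..L-1) in degrees.

    phi_i  = (C_{i-1}, N_i, CA_i, C_i)
    psi_i  = (N_i, CA_i, C_i, N_{i+1})
    omega_i = (CA_i, C_i, N_{i+1}, CA_{i+1})
    """
    L = conf.n_residues
    X = conf.coords  # (L, 3(N,CA,C), 3)
    phi, psi, omega = [], [], []
    try:
        for i in range(1, L):
            phi.append(dihedral(X[i - 1, 2], X[i, 0], X[i, 1], X[i, 2]))
        for i in range(L - 1):
            psi.append(dihedral(X[i, 0], X[i, 1], X[i, 2], X[i + 1, 0]))
            omega.append(dihedral(X[i, 1], X[i, 2], X[i + 1, 0], X[i + 1, 1]))
    except DegenerateGeometryError as err:
        raise DegenerateGeometryError(f"around residue {i}: {err}") from None
    return {
        "phi": np.asarray(phi),
        "psi": np.asarray(psi),
        "omega": np.asarray(omega),
    }


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD between paired point sets over proper rigid motions.

    Rotation + translation only; reflections are excluded (the molecules
    are chiral).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"point sets must share shape (n, 3); got {x.shape} vs {y.shape}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points for a rigid superposition")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    # align_vectors finds the proper rotation minimizing |R yc - xc|^2 (Kabsch)
    rot, _ = Rotation.align_vectors(xc, yc)
    diff = xc - rot.apply(yc)
    return float(np.sqrt((diff**2).sum() / x.shape[0]))


def radius_of_gyration(conf: BackboneConformation | np.ndarray) -> float:
    """Unweighted RMS distance of all 3L backbone atoms from their centroid, Å.

    Also accepts a bare (n, 3) point array, which is convenient in tests
    and for partial chains.
    """
    atoms = conf.atoms() if isinstance(conf, BackboneConformation) else np.asarray(conf, dtype=np.float64)
    centered = atoms - atoms.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def ca_distance_map(conf: BackboneConformation) -> np.ndarray:
    """L×L symmetric matrix of CA-CA Euclidean distances, zero diagonal."""
    ca = conf.coords[:, 1, :]
    diff = ca[:, None, :] - ca[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))
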