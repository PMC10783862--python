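"""Synthetic backbone ensembles with known statistical structure.

Real training data for this kind of model are conformations extracted from
long MD trajectories of a single protein.  This module emulates their
essential statistics at fixture scale: backbone torsions drawn from a
mixture of Ramachandran basins (wrapped-normal per basin), a near-planar
trans peptide bond, and fixed covalent geometry, turned into Cartesian
backbones by sequential natural-extension-reference-frame (NeRF) placement.

What this does NOT emulate: side chains, sterics/excluded volume beyond
what the basin choice implies, solvent effects, or temporal correlation
between frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .ensemble import BackboneConformation, Ensemble

__all__ = [
    "BasinSpec",
    "CovalentGeometry",
    "HELIX_BASIN",
    "EXTENDED_BASIN",
    "sample_dihedrals",
    "nerf_build",
    "make_ensemble",
]


@dataclass(frozen=True)
class BasinSpec:
    """One Ramachandran basin: circular means and SDs in degrees, and a mixture weight."""

    name: str
    phi_mean: float
    phi_sd: float
    psi_mean: float
    psi_sd: float
    weight: float = 1.0

    def __post_init__(self):
        if self.phi_sd <= 0 or self.psi_sd <= 0:
            raise ValueError("basin SDs must be positive")


# Canonical basins used as defaults throughout tests and worked examples.
HELIX_BASIN = BasinSpec("helix", phi_mean=-63.0, phi_sd=10.0, psi_mean=-43.0, psi_sd=10.0)
EXTENDED_BASIN = BasinSpec("extended", phi_mean=-120.0, phi_sd=15.0, psi_mean=135.0, psi_sd=15.0)


@dataclass(frozen=True)
class CovalentGeometry:
    """Fixed covalent backbone geometry (Engh–Huber-like standard values)."""

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    omega_mean: float = 180.0
    omega_sd: float = 5.0

    def __post_init__(self):
        if min(self.bond_n_ca, self.bond_ca_c, self.bond_c_n) <= 0:
            raise ValueError("bond lengths must be positive")
        for ang in (self.angle_n_ca_c, self.angle_ca_c_n, self.angle_c_n_ca):
            if not 0 < ang < 180:
                raise ValueError("bond angles must lie in (0, 180) degrees")


def _wrap_degrees(x: np.ndarray) -> np.ndarray:
    """Wrap angles into (-180, 180]."""
    wrapped = np.mod(x + 180.0, 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


def sample_dihedrals(
    basins: Sequence[BasinSpec],
    L: int,
    n: int,
    mode: Literal["per-conformation", "per-residue"] = "per-conformation",
    seed: int | None = None,
    geometry: CovalentGeometry = CovalentGeometry(),
):
    """Draw n×(L-1) phi/psi/omega tables from a basin mixture.

    ``per-conformation`` assigns one basin to each conformation (bimodal
    ensembles); ``per-residue`` draws a basin independently at every site
    (disordered ensembles).  Returns a dict with ``phi``/``psi``/``omega``
    arrays of shape (n, L-1) and the basin assignment used (shape (n,) or
    (n, L-1)).
    """
    weights = np.array([b.weight for b in basins], dtype=np.float64)
    if weights.sum() <= 0:
        raise ValueError("basin weights must sum to a positive value")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    shape = (n, L - 1)
    if mode == "per-conformation":
        assign = rng.choice(len(basins), size=n, p=weights)
        site_assign = np.repeat(assign[:, None], L - 1, axis=1)
    elif mode == "per-residue":
        assign = rng.choice(len(basins), size=shape, p=weights)
        site_assign = assign
    else:
        raise ValueError(f"unknown mode {mode!r}")

    phi_mean = np.array([b.phi_mean for b in basins])[site_assign]
    phi_sd = np.array([b.phi_sd for b in basins])[site_assign]
    psi_mean = np.array([b.psi_mean for b in basins])[site_assign]
    psi_sd = np.array([b.psi_sd for b in basins])[site_assign]

    phi = _wrap_degrees(rng.normal(phi_mean, phi_sd))
    psi = _wrap_degrees(rng.normal(psi_mean, psi_sd))
    omega = _wrap_degrees(rng.normal(geometry.omega_mean, geometry.omega_sd, size=shape))
    return {"phi": phi, "psi": psi, "omega": omega, "basin": assign}


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, angle(B,C,D) and torsion(A,B,C,D)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def nerf_build(
    dihedrals: dict,
    geometry: CovalentGeometry = CovalentGeometry(),
    L: int | None = None,
    sequence: str | None = None,
) -> BackboneConformation:
    """Build one backbone from (L-1)-long phi/psi/omega rows by NeRF placement.

    Bond lengths, bond angles and the given torsions are honored exactly:
    psi_i places N_{i+1}, omega_i places CA_{i+1}, phi_{i+1} places C_{i+1}.
    """
    phi = np.atleast_1d(np.asarray(dihedrals["phi"], dtype=np.float64))
    psi = np.atleast_1d(np.asarray(dihedrals["psi"], dtype=np.float64))
    omega = np.atleast_1d(np.asarray(dihedrals["omega"], dtype=np.float64))
    if not (len(phi) == len(psi) == len(omega)):
        raise ValueError("phi, psi, omega tables must have equal length L-1")
    if L is None:
        L = len(phi) + 1
    if len(phi) != L - 1:
        raise ValueError(f"expected {L - 1} torsion rows, got {len(phi)}")
    if sequence is None:
        sequence = "A" * L

    g = geometry
    coords = np.zeros((L, 3, 3))
    # seed residue 1 in a canonical pose: N at origin, CA on +x, C in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (g.bond_n_ca, 0.0, 0.0)
    ang = np.radians(g.angle_n_ca_c)
    coords[0, 2] = coords[0, 1] + g.bond_ca_c * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(L - 1):
        n_i, ca_i, c_i = coords[i]
        n_next = _place_atom(n_i, ca_i, c_i, g.bond_c_n, g.angle_ca_c_n, psi[i])
        ca_next = _place_atom(ca_i, c_i, n_next, g.bond_n_ca, g.angle_c_n_ca, omega[i])
        c_next = _place_atom(c_i, n_next, ca_next, g.bond_ca_c, g.angle_n_ca_c, phi[i])
        coords[i + 1] = (n_next, ca_next, c_next)
    return BackboneConformation(sequence, coords)


def _place_atoms_batch(a, b, c, bond, angle_deg, torsion_deg):
    """Vectorized NeRF placement over a batch: all arrays (n, 3) / (n,)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc, axis=1, keepdims=True)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n, axis=1, keepdims=True)
    m_hat = np.cross(n_hat, bc_hat)
    st = np.sin(theta)
    comp = np.stack(
        [np.full_like(chi, -np.cos(theta)), st * np.cos(chi), st * np.sin(chi)],
        axis=1,
    )
    return c + bond * (
        comp[:, :1] * bc_hat + comp[:, 1:2] * m_hat + comp[:, 2:3] * n_hat
    )


def nerf_build_batch(tables: dict, geometry: CovalentGeometry, L: int) -> np.ndarray:
    """Build all conformations of an ensemble at once: (n, L, 3, 3) coordinates.

    Same placement rule as :func:`nerf_build`, vectorized across the n
    conformations (the chain itself is inherently sequential).
    """
    phi = np.atleast_2d(tables["phi"])
    psi = np.atleast_2d(tables["psi"])
    omega = np.atleast_2d(tables["omega"])
    n = phi.shape[0]
    g = geometry
    coords = np.zeros((n, L, 3, 3))
    coords[:, 0, 1] = (g.bond_n_ca, 0.0, 0.0)
    ang = np.radians(g.angle_n_ca_c)
    coords[:, 0, 2] = coords[:, 0, 1] + g.bond_ca_c * np.array(
        [-np.cos(ang), np.sin(ang), 0.0]
    )
    for i in range(L - 1):
        n_i, ca_i, c_i = coords[:, i, 0], coords[:, i, 1], coords[:, i, 2]
        n_next = _place_atoms_batch(n_i, ca_i, c_i, g.bond_c_n, g.angle_ca_c_n, psi[:, i])
        ca_next = _place_atoms_batch(ca_i, c_i, n_next, g.bond_n_ca, g.angle_c_n_ca, omega[:, i])
        c_next = _place_atoms_batch(c_i, n_next, ca_next, g.bond_ca_c, g.angle_n_ca_c, phi[:, i])
        coords[:, i + 1, 0] = n_next
        coords[:, i + 1, 1] = ca_next
        coords[:, i + 1, 2] = c_next
    return coords


def make_ensemble(
    basins: Sequence[BasinSpec] = (HELIX_BASIN,),
    L: int = 6,
    n: int = 32,
    sequence: str | None = None,
    mode: Literal["per-conformation", "per-residue"] = "per-conformation",
    geometry: CovalentGeometry = CovalentGeometry(),
    seed: int | None = None,
    label: str = "synthetic",
) -> Ensemble:
    """Sample dihedrals from the basin mixture and build the full ensemble."""
    if sequence is not None and len(sequence) != L:
        raise ValueError("sequence length must equal L")
    tables = sample_dihedrals(basins, L=L, n=n, mode=mode, seed=seed, geometry=geometry)
    coords = nerf_build_batch(tables, geometry, L)
    seq = sequence if sequence is not None else "A" * L
    confs = [BackboneConformation(seq, coords[i]) for i in range(n)]
    return Ensemble(confs, label=label)
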