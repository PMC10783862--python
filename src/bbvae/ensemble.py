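"""In-memory containers for backbone conformations and ensembles.

A :class:`BackboneConformation` stores, for a chain of ``L`` residues, the
one-letter sequence and an ``(L, 3, 3)`` coordinate array whose middle axis
is ordered (N, CA, C).  An :class:`Ensemble` is an ordered collection of
conformations of one identical sequence — a training set, a generated set,
or an interpolation path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, List, Sequence

import numpy as np

STANDARD_AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass(frozen=True)
class BackboneConformation:
    """One structure's backbone: sequence plus (L, 3, 3) N/CA/C coordinates in Å."""

    sequence: str
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.float64)
        object.__setattr__(self, "coords", coords)
        L = len(self.sequence)
        if L < 2:
            raise ValueError("a conformation needs at least 2 residues")
        bad = set(self.sequence) - set(STANDARD_AA1)
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")
        if coords.shape != (L, 3, 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match (L={L}, 3, 3)"
            )
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        for r in range(L):
            a, b, c = coords[r]
            if (a == b).all() or (b == c).all() or (a == c).all():
                raise ValueError(f"residue {r}: backbone atoms are not distinct points")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def atoms(self) -> np.ndarray:
        """All backbone atoms as a flat (3L, 3) array in chain order."""
        return self.coords.reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BackboneConformation":
        """Apply a rigid transform x -> R x + t to every atom."""
        moved = self.atoms() @ np.asarray(rotation).T + np.asarray(translation)
        return BackboneConformation(self.sequence, moved.reshape(self.coords.shape))


@dataclass
class Ensemble:
    """Ordered collection of conformations sharing one sequence."""

    conformations: List[BackboneConformation]
    label: str = ""

    def __post_init__(self):
        if not self.conformations:
            raise ValueError("an ensemble must contain at least one conformation")
        seq = self.conformations[0].sequence
        for i, conf in enumerate(self.conformations):
            if conf.sequence != seq:
                raise ValueError(
                    f"conformation {i} sequence differs from the ensemble sequence"
                )

    @property
    def sequence(self) -> str:
        return self.conformations[0].sequence

    @property
    def n_residues(self) -> int:
        return self.conformations[0].n_residues

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self) -> Iterator[BackboneConformation]:
        return iter(self.conformations)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Ensemble(self.conformations[i], label=self.label)
        return self.conformations[i]

    def coords_array(self) -> np.ndarray:
        """Stack all members into an (n, L, 3, 3) array."""
        return np.stack([c.coords for c in self.conformations])

    def subset(self, indices: Sequence[int], label: str | None = None) -> "Ensemble":
        return Ensemble(
            [self.conformations[i] for i in indices],
            label=self.label if label is None else label,
        )
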