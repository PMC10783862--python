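"""Multi-model PDB reading and writing for backbone ensembles.

The interchange format is PDB v3.3 with one MODEL/ENDMDL block per
conformation.  Only backbone ATOM records (N, CA, C) of the 20 standard
amino acids are kept on read; waters, HETATM records and side-chain atoms
are dropped silently.  Files are assumed single-chain; insertion codes are
rejected.
"""

from __future__ import annotations

import os

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .ensemble import (
    AA1_TO_AA3,
    AA3_TO_AA1,
    BACKBONE_ATOMS,
    BackboneConformation,
    Ensemble,
)

__all__ = ["read_multimodel_pdb", "write_multimodel_pdb"]


def _conformation_from_model(atoms: struc.AtomArray, model_number: int) -> BackboneConformation:
    """Validate one model's atom array and pull out the (L, 3, 3) backbone."""
    atoms = atoms[~atoms.hetero]
    if "ins_code" in atoms.get_annotation_categories():
        if np.any(atoms.ins_code != ""):
            raise ValueError(
                f"model {model_number}: insertion codes are not supported"
            )
    keep = np.isin(atoms.atom_name, BACKBONE_ATOMS) & np.isin(
        atoms.res_name, list(AA3_TO_AA1)
    )
    atoms = atoms[keep]
    if atoms.array_length() == 0:
        raise ValueError(f"model {model_number}: no standard backbone atoms found")
    if len(np.unique(atoms.chain_id)) > 1:
        raise ValueError(
            f"model {model_number}: multiple chains found; single-chain files only"
        )

    # residues in record order
    res_starts = struc.get_residue_starts(atoms)
    sequence = []
    coords = []
    bounds = list(res_starts) + [atoms.array_length()]
    for r, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        res = atoms[lo:hi]
        res_coords = np.empty((3, 3))
        for a, name in enumerate(BACKBONE_ATOMS):
            hit = res[res.atom_name == name]
            if hit.array_length() != 1:
                raise ValueError(
                    f"model {model_number}, residue {r + 1} "
                    f"({res.res_name[0]} {res.res_id[0]}): missing backbone atom {name}"
                )
            res_coords[a] = hit.coord[0]
        sequence.append(AA3_TO_AA1[res.res_name[0]])
        coords.append(res_coords)
    return BackboneConformation("".join(sequence), np.asarray(coords))


def read_multimodel_pdb(path: str | os.PathLike, label: str | None = None) -> Ensemble:
    """Read a (multi-)model PDB file into an :class:`Ensemble`.

    One conformation is returned per MODEL, in file order.  Every residue
    must carry N, CA and C records; a missing atom raises an error naming
    the model and residue.  All models must share one sequence.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise ValueError(f"{path}: no structure models found")
    conformations = []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        conf = _conformation_from_model(atoms, m)
        if conformations and conf.sequence != conformations[0].sequence:
            raise ValueError(
                f"model {m}: sequence differs from model 1 "
                f"({conf.sequence!r} vs {conformations[0].sequence!r})"
            )
        conformations.append(conf)
    return Ensemble(conformations, label=label if label is not None else str(path))


def write_multimodel_pdb(ensemble: Ensemble, path: str | os.PathLike) -> None:
    """Write an ensemble as a PDB v3.3 multi-model file.

    Fixed-column ATOM records, atoms serial-numbered from 1 within each
    MODEL/ENDMDL block, occupancy 1.00 and B-factor 0.00.
    """
    L = ensemble.n_residues
    m = 3 * L
    template = struc.AtomArray(m)
    template.chain_id = np.full(m, "A")
    template.res_id = np.repeat(np.arange(1, L + 1), 3)
    template.res_name = np.repeat(
        [AA1_TO_AA3[aa] for aa in ensemble.sequence], 3
    )
    template.atom_name = np.tile(BACKBONE_ATOMS, L)
    template.element = np.tile(["N", "C", "C"], L)
    template.hetero = np.zeros(m, dtype=bool)

    arrays = []
    for conf in ensemble:
        arr = template.copy()
        arr.coord = conf.atoms()
        arrays.append(arr)
    stack = struc.stack(arrays)
    out = PDBFile()
    out.set_structure(stack)
    if len(arrays) == 1:
        # keep the MODEL/ENDMDL framing even for a single conformation
        out.lines = ["MODEL        1", *out.lines, "ENDMDL"]
    out.write(str(path))
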