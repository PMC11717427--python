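"""Loading predicted dimer models from PDB/mmCIF + JSON sidecars.

Score files follow a minimal flat schema:
``{"iptm": float, "ptm": float, "version": "AF2"|"AF3",
"disorder_frac": float?}``. PAE files carry one square matrix under ``pae``
or ``predicted_aligned_error`` (the bare matrix and the AF2 list-of-dicts
layout are also accepted).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure

from metascreen.triage.models import ChainModel, DimerModel, ModelScore, PAEMatrix


def _read_structure(path: Path) -> struc.AtomArray:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        atoms = PDBFile.read(str(path)).get_structure(
            model=1, extra_fields=["b_factor"]
        )
    elif suffix in (".cif", ".mmcif", ".pdbx"):
        atoms = get_structure(
            CIFFile.read(str(path)), model=1, extra_fields=["b_factor"]
        )
    else:
        raise ValueError(f"unknown coordinate format {suffix!r} for {path}")
    return atoms[struc.filter_amino_acids(atoms)]


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"


def _chain_from_atoms(atoms: struc.AtomArray, chain_id: str) -> ChainModel:
    chain = atoms[atoms.chain_id == chain_id]
    ca = chain[chain.atom_name == "CA"]
    if len(ca) == 0:
        raise ValueError(f"chain {chain_id} has no Ca atoms")
    # renumber residues 1..L per chain, in order of appearance
    res_ids = ca.res_id
    renumber = {int(r): i + 1 for i, r in enumerate(res_ids)}
    sequence = "".join(_three_to_one(rn) for rn in ca.res_name)
    atom_res = np.array([renumber.get(int(r), 0) for r in chain.res_id])
    keep = atom_res > 0
    return ChainModel(
        chain_id=str(chain_id),
        sequence=sequence,
        ca_coords=ca.coord.astype(float),
        plddt=(
            ca.b_factor.astype(float)
            if "b_factor" in ca.get_annotation_categories()
            else np.zeros(len(ca))
        ),
        atom_coords=chain.coord[keep].astype(float),
        atom_elements=[str(e) for e in chain.element[keep]],
        atom_res_ids=atom_res[keep],
    )


def read_pae(path: str | Path, len_a: int, len_b: int) -> PAEMatrix:
    """Parse a PAE JSON file into a validated matrix."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, list) and data and isinstance(data[0], dict):
        data = data[0]  # AF2 pickle-to-JSON layout: [{"predicted_aligned_error": ...}]
    if isinstance(data, dict):
        for key in ("pae", "predicted_aligned_error"):
            if key in data:
                data = data[key]
                break
        else:
            raise ValueError(f"no PAE matrix found in {path}")
    values = np.asarray(data, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"PAE in {path} is not a square matrix: {values.shape}")
    if values.shape[0] != len_a + len_b:
        raise ValueError(
            f"PAE dimension {values.shape[0]} does not equal total residue "
            f"count {len_a + len_b}"
        )
    return PAEMatrix(values=values, len_a=len_a, len_b=len_b)


def read_scores(path: str | Path) -> ModelScore:
    data = json.loads(Path(path).read_text())
    version = str(data.get("version", "AF2")).upper().replace("-LIKE", "")
    return ModelScore(
        iptm=float(data["iptm"]),
        ptm=float(data["ptm"]),
        version=version,  # type: ignore[arg-type]
        disorder_frac=(
            float(data["disorder_frac"]) if data.get("disorder_frac") is not None
            else None
        ),
    )


def load_model(
    coords: str | Path, pae: str | Path, scores: str | Path
) -> DimerModel:
    """Load a two-chain model with its PAE matrix and ranking metadata.

    Residues are renumbered 1..L per chain; the PAE matrix is ordered chain A
    residues first, then chain B.
    """
    atoms = _read_structure(Path(coords))
    chain_ids = list(dict.fromkeys(atoms.chain_id))
    if len(chain_ids) != 2:
        raise ValueError(
            f"expected exactly 2 chains, found {len(chain_ids)}: {chain_ids}"
        )
    chain_a = _chain_from_atoms(atoms, chain_ids[0])
    chain_b = _chain_from_atoms(atoms, chain_ids[1])
    pae_matrix = read_pae(pae, len(chain_a), len(chain_b))
    score = read_scores(scores)
    return DimerModel(chain_a=chain_a, chain_b=chain_b, pae=pae_matrix, score=score)
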