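"""Domain types for predicted-dimer triage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

Version = Literal["AF2", "AF3"]

# Van der Waals radii by element (A); unlisted elements fall back to carbon.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_RADIUS = 1.70


@dataclass
class ChainModel:
    """One chain: sequence, Ca trace, per-residue confidence, optional atoms."""

    chain_id: str
    sequence: str
    ca_coords: np.ndarray  # (L, 3) in Angstrom
    plddt: np.ndarray  # (L,) in [0, 100]
    atom_coords: np.ndarray | None = None  # (n_atoms, 3)
    atom_elements: list[str] | None = None
    atom_res_ids: np.ndarray | None = None  # 1-based residue index per atom

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        L = len(self.sequence)
        if self.ca_coords.shape != (L, 3):
            raise ValueError(
                f"chain {self.chain_id}: {L} residues but Ca coords of "
                f"shape {self.ca_coords.shape}"
            )
        if self.plddt.shape != (L,):
            raise ValueError(f"chain {self.chain_id}: pLDDT length mismatch")
        if not np.isfinite(self.ca_coords).all():
            raise ValueError(f"chain {self.chain_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.sequence)

    def atoms_of_residues(self, residues) -> tuple[np.ndarray, np.ndarray]:
        """(coords, radii) of all atoms belonging to the 1-based residue ids."""
        if self.atom_coords is None or self.atom_res_ids is None:
            raise ValueError(f"chain {self.chain_id} carries no atom records")
        residues = sorted(set(int(r) for r in residues))
        mask = np.isin(self.atom_res_ids, residues)
        present = set(self.atom_res_ids[mask].tolist())
        missing = [r for r in residues if r not in present]
        if missing:
            raise ValueError(
                f"chain {self.chain_id}: no atoms for residue(s) {missing}"
            )
        radii = np.array(
            [
                VDW_RADII.get(self.atom_elements[i].upper(), DEFAULT_RADIUS)
                for i in np.flatnonzero(mask)
            ]
        )
        return self.atom_coords[mask], radii


@dataclass
class PAEMatrix:
    """L x L predicted aligned error (A); rows/cols ordered chain A then B."""

    values: np.ndarray
    len_a: int
    len_b: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L = self.len_a + self.len_b
        if self.values.shape != (L, L):
            raise ValueError(
                f"PAE shape {self.values.shape} does not match total residue "
                f"count {L}"
            )
        if (self.values < 0).any():
            raise ValueError("PAE values must be nonnegative")

    def inter_blocks(self) -> tuple[np.ndarray, np.ndarray]:
        """(PAE[a, b], PAE[b, a]) blocks, both shaped (len_a, len_b)."""
        a, b = self.len_a, self.len_b
        return self.values[:a, a:], self.values[a:, :a].T


@dataclass
class ModelScore:
    """Confidence metadata of one predicted model."""

    iptm: float
    ptm: float
    version: Version = "AF2"
    disorder_frac: float | None = None

    def __post_init__(self) -> None:
        for name in ("iptm", "ptm"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.version not in ("AF2", "AF3"):
            raise ValueError(f"version must be 'AF2' or 'AF3', got {self.version!r}")
        if self.version == "AF3" and self.disorder_frac is None:
            raise ValueError("AF3 scores require disorder_frac")
        if self.disorder_frac is not None and not (0.0 <= self.disorder_frac <= 1.0):
            raise ValueError("disorder_frac must be in [0, 1]")


def ranking_score(s: ModelScore) -> float:
    """0.8*ipTM + 0.2*pTM, plus 0.5*disorder for AF3-style models."""
    base = 0.8 * s.iptm + 0.2 * s.ptm
    if s.version == "AF3":
        assert s.disorder_frac is not None
        base += 0.5 * s.disorder_frac
    return base


@dataclass
class DimerModel:
    """A loaded two-chain model with its PAE matrix and score metadata."""

    chain_a: ChainModel
    chain_b: ChainModel
    pae: PAEMatrix
    score: ModelScore

    def __post_init__(self) -> None:
        if self.pae.len_a != len(self.chain_a) or self.pae.len_b != len(self.chain_b):
            raise ValueError(
                f"PAE chain splits ({self.pae.len_a}, {self.pae.len_b}) do not "
                f"match chain lengths ({len(self.chain_a)}, {len(self.chain_b)})"
            )

    @property
    def ranking(self) -> float:
        return ranking_score(self.score)


@dataclass(frozen=True, order=True)
class ContactPair:
    """One inter-chain residue pair passing the distance + PAE constraints."""

    res_a: int  # 1-based in chain A (bait)
    res_b: int  # 1-based in chain B (prey)
    ca_distance: float
    pae_ab: float
    pae_ba: float


@dataclass
class InteractionCall:
    """Verdicts for one bait-prey pair under both criteria generations."""

    pair_id: tuple[str, str]
    pairs: frozenset[ContactPair]
    n_bait: int
    n_prey: int
    ranking: float
    area_norm: float = 0.0
    passes_v1: bool = False
    passes_v2: bool = False

    @property
    def bait_residues(self) -> frozenset[int]:
        return frozenset(p.res_a for p in self.pairs)

    @property
    def prey_residues(self) -> frozenset[int]:
        return frozenset(p.res_b for p in self.pairs)
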