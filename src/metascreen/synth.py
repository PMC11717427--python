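"""Seeded generators for corpora, dimer fixtures and nucleotide sequences.

All generators are deterministic under their seed and write machine-readable
ground-truth sidecars, so every downstream stage can be exercised offline
against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

from metascreen.ingest import GeneList
from metascreen.orfscan import six_frame_longest
from metascreen.triage.models import (
    ChainModel,
    DimerModel,
    ModelScore,
    PAEMatrix,
    ranking_score,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CA_SPACING = 3.8


# ---------------------------------------------------------------------------
# gene-list corpora with planted co-occurring blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """A planted set of co-occurring genes."""

    n_genes: int
    n_lists: int  # number of lists the block is planted into
    co_prob: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.co_prob <= 1.0):
            raise ValueError("co_prob must be in [0, 1]")


@dataclass
class ListCorpusSpec:
    n_genes: int = 20000
    n_lists: int = 100
    size_min: int = 10
    size_max: int = 2000
    blocks: list[BlockSpec] = field(default_factory=list)
    background_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.size_min <= self.size_max <= self.n_genes):
            raise ValueError("need 1 <= size_min <= size_max <= n_genes")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValueError("background_rate must be in [0, 1]")
        if sum(b.n_genes for b in self.blocks) > self.n_genes:
            raise ValueError("blocks exceed the gene universe")
        for b in self.blocks:
            if b.n_genes > self.size_max:
                raise ValueError(
                    f"block of {b.n_genes} genes cannot fit in any list "
                    f"(max size {self.size_max})"
                )
            if b.n_lists > self.n_lists:
                raise ValueError("block planted into more lists than exist")


def gen_list_corpus(spec: ListCorpusSpec) -> tuple[list[GeneList], dict]:
    """Generate lists with planted co-occurring blocks over a gene universe.

    Block genes co-occur (each with probability ``co_prob``) within the
    block's designated lists; remaining capacity up to each list's sampled
    size is filled with uniform background genes, scaled by
    ``background_rate`` (0 means lists contain only planted genes).
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    cursor = 0
    block_genes: list[list[str]] = []
    for b in spec.blocks:
        block_genes.append(genes[cursor: cursor + b.n_genes])
        cursor += b.n_genes
    background = genes[cursor:]
    block_lists = [
        sorted(rng.choice(spec.n_lists, size=b.n_lists, replace=False).tolist())
        for b in spec.blocks
    ]
    sizes = np.exp(
        rng.uniform(np.log(spec.size_min), np.log(spec.size_max), size=spec.n_lists)
    ).round().astype(int)
    lists = []
    for i in range(spec.n_lists):
        members: set[str] = set()
        for b, bg, bl in zip(spec.blocks, block_genes, block_lists):
            if i in bl:
                mask = rng.random(len(bg)) < b.co_prob
                members.update(g for g, keep in zip(bg, mask) if keep)
        want = max(0, int(sizes[i]) - len(members))
        n_fill = int(round(want * spec.background_rate))
        n_fill = min(n_fill, len(background))
        if n_fill:
            fill = rng.choice(len(background), size=n_fill, replace=False)
            members.update(background[k] for k in fill)
        lists.append(
            GeneList(
                list_id=f"L{i:04d}",
                source_id="synthetic_corpus",
                category="other",
                genes=frozenset(members),
            )
        )
    truth = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "n_lists": spec.n_lists,
        "blocks": [
            {"genes": bg, "lists": bl, "co_prob": b.co_prob}
            for b, bg, bl in zip(spec.blocks, block_genes, block_lists)
        ],
        "n_background_genes": len(background),
    }
    return lists, truth


# ---------------------------------------------------------------------------
# dimer fixtures with planted contacts
# ---------------------------------------------------------------------------


@dataclass
class DimerFixtureSpec:
    len_a: int = 50
    len_b: int = 40
    pairs: list[tuple[int, int]] | None = None  # explicit 1-based (bait, prey)
    n_pairs: int = 0  # diagonal 1:1 contacts when pairs is None
    n_bait: int | None = None  # alternative: plant given residue counts
    n_prey: int | None = None
    contact_height: float = 4.0  # A between paired residues (< 6 with offsets)
    noncontact_sep: float = 20.0  # baseline inter-chain separation (>= 12)
    pae_signal: float = 3.0  # < 5
    pae_noise: float = 20.0  # >= 8
    iptm: float = 0.8
    ptm: float = 0.7
    version: str = "AF2"
    disorder_frac: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noncontact_sep < 12.0:
            raise ValueError("noncontact_sep must be >= 12 A")
        if not (self.pae_signal < 5.0 <= self.pae_noise):
            raise ValueError("need pae_signal < 5 and pae_noise >= 8 (got outside)")

    def planted_pairs(self) -> list[tuple[int, int]]:
        """Resolve the planted 1-based (bait, prey) pair list."""
        if self.pairs is not None:
            return sorted(set((int(a), int(b)) for a, b in self.pairs))
        if self.n_bait is not None or self.n_prey is not None:
            nb = self.n_bait or 1
            np_ = self.n_prey or 1
            if np_ < nb:
                raise ValueError("n_prey must be >= n_bait for this layout")
            baits = list(range(1, 1 + 3 * nb, 3))  # spaced to avoid crowding
            return sorted((baits[k % nb], k + 1) for k in range(np_))
        return [(k + 1, k + 1) for k in range(self.n_pairs)]


def _build_dimer(spec: DimerFixtureSpec) -> tuple[DimerModel, list[tuple[int, int]]]:
    rng = np.random.default_rng(spec.seed)
    pairs = spec.planted_pairs()
    for a, b in pairs:
        if not (1 <= a <= spec.len_a and 1 <= b <= spec.len_b):
            raise ValueError(f"planted pair {(a, b)} outside chain lengths")
    # a z-wiggle keeps the traces non-collinear so rigid fits are well-posed;
    # inter-chain separation is carried by the y axis and is unaffected
    coords_a = np.column_stack(
        (
            _CA_SPACING * np.arange(spec.len_a),
            np.zeros(spec.len_a),
            2.0 * np.sin(0.7 * np.arange(spec.len_a)),
        )
    )
    coords_b = np.column_stack(
        (
            _CA_SPACING * np.arange(spec.len_b),
            np.full(spec.len_b, spec.noncontact_sep),
            2.0 * np.cos(0.7 * np.arange(spec.len_b)),
        )
    )
    # relocate each contact prey residue next to (the centroid of) its baits
    by_prey: dict[int, list[int]] = {}
    for a, b in pairs:
        by_prey.setdefault(b, []).append(a)
    by_bait_order: dict[int, int] = {}
    reach = np.sqrt(6.0**2 - spec.contact_height**2) - 1e-6
    for prey, baits in sorted(by_prey.items()):
        center = np.mean([coords_a[a - 1] for a in baits], axis=0)
        slot = by_bait_order.get(min(baits), 0)
        by_bait_order[min(baits)] = slot + 1
        dx = ((slot + 1) // 2) * 1.0 * (1 if slot % 2 else -1)
        pos = center + np.array([dx, spec.contact_height, 0.0])
        for a in baits:
            if np.linalg.norm(pos - coords_a[a - 1]) >= 6.0:
                raise ValueError(
                    f"cannot satisfy contact geometry for prey {prey} "
                    f"(baits {baits} too spread out)"
                )
        coords_b[prey - 1] = pos
    seq_a = "".join(rng.choice(list(AMINO_ACIDS), size=spec.len_a))
    seq_b = "".join(rng.choice(list(AMINO_ACIDS), size=spec.len_b))
    plddt_a = rng.uniform(70, 95, size=spec.len_a).round(2)
    plddt_b = rng.uniform(70, 95, size=spec.len_b).round(2)
    chain_a = ChainModel(
        chain_id="A",
        sequence=seq_a,
        ca_coords=coords_a,
        plddt=plddt_a,
        atom_coords=coords_a.copy(),
        atom_elements=["C"] * spec.len_a,
        atom_res_ids=np.arange(1, spec.len_a + 1),
    )
    chain_b = ChainModel(
        chain_id="B",
        sequence=seq_b,
        ca_coords=coords_b,
        plddt=plddt_b,
        atom_coords=coords_b.copy(),
        atom_elements=["C"] * spec.len_b,
        atom_res_ids=np.arange(1, spec.len_b + 1),
    )
    L = spec.len_a + spec.len_b
    pae = np.full((L, L), spec.pae_noise, dtype=float)
    np.fill_diagonal(pae, 0.5)
    for a, b in pairs:
        pae[a - 1, spec.len_a + b - 1] = spec.pae_signal
        pae[spec.len_a + b - 1, a - 1] = spec.pae_signal
    score = ModelScore(
        iptm=spec.iptm,
        ptm=spec.ptm,
        version=spec.version,  # type: ignore[arg-type]
        disorder_frac=spec.disorder_frac,
    )
    model = DimerModel(
        chain_a=chain_a,
        chain_b=chain_b,
        pae=PAEMatrix(values=pae, len_a=spec.len_a, len_b=spec.len_b),
        score=score,
    )
    # self-check: the declared geometry must hold after generation
    for a, b in pairs:
        d = float(np.linalg.norm(coords_a[a - 1] - coords_b[b - 1]))
        if d >= 6.0:
            raise ValueError(f"generated pair {(a, b)} at {d:.2f} A (>= 6)")
    contact_preys = set(by_prey)
    for j in range(1, spec.len_b + 1):
        if j in contact_preys:
            continue
        d_min = float(np.linalg.norm(coords_a - coords_b[j - 1], axis=1).min())
        if d_min < 12.0:
            raise ValueError(f"non-contact prey residue {j} at {d_min:.2f} A (< 12)")
    return model, pairs


def _chains_to_atom_array(model: DimerModel) -> struc.AtomArray:
    chains = [model.chain_a, model.chain_b]
    total = sum(len(c) for c in chains)
    atoms = struc.AtomArray(total)
    atoms.add_annotation("b_factor", dtype=float)
    idx = 0
    for chain in chains:
        for i, (aa, coord, plddt) in enumerate(
            zip(chain.sequence, chain.ca_coords, chain.plddt)
        ):
            atoms.coord[idx] = coord
            atoms.chain_id[idx] = chain.chain_id
            atoms.res_id[idx] = i + 1
            atoms.res_name[idx] = ProteinSequence.convert_letter_1to3(aa)
            atoms.atom_name[idx] = "CA"
            atoms.element[idx] = "C"
            atoms.b_factor[idx] = plddt
            idx += 1
    atoms.hetero = np.zeros(total, dtype=bool)
    return atoms


def gen_dimer_fixture(
    spec: DimerFixtureSpec, outdir: str | Path, name: str = "dimer"
) -> dict:
    """Write a loadable PDB + PAE JSON + score JSON fixture and its truth.

    The planted pair set equals ``constrained_pairs`` at default thresholds
    by construction (contacts are close and confidently scored; everything
    else is either far apart or drowned in PAE noise).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, pairs = _build_dimer(spec)
    pdb_path = outdir / f"{name}.pdb"
    pae_path = outdir / f"{name}_pae.json"
    scores_path = outdir / f"{name}_scores.json"
    truth_path = outdir / f"{name}_truth.json"
    pdb_file = PDBFile()
    pdb_file.set_structure(_chains_to_atom_array(model))
    pdb_file.write(str(pdb_path))
    pae_path.write_text(json.dumps({"pae": model.pae.values.tolist()}))
    scores = {
        "iptm": spec.iptm,
        "ptm": spec.ptm,
        "version": spec.version,
    }
    if spec.disorder_frac is not None:
        scores["disorder_frac"] = spec.disorder_frac
    scores_path.write_text(json.dumps(scores))
    ranking = ranking_score(model.score)
    n_bait = len({a for a, _ in pairs})
    n_prey = len({b for _, b in pairs})
    truth = {
        "seed": spec.seed,
        "pairs": [[a, b] for a, b in pairs],
        "n_bait": n_bait,
        "n_prey": n_prey,
        "ranking": ranking,
        "passes_v1": ranking > 0.6 and n_prey >= 20,
        "passes_v2": ranking > 0.6 and n_bait * n_prey > 100,
        "files": {
            "coords": pdb_path.name,
            "pae": pae_path.name,
            "scores": scores_path.name,
        },
    }
    truth_path.write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# nucleotide sequences with a planted longest stop-free run
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def gen_pseudogene_seq(
    length: int,
    planted_run_codons: int,
    frame: int,
    seed: int = 0,
    *,
    max_tries: int = 500,
) -> tuple[str, dict]:
    """A random sequence whose longest stop-free run sits in *frame*.

    The planted run has exactly ``planted_run_codons`` codons and is strictly
    longer than the longest run in every other frame (verified at
    generation; raises if the construction cannot be satisfied).
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be one of +-1..3, got {frame}")
    offset = abs(frame) - 1
    n_codons = (length - offset) // 3
    if planted_run_codons > n_codons or planted_run_codons < 1:
        raise ValueError(
            f"planted run of {planted_run_codons} codons does not fit in "
            f"{length} nt at frame {frame}"
        )
    rng = np.random.default_rng(seed)
    spans_whole = planted_run_codons == n_codons
    for _ in range(max_tries):
        codons = []
        for _k in range(n_codons):
            if rng.random() < 0.25:
                codons.append(_STOPS[rng.integers(len(_STOPS))])
            else:
                codons.append(_NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))])
        start = int(rng.integers(0, n_codons - planted_run_codons + 1))
        for k in range(start, start + planted_run_codons):
            codons[k] = _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
        if start > 0:
            codons[start - 1] = _STOPS[rng.integers(len(_STOPS))]
        if start + planted_run_codons < n_codons:
            codons[start + planted_run_codons] = _STOPS[rng.integers(len(_STOPS))]
        prefix = "".join(rng.choice(list("ACGT"), size=offset))
        tail_len = length - offset - 3 * n_codons
        suffix = "".join(rng.choice(list("ACGT"), size=tail_len))
        strand = prefix + "".join(codons) + suffix
        seq = strand if frame > 0 else _revcomp(strand)
        repaired = _repair_other_frames(
            seq, frame, planted_run_codons, allow_ties=spans_whole
        )
        if repaired is None:
            continue
        results, _ = six_frame_longest(repaired)
        truth = {
            "seed": seed,
            "frame": frame,
            "length_nt": length,
            "planted_run_codons": planted_run_codons,
            "start": results[frame].start,
            "end": results[frame].end,
            "peptide": results[frame].peptide,
        }
        return repaired, truth
    raise ValueError(
        f"could not construct a {length} nt sequence with a dominant "
        f"{planted_run_codons}-codon run in frame {frame} after {max_tries} tries"
    )


def _repair_other_frames(
    seq: str, frame: int, planted: int, *, allow_ties: bool
) -> str | None:
    """Inject stop codons into competing frames until the planted run wins.

    Stops are written in codon register for the offending frame (``TAA`` on
    the forward strand, ``TTA`` on the input strand for reverse frames) at
    positions clear of the planted run; returns None when a repair would
    damage the planted run, signalling the caller to reroll.
    """
    for _ in range(60):
        results, best = six_frame_longest(seq)
        if results[frame].length != planted:
            return None
        offenders = [
            f for f, r in results.items() if f != frame and r.length >= planted
        ]
        if not offenders:
            return seq
        if allow_ties:
            # run spans the whole sequence: only require the tie-break to win
            return seq if best.frame == frame else None
        target = results[frame]
        protected = range(target.start - 1, target.end)  # 0-based nt span
        worst = max(offenders, key=lambda f: results[f].length)
        run = results[worst]
        stop_nt = "TAA" if worst > 0 else "TTA"
        # try codon slots of the offending run from the middle outward
        n_run = run.length
        order = sorted(range(n_run), key=lambda k: abs(k - n_run // 2))
        for k in order:
            p = run.start - 1 + 3 * k
            if p in protected or (p + 2) in protected:
                continue
            seq = seq[:p] + stop_nt + seq[p + 3:]
            break
        else:
            return None
    return None


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
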