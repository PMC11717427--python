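"""Six-frame scan for the longest uninterrupted (stop-free) peptide stretch.

Runs are stop-to-stop by default (no start codon required); codons that
contain N translate to X and never terminate a run. Frames -1/-2/-3 are the
three forward frames of the reverse complement; reported spans are 1-based
closed intervals on the *input* strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass(frozen=True)
class FrameResult:
    frame: int  # one of +-1, +-2, +-3
    peptide: str
    start: int  # 1-based, closed, on the input strand
    end: int

    @property
    def length(self) -> int:
        return len(self.peptide)


def translate_codon(codon: str) -> str:
    """Single-codon translation; ambiguous codons become X, stops become *."""
    codon = codon.upper()
    if codon in _STOP_CODONS:
        return "*"
    if "N" in codon:
        return "X"
    try:
        return _CODON_TABLE[codon]
    except KeyError:
        raise ValueError(f"illegal codon {codon!r}")


def _longest_run(codons: list[str]) -> tuple[int, int]:
    """(start_codon, end_codon) 0-based closed of the longest non-stop run.

    Ties resolve to the 5'-most run; no run yields (0, -1).
    """
    best = (0, -1)
    best_len = 0
    start = None
    for i, aa in enumerate([translate_codon(c) for c in codons] + ["*"]):
        if aa == "*":
            if start is not None and i - start > best_len:
                best_len = i - start
                best = (start, i - 1)
            start = None
        elif start is None:
            start = i
    return best


def _scan_frame(seq: str, frame: int) -> FrameResult:
    length = len(seq)
    if frame > 0:
        strand, offset = seq, frame - 1
    else:
        strand, offset = str(Seq(seq).reverse_complement()), -frame - 1
    n_codons = (length - offset) // 3
    codons = [strand[offset + 3 * k: offset + 3 * k + 3] for k in range(n_codons)]
    c0, c1 = _longest_run(codons)
    if c1 < c0:
        return FrameResult(frame=frame, peptide="", start=0, end=-1)
    peptide = "".join(translate_codon(c) for c in codons[c0: c1 + 1])
    s = offset + 3 * c0 + 1  # 1-based on the scanned strand
    e = offset + 3 * (c1 + 1)
    if frame < 0:  # map back to input-strand coordinates
        s, e = length - e + 1, length - s + 1
    return FrameResult(frame=frame, peptide=peptide, start=s, end=e)


def six_frame_longest(seq: str) -> tuple[dict[int, FrameResult], FrameResult]:
    """Longest stop-free peptide per frame, plus the overall best.

    The best frame is the one with the longest run; ties prefer forward
    frames in the order +1, +2, +3, -1, -2, -3.
    """
    seq = seq.strip().upper()
    if len(seq) < 3:
        raise ValueError(f"sequence too short to contain a codon: {len(seq)} nt")
    illegal = set(seq) - set("ACGTN")
    if illegal:
        raise ValueError(f"illegal characters in sequence: {sorted(illegal)}")
    results = {frame: _scan_frame(seq, frame) for frame in FRAMES}
    best = max(results.values(), key=lambda r: (r.length, -FRAMES.index(r.frame)))
    return results, best


def scan_fasta(path: str | Path, *, require_atg: bool = False) -> pd.DataFrame:
    """Scan every record of a FASTA file; one row per frame per record."""
    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if require_atg:
            results = {f: _scan_frame_atg(seq, f) for f in FRAMES}
        else:
            results, _ = six_frame_longest(seq)
        for frame in FRAMES:
            r = results[frame]
            rows.append(
                {
                    "record": record.id,
                    "frame": frame,
                    "start": r.start,
                    "end": r.end,
                    "length": r.length,
                    "peptide": r.peptide,
                }
            )
    return pd.DataFrame(rows, columns=["record", "frame", "start", "end",
                                       "length", "peptide"])


def _scan_frame_atg(seq: str, frame: int) -> FrameResult:
    """Variant requiring the run to begin with a Met codon."""
    seq = seq.strip().upper()
    base = _scan_frame(seq, frame)
    length = len(seq)
    strand = seq if frame > 0 else str(Seq(seq).reverse_complement())
    offset = frame - 1 if frame > 0 else -frame - 1
    n_codons = (length - offset) // 3
    codons = [strand[offset + 3 * k: offset + 3 * k + 3] for k in range(n_codons)]
    aas = [translate_codon(c) for c in codons]
    best = (0, -1)
    for i, aa in enumerate(aas):
        if aa != "M":
            continue
        j = i
        while j < len(aas) and aas[j] != "*":
            j += 1
        if j - i > best[1] - best[0] + 1:
            best = (i, j - 1)
    if best[1] < best[0]:
        return FrameResult(frame=frame, peptide="", start=0, end=-1)
    c0, c1 = best
    peptide = "".join(aas[c0: c1 + 1])
    s = offset + 3 * c0 + 1
    e = offset + 3 * (c1 + 1)
    if frame < 0:
        s, e = length - e + 1, length - s + 1
    return FrameResult(frame=frame, peptide=peptide, start=s, end=e)
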