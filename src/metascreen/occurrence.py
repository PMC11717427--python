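"""Genes x lists incidence and the selectivity-weighted regulation score.

The central quantity is the score of a gene set G over a corpus of n lists:

    score(G) = sum_i S_i / T_i

where S_i is the overlap of G with the i-th list and T_i the list size. A
per-gene variant distributes each list's S_i/T_i contribution to the members
of G it contains, so culling the top-g most frequent genes and then scoring
them yields a prioritization order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from metascreen.ingest import GeneList

ScoreMode = Literal["overlap", "selectivity"]


@dataclass
class OccurrenceMatrix:
    """Binary incidence of genes (rows) across lists (columns)."""

    gene_ids: list[str]
    list_ids: list[str]
    incidence: np.ndarray  # bool, shape (genes, lists)
    T: np.ndarray  # int, per-list sizes

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        self.T = np.asarray(self.T, dtype=int)
        g, n = self.incidence.shape
        if g != len(self.gene_ids) or n != len(self.list_ids):
            raise ValueError("incidence shape does not match id sequences")
        if n < 1:
            raise ValueError("at least one list required")
        if not np.array_equal(self.incidence.sum(axis=0), self.T):
            raise ValueError("column sums must equal per-list sizes T")
        if (self.incidence.sum(axis=1) == 0).any():
            raise ValueError("all-zero gene rows are not allowed")

    @property
    def n(self) -> int:
        """Number of lists."""
        return len(self.list_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in matrix") from exc

    def frequencies(self) -> np.ndarray:
        """Per-gene count of lists containing the gene."""
        return self.incidence.sum(axis=1)

    def presence(self, gene: str) -> np.ndarray:
        """Binary presence vector of one gene over the lists."""
        return self.incidence[self.gene_index([gene])[0]]


def build_matrix(lists: Sequence[GeneList]) -> OccurrenceMatrix:
    """Join gene lists into an incidence matrix; empty lists are excluded."""
    lists = [gl for gl in lists if not gl.is_empty]
    if not lists:
        raise ValueError("no non-empty lists to build a matrix from")
    ids = [gl.list_id for gl in lists]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate list ids: {dupes}")
    genes = sorted(set().union(*(gl.genes for gl in lists)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    incidence = np.zeros((len(genes), len(lists)), dtype=bool)
    for j, gl in enumerate(lists):
        for g in gl.genes:
            incidence[gene_idx[g], j] = True
    return OccurrenceMatrix(
        gene_ids=genes,
        list_ids=ids,
        incidence=incidence,
        T=incidence.sum(axis=0),
    )


def top_genes(m: OccurrenceMatrix, g: int) -> list[str]:
    """The g most frequent genes, ties broken lexicographically by id."""
    if not (1 <= g <= m.n_genes):
        raise ValueError(f"g must be in [1, {m.n_genes}], got {g}")
    freq = m.frequencies()
    order = sorted(range(m.n_genes), key=lambda i: (-freq[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[:g]]


def rg_set_score(m: OccurrenceMatrix, geneset: Iterable[str]) -> float:
    """Set-level score: sum over lists of |geneset ∩ list| / T_i."""
    genes = list(geneset)
    if not genes:
        return 0.0
    idx = m.gene_index(genes)
    S = m.incidence[idx].sum(axis=0)
    return float((S / m.T).sum())


def rg_gene_scores(
    m: OccurrenceMatrix, g: int, *, mode: ScoreMode = "overlap"
) -> pd.DataFrame:
    """Score the top-g genes individually and rank them.

    In the default ``overlap`` mode each list containing gene j contributes
    S_i/T_i, where S_i counts the whole top-g set's members in that list; the
    ``selectivity`` alternative contributes 1/T_i instead. Output columns:
    gene, frequency, r_score, rank (1-based, r descending, lexicographic
    tie-break).
    """
    culled = top_genes(m, g)
    idx = m.gene_index(culled)
    sub = m.incidence[idx]  # (g, n)
    S = sub.sum(axis=0)  # per-list overlap with the top set
    if mode == "overlap":
        per_list = S / m.T
    elif mode == "selectivity":
        per_list = 1.0 / m.T
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    r = (sub * per_list).sum(axis=1)
    freq = sub.sum(axis=1)
    df = pd.DataFrame({"gene": culled, "frequency": freq, "r_score": r})
    df = df.sort_values(
        ["r_score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def rg_contributions(m: OccurrenceMatrix, g: int) -> dict:
    """Audit of per-list S_i/T_i contributions for each top-g gene."""
    culled = top_genes(m, g)
    idx = m.gene_index(culled)
    sub = m.incidence[idx]
    S = sub.sum(axis=0)
    audit = {}
    for row, gene in zip(sub, culled):
        audit[gene] = {
            m.list_ids[i]: {"S": int(S[i]), "T": int(m.T[i])}
            for i in np.flatnonzero(row)
        }
    return audit


def rank_stability(m: OccurrenceMatrix, g1: int, g2: int) -> int:
    """Overlap of the top-g1 genes ranked with parameter g1 vs parameter g2."""
    if not (1 <= g1 <= g2 <= m.n_genes):
        raise ValueError(f"need 1 <= g1 <= g2 <= {m.n_genes}, got {g1}, {g2}")
    by_g1 = set(rg_gene_scores(m, g1)["gene"].iloc[:g1])
    by_g2 = set(rg_gene_scores(m, g2)["gene"].iloc[:g1])
    return len(by_g1 & by_g2)
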