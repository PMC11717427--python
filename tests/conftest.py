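import numpy as np
import pytest

from metascreen.ingest import GeneList
from metascreen.occurrence import OccurrenceMatrix, build_matrix


def make_lists(*gene_sets: str | set) -> list[GeneList]:
    """Gene lists from iterables of single-character gene ids."""
    return [
        GeneList(
            list_id=f"L{i + 1}",
            source_id=f"S{i + 1}",
            category="other",
            genes=frozenset(gs),
        )
        for i, gs in enumerate(gene_sets)
    ]


@pytest.fixture
def toy_matrix() -> OccurrenceMatrix:
    """The worked 3-list example: L1={a,b}, L2={a,c}, L3={a,b,c,d}."""
    return build_matrix(make_lists("ab", "ac", "abcd"))


def random_matrix(rng: np.random.Generator, n_genes=12, n_lists=8) -> OccurrenceMatrix:
    """A random incidence matrix with no empty lists or all-zero genes."""
    while True:
        incidence = rng.random((n_genes, n_lists)) < 0.4
        if incidence.sum(axis=0).min() > 0 and incidence.sum(axis=1).min() > 0:
            break
    genes = [f"g{i:02d}" for i in range(n_genes)]
    lists = [f"L{i:02d}" for i in range(n_lists)]
    return OccurrenceMatrix(
        gene_ids=genes,
        list_ids=lists,
        incidence=incidence,
        T=incidence.sum(axis=0),
    )
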