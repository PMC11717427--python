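"""Overlap probabilities between random lists and a fixed top-gene set.

For a genome of N genes, a chosen set of g genes and a random list of T
genes, the chance of at least one overlap is hypergeometric:

    P(S > 0) = 1 - C(N - g, T) / C(N, T)

computed via log-gamma to stay stable at genome scale. The Monte-Carlo
counterpart draws uniform T-subsets and records, per run, the fraction of
lists hitting the set. A preferential-attachment generator grows lists whose
gene draws favor genes already seen, producing the heavy-tailed occurrence
counts that accumulating literatures display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from metascreen.ingest import GeneList
from metascreen.occurrence import OccurrenceMatrix, build_matrix


@dataclass(frozen=True)
class SimConfig:
    N: int
    g: int
    T: int
    runs: int = 100
    lists_per_run: int = 398
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.g <= self.N):
            raise ValueError(f"need 0 <= g <= N, got g={self.g}, N={self.N}")
        if not (1 <= self.T <= self.N):
            raise ValueError(f"need 1 <= T <= N, got T={self.T}, N={self.N}")
        if self.runs < 1 or self.lists_per_run < 1:
            raise ValueError("runs and lists_per_run must be positive")


@dataclass
class OverlapDistribution:
    config: SimConfig
    estimates: np.ndarray  # per-run P(S_i > 0) estimates

    def summary(self) -> dict:
        q1, med, q3 = np.percentile(self.estimates, [25, 50, 75])
        return {"q1": float(q1), "median": float(med), "q3": float(q3),
                "mean": float(self.estimates.mean())}

    def to_frame(self) -> pd.DataFrame:
        c = self.config
        return pd.DataFrame(
            {
                "N": c.N,
                "g": c.g,
                "T": c.T,
                "run": np.arange(1, c.runs + 1),
                "estimate": self.estimates,
            }
        )


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def p_overlap_analytic(N: int, g: int, T: int) -> float:
    """Exact P(S > 0) = 1 - C(N-g, T)/C(N, T), stable at large N."""
    SimConfig(N=N, g=g, T=T)  # parameter validation
    if g == 0:
        return 0.0
    if T > N - g:
        return 1.0
    log_ratio = _log_binom(N - g, T) - _log_binom(N, T)
    return float(1.0 - np.exp(log_ratio))


def simulate_overlap(cfg: SimConfig) -> OverlapDistribution:
    """Monte-Carlo estimate of P(S > 0): uniform T-subsets vs a fixed g-set."""
    rng = np.random.default_rng(cfg.seed)
    estimates = np.empty(cfg.runs)
    for run in range(cfg.runs):
        hits = 0
        for _ in range(cfg.lists_per_run):
            draw = rng.choice(cfg.N, size=cfg.T, replace=False)
            if cfg.g > 0 and (draw < cfg.g).any():
                hits += 1
        estimates[run] = hits / cfg.lists_per_run
    return OverlapDistribution(config=cfg, estimates=estimates)


def preferential_attachment_lists(
    N: int,
    n_lists: int,
    list_size_sampler: int | Callable[[np.random.Generator], int],
    attachment_strength: float,
    seed: int = 0,
    *,
    initial_counts: Mapping[int, int] | None = None,
) -> tuple[OccurrenceMatrix, np.ndarray]:
    """Grow lists sequentially with rich-get-richer gene sampling.

    Each list draws its genes without replacement with probability
    proportional to (current occurrence count + attachment_strength). When
    every remaining weight is zero (only possible at strength 0), the
    remainder of the list is filled uniformly. Returns the resulting
    occurrence matrix and the per-gene final counts (length N, indexed by
    gene number, including genes that never occurred).
    """
    if attachment_strength < 0:
        raise ValueError("attachment_strength must be >= 0")
    if n_lists < 1:
        raise ValueError("need at least one list")
    rng = np.random.default_rng(seed)
    counts = np.zeros(N, dtype=float)
    if initial_counts:
        for gene, c in initial_counts.items():
            counts[gene] = c
    width = len(str(N - 1))
    gene_names = [f"G{i:0{width}d}" for i in range(N)]
    lists = []
    for li in range(n_lists):
        size = (
            list_size_sampler
            if isinstance(list_size_sampler, int)
            else int(list_size_sampler(rng))
        )
        if size > N:
            raise ValueError(f"list size {size} exceeds genome size {N}")
        weights = counts + attachment_strength
        positive = np.flatnonzero(weights > 0)
        chosen: list[int] = []
        if positive.size:
            k = min(size, positive.size)
            # Gumbel top-k = weighted sampling without replacement
            keys = np.log(weights[positive]) + rng.gumbel(size=positive.size)
            chosen.extend(positive[np.argsort(keys)[::-1][:k]].tolist())
        if len(chosen) < size:
            zero = np.setdiff1d(np.arange(N), np.array(chosen, dtype=int))
            fill = rng.choice(zero, size=size - len(chosen), replace=False)
            chosen.extend(fill.tolist())
        counts[chosen] += 1
        lists.append(
            GeneList(
                list_id=f"pa{li:04d}",
                source_id="preferential_attachment",
                category="other",
                genes=frozenset(gene_names[i] for i in chosen),
            )
        )
    return build_matrix(lists), counts.astype(int)
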