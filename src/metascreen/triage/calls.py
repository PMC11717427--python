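"""Constrained-pair calling and interaction verdicts.

A residue pair (i in chain A, j in chain B) is *constrained* when the
Ca-Ca distance is strictly below ``dist_max`` and the larger of the two PAE
entries for the pair is strictly below ``pae_max``. Two generations of
significance criteria are applied on top:

* v1 — ranking score > ``min_rank`` and at least ``min_prey_residues``
  distinct constrained residues in the prey (candidate) chain;
* v2 — ranking score > ``min_rank`` and n_bait * n_prey > ``min_product``.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from metascreen.triage.models import ContactPair, DimerModel, InteractionCall

DistanceMode = Literal["ca", "all_atom"]
Verdict = Literal[
    "similar_interface", "different_interface", "one_sided", "neither"
]


def _residue_distances(model: DimerModel, mode: DistanceMode) -> np.ndarray:
    a, b = model.chain_a, model.chain_b
    if mode == "ca":
        return cdist(a.ca_coords, b.ca_coords)
    if mode != "all_atom":
        raise ValueError(f"unknown distance mode {mode!r}")
    dists = np.full((len(a), len(b)), np.inf)
    for i in range(1, len(a) + 1):
        ca_coords, _ = a.atoms_of_residues([i])
        for j in range(1, len(b) + 1):
            cb_coords, _ = b.atoms_of_residues([j])
            dists[i - 1, j - 1] = cdist(ca_coords, cb_coords).min()
    return dists


def constrained_pairs(
    model: DimerModel,
    pae_max: float = 5.0,
    dist_max: float = 6.0,
    *,
    distance_mode: DistanceMode = "ca",
) -> frozenset[ContactPair]:
    """Inter-chain pairs with distance < dist_max and max PAE < pae_max."""
    dists = _residue_distances(model, distance_mode)
    pae_ab, pae_ba = model.pae.inter_blocks()
    pae_sym = np.maximum(pae_ab, pae_ba)
    mask = (dists < dist_max) & (pae_sym < pae_max)
    pairs = {
        ContactPair(
            res_a=int(i) + 1,
            res_b=int(j) + 1,
            ca_distance=float(dists[i, j]),
            pae_ab=float(pae_ab[i, j]),
            pae_ba=float(pae_ba[i, j]),
        )
        for i, j in zip(*np.nonzero(mask))
    }
    return frozenset(pairs)


def call_interaction(
    model: DimerModel,
    *,
    pair_id: tuple[str, str] = ("bait", "prey"),
    min_rank: float = 0.6,
    min_prey_residues: int = 20,
    min_product: int = 100,
    pae_max: float = 5.0,
    dist_max: float = 6.0,
    distance_mode: DistanceMode = "ca",
    area_norm: float = 0.0,
    pairs: frozenset[ContactPair] | None = None,
) -> InteractionCall:
    """Apply both criteria generations to a model's constrained pairs."""
    if pairs is None:
        pairs = constrained_pairs(
            model, pae_max=pae_max, dist_max=dist_max, distance_mode=distance_mode
        )
    n_bait = len({p.res_a for p in pairs})
    n_prey = len({p.res_b for p in pairs})
    ranking = model.ranking
    return InteractionCall(
        pair_id=pair_id,
        pairs=pairs,
        n_bait=n_bait,
        n_prey=n_prey,
        ranking=ranking,
        area_norm=area_norm,
        passes_v1=ranking > min_rank and n_prey >= min_prey_residues,
        passes_v2=ranking > min_rank and n_bait * n_prey > min_product,
    )


def constrained_profile(
    model: DimerModel,
    pairs: frozenset[ContactPair] | None = None,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Per-chain boolean tracks marking residues in at least one pair."""
    if pairs is None:
        pairs = constrained_pairs(model, **kwargs)
    track_a = np.zeros(len(model.chain_a), dtype=bool)
    track_b = np.zeros(len(model.chain_b), dtype=bool)
    for p in pairs:
        track_a[p.res_a - 1] = True
        track_b[p.res_b - 1] = True
    return {model.chain_a.chain_id: track_a, model.chain_b.chain_id: track_b}


def concordance(
    call_a: InteractionCall,
    call_b: InteractionCall,
    overlap_min: float = 0.25,
    *,
    criteria: Literal["v1", "v2"] = "v2",
) -> Verdict:
    """Compare two calls for the same pair (e.g. from two predictors).

    Both passing: interfaces are ``similar`` when the Jaccard overlap of
    their constrained prey-residue sets reaches ``overlap_min`` (inclusive),
    else ``different``. One passing: ``one_sided``; none: ``neither``.
    """
    pass_a = call_a.passes_v2 if criteria == "v2" else call_a.passes_v1
    pass_b = call_b.passes_v2 if criteria == "v2" else call_b.passes_v1
    if pass_a and pass_b:
        sa, sb = call_a.prey_residues, call_b.prey_residues
        union = sa | sb
        overlap = len(sa & sb) / len(union) if union else 0.0
        return "similar_interface" if overlap >= overlap_min else "different_interface"
    if pass_a or pass_b:
        return "one_sided"
    return "neither"
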