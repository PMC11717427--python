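"""Rigid superposition (Kabsch) and model-convergence RMSD tables."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from metascreen.triage.models import DimerModel


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto reference.

    Applying ``x @ R.T + t`` to mobile coordinates minimizes the RMSD to the
    reference; reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate sets must have identical shapes")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = rc - rot @ mc
    return rot, trans


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_rmsd(
    model_ref: DimerModel,
    model_alt: DimerModel,
    anchor_chain: str = "A",
    *,
    whole_complex: bool = False,
) -> float:
    """RMSD of the partner chain after aligning models on the anchor chain.

    Both models must share both chain sequences. The rigid fit uses the
    anchor chain's Ca atoms; the reported RMSD covers the other chain's Ca
    atoms (or both chains with ``whole_complex=True``).
    """
    for ref_chain, alt_chain in (
        (model_ref.chain_a, model_alt.chain_a),
        (model_ref.chain_b, model_alt.chain_b),
    ):
        if ref_chain.sequence != alt_chain.sequence:
            raise ValueError(
                f"chain {ref_chain.chain_id} sequences differ between models"
            )
    chains_ref = {model_ref.chain_a.chain_id: model_ref.chain_a,
                  model_ref.chain_b.chain_id: model_ref.chain_b}
    chains_alt = {model_alt.chain_a.chain_id: model_alt.chain_a,
                  model_alt.chain_b.chain_id: model_alt.chain_b}
    if anchor_chain not in chains_ref:
        raise ValueError(f"unknown anchor chain {anchor_chain!r}")
    rot, trans = kabsch(
        chains_alt[anchor_chain].ca_coords, chains_ref[anchor_chain].ca_coords
    )
    if whole_complex:
        targets = list(chains_ref)
    else:
        targets = [c for c in chains_ref if c != anchor_chain]
    ref = np.vstack([chains_ref[c].ca_coords for c in targets])
    alt = np.vstack([chains_alt[c].ca_coords for c in targets])
    return _rmsd(alt @ rot.T + trans, ref)


def convergence_table(
    models: Sequence[DimerModel], anchor_chain: str = "A"
) -> pd.DataFrame:
    """RMSD of every model against the highest-ranking one, sorted ascending.

    Columns: model (input index), ranking, rmsd. The top model appears first
    with RMSD 0.
    """
    if not models:
        raise ValueError("need at least one model")
    rankings = [m.ranking for m in models]
    top = int(np.argmax(rankings))
    rows = []
    for i, model in enumerate(models):
        rmsd = (
            0.0 if i == top else superpose_rmsd(models[top], model, anchor_chain)
        )
        rows.append({"model": i, "ranking": rankings[i], "rmsd": rmsd})
    df = pd.DataFrame(rows).sort_values(
        ["rmsd", "model"], kind="mergesort"
    ).reset_index(drop=True)
    return df
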