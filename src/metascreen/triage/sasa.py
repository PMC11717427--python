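"""Solvent-accessible surface area and buried interface area.

Shrake-Rupley quadrature on a Fibonacci sphere. Buried area follows the
half-sum convention:

    buried = 1/2 * (SASA(A alone) + SASA(B alone) - SASA(A u B together))

computed over the isolated constrained-residue selections, and is then
normalized by the product of the two chain lengths.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from metascreen.triage.models import DimerModel


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (A^2) of a set of spheres."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n_atoms, 3)")
    if radii.shape != (coords.shape[0],):
        raise ValueError("radii must match atom count")
    sphere = _fibonacci_sphere(n_points)
    n_atoms = coords.shape[0]
    areas = np.empty(n_atoms)
    pairwise = cdist(coords, coords)
    for i in range(n_atoms):
        neighbors = np.flatnonzero(
            (pairwise[i] < radii[i] + radii) & (np.arange(n_atoms) != i)
        )
        points = coords[i] + radii[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            accessible &= (
                np.linalg.norm(points - coords[j], axis=1) >= radii[j]
            )
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return areas


def interface_area(
    model: DimerModel,
    residues_a: Iterable[int],
    residues_b: Iterable[int],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[float, float]:
    """(buried_area, area_norm) over the constrained-residue selections.

    Empty selections yield (0, 0). Residues lacking atom records raise,
    naming the offending residue.
    """
    residues_a = sorted(set(int(r) for r in residues_a))
    residues_b = sorted(set(int(r) for r in residues_b))
    if not residues_a or not residues_b:
        return 0.0, 0.0
    coords_a, radii_a = model.chain_a.atoms_of_residues(residues_a)
    coords_b, radii_b = model.chain_b.atoms_of_residues(residues_b)
    sasa_a = shrake_rupley(coords_a, radii_a, probe_radius, n_points).sum()
    sasa_b = shrake_rupley(coords_b, radii_b, probe_radius, n_points).sum()
    combined_coords = np.vstack([coords_a, coords_b])
    combined_radii = np.concatenate([radii_a, radii_b])
    sasa_ab = shrake_rupley(combined_coords, combined_radii, probe_radius, n_points).sum()
    buried = 0.5 * (sasa_a + sasa_b - sasa_ab)
    area_norm = buried / (len(model.chain_a) * len(model.chain_b))
    return float(buried), float(area_norm)
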