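"""Residue-level geometry: minimum heavy-atom distances and contact gaps.

The contact criterion everywhere in the package is the closest heavy-atom
approach: two residues are in contact when some atom pair is closer than the
sum of the two van der Waals radii plus a pad (0.5 Å by default).  The "gap"
matrix below stores min over atom pairs of (distance − r_a − r_b), so the
contact test is simply ``gap < pad``.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .features import Protein, ResidueRecord

DEFAULT_CONTACT_PAD = 0.5  # Å


def _atom_blocks(protein: Protein):
    coords = np.concatenate([r.coords for r in protein.residues])
    radii = np.concatenate([r.radii for r in protein.residues])
    counts = [len(r.atoms) for r in protein.residues]
    bounds = np.concatenate([[0], np.cumsum(counts)])
    return coords, radii, bounds


def _block_min(mat: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    """Reduce an atom-pair matrix to a residue-pair matrix by blockwise min."""
    n = len(bounds) - 1
    out = np.empty((n, n))
    for i in range(n):
        rows = mat[bounds[i]:bounds[i + 1]]
        for j in range(i, n):
            m = rows[:, bounds[j]:bounds[j + 1]].min()
            out[i, j] = out[j, i] = m
    return out


def min_distance_matrix(protein: Protein) -> np.ndarray:
    """(n, n) minimum heavy-atom distance (Å) between residue pairs; 0 on diagonal."""
    coords, _, bounds = _atom_blocks(protein)
    return _block_min(cdist(coords, coords), bounds)


def contact_gap_matrix(protein: Protein) -> np.ndarray:
    """(n, n) min over atom pairs of (distance − r_a − r_b); negative = overlap."""
    coords, radii, bounds = _atom_blocks(protein)
    gaps = cdist(coords, coords) - radii[:, None] - radii[None, :]
    return _block_min(gaps, bounds)


def residue_pair_gap(r1: ResidueRecord, r2: ResidueRecord) -> float:
    """Min over atom pairs of (distance − r_a − r_b) for two residues."""
    d = cdist(r1.coords, r2.coords)
    return float((d - r1.radii[:, None] - r2.radii[None, :]).min())
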