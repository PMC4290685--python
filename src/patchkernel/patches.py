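"""Interface/surface residue sets and the three patch kinds.

Definitions (solvent-accessible surface area = ASA):

* interface residue — its ASA in the protein–DNA complex is smaller than in
  the unbound protein by at least 1 Å² (inclusive threshold);
* surface residue — relative accessibility in the unbound protein is
  strictly greater than 5%;
* interface patch — all interface residues of one protein (connectivity is
  not imposed);
* non-interface patch — a contiguous group of non-interface surface residues
  sampled at random, size-matched to the interface patch;
* centered surface patch — a surface residue plus its k nearest surface
  neighbours (k = 5 by default, giving 6-residue patches).

"Nearest" uses the minimum heavy-atom distance, consistent with the contact
criterion; ties break on (chain, resnum, icode) order so every operation is
deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, EmptyInterfaceError, SamplingError
from .features import Protein, ResKey
from .geometry import DEFAULT_CONTACT_PAD, contact_gap_matrix, min_distance_matrix

INTERFACE = "interface"
NON_INTERFACE = "non_interface"
UNKNOWN = "unknown"

INTERFACE_ASA_LOSS = 1.0  # Å², inclusive
SURFACE_REL_ACC = 5.0  # %, strict

_MAX_SAMPLING_RESTARTS = 100


@dataclass(frozen=True)
class Patch:
    """A set of residues from one protein, with an optional center and label."""

    protein_id: str
    residue_keys: tuple[ResKey, ...]
    label: str = UNKNOWN
    center: ResKey | None = None

    def __post_init__(self) -> None:
        if len(set(self.residue_keys)) != len(self.residue_keys):
            raise ValueError("patch has duplicate residue keys")
        if self.center is not None and self.center not in self.residue_keys:
            raise ValueError("patch center must be one of its residues")
        if self.label not in (INTERFACE, NON_INTERFACE, UNKNOWN):
            raise ValueError(f"unknown patch label {self.label!r}")

    @property
    def size(self) -> int:
        return len(self.residue_keys)

    @property
    def key_set(self) -> frozenset[ResKey]:
        return frozenset(self.residue_keys)


def interface_residues(protein: Protein) -> set[ResKey]:
    """Residues losing ≥ 1 Å² of ASA upon complex formation."""
    out: set[ResKey] = set()
    for res in protein.residues:
        if res.asa_complex is None or res.asa_unbound is None:
            raise DataError(f"{protein.protein_id}: residue {res.key} lacks ASA values")
        if res.asa_unbound - res.asa_complex >= INTERFACE_ASA_LOSS:
            out.add(res.key)
    return out


def surface_residues(protein: Protein) -> set[ResKey]:
    """Residues with unbound relative accessibility strictly above 5%."""
    out: set[ResKey] = set()
    for res in protein.residues:
        if res.rel_acc is None:
            raise DataError(
                f"{protein.protein_id}: residue {res.key} lacks relative accessibility"
            )
        if res.rel_acc > SURFACE_REL_ACC:
            out.add(res.key)
    return out


def extract_interface_patch(protein: Protein) -> Patch:
    """The patch containing every interface residue of the protein."""
    keys = interface_residues(protein)
    if not keys:
        raise EmptyInterfaceError(f"{protein.protein_id}: no interface residues")
    return Patch(
        protein_id=protein.protein_id,
        residue_keys=tuple(sorted(keys)),
        label=INTERFACE,
    )


def sample_noninterface_patch(protein: Protein, size: int, rng_seed: int, *,
                              pad: float = DEFAULT_CONTACT_PAD) -> Patch:
    """Sample a contiguous patch of ``size`` non-interface surface residues.

    A uniformly random eligible seed residue is chosen and the patch grows by
    repeatedly adding the closest eligible surface residue in contact with the
    current patch; if growth stalls before reaching ``size`` the sample is
    restarted from a fresh seed (at most 100 restarts).  Identical
    ``rng_seed`` yields an identical patch.
    """
    interface = interface_residues(protein)
    eligible = sorted(surface_residues(protein) - interface)
    if len(eligible) < size:
        raise SamplingError(
            f"{protein.protein_id}: only {len(eligible)} non-interface surface "
            f"residues, cannot build a patch of size {size}"
        )
    keys = protein.keys()
    key_index = {k: i for i, k in enumerate(keys)}
    gap = contact_gap_matrix(protein)
    dist = min_distance_matrix(protein)
    elig_idx = [key_index[k] for k in eligible]

    rng = np.random.default_rng(rng_seed)
    for _ in range(_MAX_SAMPLING_RESTARTS):
        start = elig_idx[int(rng.integers(len(elig_idx)))]
        patch = [start]
        in_patch = {start}
        while len(patch) < size:
            best = None  # (distance to patch, key) for tie-breaking
            for j in elig_idx:
                if j in in_patch:
                    continue
                if min(gap[j, i] for i in patch) >= pad:
                    continue  # not in contact with the patch
                d = min(dist[j, i] for i in patch)
                cand = (d, keys[j], j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
            if best is None:
                break  # stalled: no eligible contacting residue left
            patch.append(best[2])
            in_patch.add(best[2])
        if len(patch) == size:
            return Patch(
                protein_id=protein.protein_id,
                residue_keys=tuple(sorted(keys[i] for i in patch)),
                label=NON_INTERFACE,
            )
    raise SamplingError(
        f"{protein.protein_id}: no contiguous non-interface patch of size "
        f"{size} found after {_MAX_SAMPLING_RESTARTS} restarts"
    )


def centered_surface_patches(protein: Protein, k: int = 5) -> list[Patch]:
    """One patch per surface residue: the residue plus its k nearest surface
    neighbours (patch size k + 1); label is unknown."""
    surface = sorted(surface_residues(protein))
    if len(surface) < k + 1:
        raise DataError(
            f"{protein.protein_id}: {len(surface)} surface residues, "
            f"need at least {k + 1} for centered patches"
        )
    keys = protein.keys()
    key_index = {key: i for i, key in enumerate(keys)}
    dist = min_distance_matrix(protein)
    surf_idx = np.array([key_index[key] for key in surface])

    out: list[Patch] = []
    for center in surface:
        ci = key_index[center]
        others = [(dist[ci, j], keys[j]) for j in surf_idx if j != ci]
        others.sort()
        members = [center] + [key for _, key in others[:k]]
        out.append(
            Patch(
                protein_id=protein.protein_id,
                residue_keys=tuple(sorted(members)),
                label=UNKNOWN,
                center=center,
            )
        )
    return out
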