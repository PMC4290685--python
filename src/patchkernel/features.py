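"""Residue/feature data model: structures, feature tables, normalization.

A protein is a sequence of residues; each residue carries its heavy atoms
(coordinates + van der Waals radii) and a fixed-order vector of 26 per-residue
attributes used as graph node labels:

    index 0      relative solvent accessibility (rASA)
    index 1      electrostatic potential
    index 2      sequence entropy
    index 3      surface curvature
    index 4      pocket size
    index 5      structural conservation
    indices 6-25 PSSM log-odds, columns in standard PSI-BLAST order
                 (A R N D C Q E G H I L K M F P S T W Y V)

Attribute computation (NACCESS, Delphi, PSI-BLAST, ...) is out of scope: the
attributes, the bound/unbound solvent-accessible surface areas and the relative
accessibility are consumed from a tab-separated feature table.  This module
reads both inputs, merges them, and min-max normalizes the attributes to [0, 1]
over a training set so that the Gaussian node kernel sees commensurate scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DataError,
    EmptyInputError,
    FormatError,
    StateError,
)

#: residue key: (chain id, residue number, insertion code; "" when absent)
ResKey = tuple[str, int, str]

#: PSI-BLAST PSSM column order (amino acids alphabetical by three-letter code)
PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"

SCALAR_ATTRIBUTES = ("rasa", "ep", "entropy", "curv", "pocket", "strcn")
ATTRIBUTE_NAMES: tuple[str, ...] = SCALAR_ATTRIBUTES + tuple(
    f"pssm_{aa}" for aa in PSSM_ORDER
)
N_ATTRIBUTES = len(ATTRIBUTE_NAMES)  # 26

#: named attribute-index groups for feature-subset runs
FEATURE_GROUPS: dict[str, tuple[int, ...]] = {
    "rasa": (0,),
    "ep": (1,),
    "entropy": (2,),
    "curv": (3,),
    "pocket": (4,),
    "strcn": (5,),
    "pssm": tuple(range(6, N_ATTRIBUTES)),
    "all": tuple(range(N_ATTRIBUTES)),
}

#: van der Waals radii (Angstrom) by element; overridable via config
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
FALLBACK_RADIUS = 1.70

_TABLE_PREFIX = ("protein_id", "chain", "resnum", "icode", "aa",
                 "asa_complex", "asa_unbound", "rel_acc")
FEATURE_TABLE_COLUMNS: tuple[str, ...] = _TABLE_PREFIX + ATTRIBUTE_NAMES
_PSSM_ONLY_COLUMNS: tuple[str, ...] = tuple(
    c for c in FEATURE_TABLE_COLUMNS if c != "strcn"
)
_STRCN_INDEX = ATTRIBUTE_NAMES.index("strcn")


def radius_for(element: str, radii: Mapping[str, float] | None = None) -> float:
    """Van der Waals radius for an element symbol, with a carbon-like fallback."""
    table = DEFAULT_RADII if radii is None else radii
    return float(table.get(element.upper(), FALLBACK_RADIUS))


@dataclass(frozen=True)
class Atom:
    """One heavy atom: PDB atom name, element symbol, coordinates (Å), radius (Å)."""

    name: str
    element: str
    coords: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if not self.radius > 0:
            raise ValueError(f"atom {self.name}: radius must be positive")


@dataclass
class ResidueRecord:
    """One residue: identity, heavy atoms, 26-attribute label vector, ASA fields.

    ``attributes`` may be ``None`` for a structure read without features, and is
    unnormalized until a fitted :class:`Normalizer` is applied.  ``asa_complex``
    and ``asa_unbound`` are solvent-accessible surface areas (Å²) in the
    protein–DNA complex and in the unbound protein; ``rel_acc`` is the relative
    accessibility (%) in the unbound protein.
    """

    protein_id: str
    chain: str
    resnum: int
    icode: str
    aa: str
    atoms: tuple[Atom, ...]
    attributes: np.ndarray | None = None
    asa_complex: float | None = None
    asa_unbound: float | None = None
    rel_acc: float | None = None

    def __post_init__(self) -> None:
        self.atoms = tuple(self.atoms)
        if not self.atoms:
            raise ValueError(f"residue {self.key}: needs at least one heavy atom")
        if self.attributes is not None:
            attrs = np.asarray(self.attributes, dtype=float)
            if attrs.shape != (N_ATTRIBUTES,):
                raise ValueError(
                    f"residue {self.key}: expected {N_ATTRIBUTES} attributes, "
                    f"got {attrs.shape}"
                )
            self.attributes = attrs
        for name in ("asa_complex", "asa_unbound"):
            val = getattr(self, name)
            if val is not None and val < 0:
                raise ValueError(f"residue {self.key}: {name} must be >= 0")

    @property
    def key(self) -> ResKey:
        return (self.chain, self.resnum, self.icode)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) heavy-atom coordinates."""
        return np.stack([a.coords for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])


@dataclass
class Protein:
    """A protein structure plus optional per-residue features and interface labels."""

    protein_id: str
    residues: list[ResidueRecord]
    interface_set: frozenset[ResKey] = field(default_factory=frozenset)
    normalized: bool = False

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError(f"{self.protein_id}: duplicate residue keys")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.residues)

    def keys(self) -> list[ResKey]:
        return [r.key for r in self.residues]

    def residue(self, key: ResKey) -> ResidueRecord:
        try:
            return self.residues[self._index[key]]
        except KeyError:
            raise DataError(f"{self.protein_id}: no residue {key}") from None

    def has_features(self) -> bool:
        return all(r.attributes is not None for r in self.residues)


# ---------------------------------------------------------------------------
# Structure input


def read_structure(pdb_path: str | Path, *,
                   radii: Mapping[str, float] | None = None) -> Protein:
    """Read a PDB file into a :class:`Protein` (coordinates and atoms only).

    Hydrogens, waters and non-amino-acid hetero groups are dropped.  Alternate
    locations are resolved to the highest-occupancy conformer (first-listed on
    ties).  Attributes and ASA fields are left unset; merge a feature table
    with :func:`attach_features`.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    path = Path(pdb_path)
    try:
        pdb_file = PDBFile.read(str(path))
        if pdb_file.get_model_count() == 0:
            raise EmptyInputError(f"{path}: no atom records found")
        arr = pdb_file.get_structure(model=1, altloc="occupancy")
    except EmptyInputError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"{path}: not a parseable PDB file: {exc}") from exc

    mask = struc.filter_amino_acids(arr)
    mask &= ~np.isin(arr.element, ("H", "D"))
    arr = arr[mask]
    if arr.array_length() == 0:
        raise EmptyInputError(f"{path}: no amino-acid heavy atoms found")

    from biotite.sequence import ProteinSequence

    residues: list[ResidueRecord] = []
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for lo, hi in zip(starts[:-1], starts[1:]):
        sub = arr[lo:hi]
        try:
            aa = ProteinSequence.convert_letter_3to1(sub.res_name[0])
        except Exception:
            aa = "X"
        atoms = tuple(
            Atom(
                name=sub.atom_name[i],
                element=sub.element[i],
                coords=sub.coord[i],
                radius=radius_for(sub.element[i], radii),
            )
            for i in range(sub.array_length())
        )
        icode = sub.ins_code[0].strip() if "ins_code" in sub.get_annotation_categories() else ""
        residues.append(
            ResidueRecord(
                protein_id=path.stem,
                chain=str(sub.chain_id[0]),
                resnum=int(sub.res_id[0]),
                icode=icode,
                aa=aa,
                atoms=atoms,
            )
        )
    return Protein(protein_id=path.stem, residues=residues)


# ---------------------------------------------------------------------------
# Feature table I/O


@dataclass(frozen=True)
class FeatureRow:
    protein_id: str
    aa: str
    attributes: np.ndarray  # (26,)
    asa_complex: float
    asa_unbound: float
    rel_acc: float


@dataclass
class FeatureTable:
    """Mapping residue key -> features, plus the PSSM-only mode flag.

    ``pssm_only`` is set when the optional structural-conservation column is
    absent from the file (the case where no structural neighbours exist and
    only the PSSM should enter the kernel); the missing attribute is stored
    as 0 so the vector keeps its fixed length.
    """

    rows: dict[ResKey, FeatureRow]
    pssm_only: bool = False

    def __len__(self) -> int:
        return len(self.rows)

    def __getitem__(self, key: ResKey) -> FeatureRow:
        return self.rows[key]


def _parse_icode(token: str) -> str:
    return "" if token == "-" else token


def _format_icode(icode: str) -> str:
    return icode if icode else "-"


def read_feature_table(tsv_path: str | Path) -> FeatureTable:
    """Read the per-residue feature TSV (documented column contract).

    The header must list exactly the documented columns; ``strcn`` may be
    absent, which switches on PSSM-only mode.  Any other deviation, a wrong
    per-row column count, or a non-numeric cell is a :class:`FormatError`.
    """
    path = Path(tsv_path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty feature table")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header == FEATURE_TABLE_COLUMNS:
        pssm_only = False
        columns = FEATURE_TABLE_COLUMNS
    elif header == _PSSM_ONLY_COLUMNS:
        pssm_only = True
        columns = _PSSM_ONLY_COLUMNS
    else:
        raise FormatError(
            f"{path}: header does not match the feature-table contract "
            f"(got {len(header)} columns)"
        )

    rows: dict[ResKey, FeatureRow] = {}
    for lineno, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise FormatError(
                f"{path}: row {lineno}: expected {len(columns)} columns, "
                f"got {len(cells)}"
            )
        rec = dict(zip(columns, cells))
        try:
            numeric = {
                name: float(rec[name])
                for name in columns
                if name not in ("protein_id", "chain", "icode", "aa")
            }
        except ValueError as exc:
            raise FormatError(f"{path}: row {lineno}: non-numeric cell: {exc}") from exc
        attrs = np.zeros(N_ATTRIBUTES)
        for i, name in enumerate(ATTRIBUTE_NAMES):
            if pssm_only and name == "strcn":
                continue
            attrs[i] = numeric[name]
        key: ResKey = (rec["chain"], int(numeric["resnum"]), _parse_icode(rec["icode"]))
        rows[key] = FeatureRow(
            protein_id=rec["protein_id"],
            aa=rec["aa"],
            attributes=attrs,
            asa_complex=numeric["asa_complex"],
            asa_unbound=numeric["asa_unbound"],
            rel_acc=numeric["rel_acc"],
        )
    return FeatureTable(rows=rows, pssm_only=pssm_only)


def write_feature_table(table: FeatureTable | Mapping[ResKey, FeatureRow],
                        tsv_path: str | Path, *, float_fmt: str = "%.4f") -> None:
    """Write a feature table in the documented TSV dialect (deterministic bytes)."""
    rows = table.rows if isinstance(table, FeatureTable) else dict(table)
    pssm_only = table.pssm_only if isinstance(table, FeatureTable) else False
    columns = _PSSM_ONLY_COLUMNS if pssm_only else FEATURE_TABLE_COLUMNS
    out = ["\t".join(columns)]
    for key in sorted(rows):
        chain, resnum, icode = key
        row = rows[key]
        cells = [row.protein_id, chain, str(resnum), _format_icode(icode), row.aa,
                 float_fmt % row.asa_complex, float_fmt % row.asa_unbound,
                 float_fmt % row.rel_acc]
        for i, name in enumerate(ATTRIBUTE_NAMES):
            if pssm_only and name == "strcn":
                continue
            cells.append(float_fmt % row.attributes[i])
        out.append("\t".join(cells))
    Path(tsv_path).write_text("\n".join(out) + "\n")


def attach_features(protein: Protein, table: FeatureTable) -> Protein:
    """Return a copy of ``protein`` with attributes/ASA fields merged in."""
    residues = []
    for res in protein.residues:
        try:
            row = table[res.key]
        except KeyError:
            raise DataError(
                f"{protein.protein_id}: residue {res.key} missing from feature table"
            ) from None
        residues.append(
            replace(
                res,
                attributes=row.attributes.copy(),
                asa_complex=row.asa_complex,
                asa_unbound=row.asa_unbound,
                rel_acc=row.rel_acc,
            )
        )
    return Protein(protein_id=protein.protein_id, residues=residues,
                   interface_set=protein.interface_set)


def load_protein(pdb_path: str | Path, features_path: str | Path, *,
                 radii: Mapping[str, float] | None = None) -> tuple[Protein, FeatureTable]:
    """Read a structure and its feature table and merge them."""
    table = read_feature_table(features_path)
    protein = attach_features(read_structure(pdb_path, radii=radii), table)
    return protein, table


# ---------------------------------------------------------------------------
# Normalization


@dataclass
class Normalizer:
    """Per-attribute min-max scaler fitted on training-set residues.

    Fitting pools residues across all training proteins (the kernel compares
    residues across proteins, so per-protein scaling would distort
    inter-protein similarity).  A constant attribute maps to 0; applying to
    unseen values clips into [0, 1].  Applying to an already-normalized
    protein is a no-op, so application is idempotent.
    """

    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mins is not None

    def fit(self, proteins: Iterable[Protein] | Protein) -> "Normalizer":
        if isinstance(proteins, Protein):
            proteins = [proteins]
        stacks = [
            res.attributes
            for prot in proteins
            for res in prot.residues
            if res.attributes is not None
        ]
        if not stacks:
            raise EmptyInputError("normalizer fit requires at least one residue with attributes")
        data = np.stack(stacks)
        self.mins = data.min(axis=0)
        self.maxs = data.max(axis=0)
        return self

    def transform_values(self, attrs: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise StateError("normalizer has not been fitted")
        span = self.maxs - self.mins
        out = np.zeros_like(attrs, dtype=float)
        nonconst = span > 0
        out[..., nonconst] = (attrs[..., nonconst] - self.mins[nonconst]) / span[nonconst]
        return np.clip(out, 0.0, 1.0)

    def transform(self, protein: Protein) -> Protein:
        if not self.fitted:
            raise StateError("normalizer has not been fitted")
        if protein.normalized:
            return protein
        if not protein.has_features():
            raise DataError(f"{protein.protein_id}: residues without attributes")
        residues = [
            replace(res, attributes=self.transform_values(res.attributes))
            for res in protein.residues
        ]
        return Protein(protein_id=protein.protein_id, residues=residues,
                       interface_set=protein.interface_set, normalized=True)


def fit_normalizer(training_proteins: Iterable[Protein] | Protein) -> Normalizer:
    """Fit a min-max normalizer on the pooled residues of the training proteins."""
    return Normalizer().fit(training_proteins)


def apply_normalizer(normalizer: Normalizer, protein: Protein) -> Protein:
    """Scale a protein's attributes into [0, 1] with a fitted normalizer."""
    return normalizer.transform(protein)


def load_dataset(directory: str | Path, *,
                 radii: Mapping[str, float] | None = None) -> list[Protein]:
    """Load every ``<id>.pdb`` + ``<id>.tsv`` pair in a directory (sorted by id)."""
    root = Path(directory)
    proteins = []
    for pdb_path in sorted(root.glob("*.pdb")):
        tsv_path = pdb_path.with_suffix(".tsv")
        if not tsv_path.exists():
            raise DataError(f"{pdb_path}: no matching feature table {tsv_path.name}")
        protein, _ = load_protein(pdb_path, tsv_path, radii=radii)
        proteins.append(protein)
    if not proteins:
        raise EmptyInputError(f"{root}: no PDB/TSV pairs found")
    return proteins


def key_to_str(key: ResKey) -> str:
    chain, resnum, icode = key
    return f"{chain}{resnum}{icode}"


def str_to_key(text: str) -> ResKey:
    """Inverse of :func:`key_to_str` (chain is the leading non-digit run)."""
    i = 0
    while i < len(text) and not text[i].isdigit() and text[i] not in "-":
        i += 1
    j = i
    if j < len(text) and text[j] == "-":
        j += 1
    while j < len(text) and text[j].isdigit():
        j += 1
    if i == j:
        raise FormatError(f"cannot parse residue key {text!r}")
    return (text[:i], int(text[i:j]), text[j:])
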