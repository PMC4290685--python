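"""Structure reading, feature-table I/O, and attribute normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchkernel.errors import EmptyInputError, FormatError, StateError
from patchkernel.features import (
    ATTRIBUTE_NAMES,
    FEATURE_TABLE_COLUMNS,
    FeatureRow,
    FeatureTable,
    N_ATTRIBUTES,
    apply_normalizer,
    fit_normalizer,
    key_to_str,
    read_feature_table,
    read_structure,
    str_to_key,
    write_feature_table,
)

from conftest import make_protein


def _pdb_line(serial, name, altloc, resname, chain, resseq, xyz, occ, element):
    x, y, z = xyz
    return (
        f"ATOM  {serial:>5d}  {name:<3s}{altloc:1s}{resname:>3s} {chain:1s}"
        f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Three residues; res 1 has a hydrogen, res 2 has two altlocs (A at
    occupancy 0.6, B at 0.4)."""
    lines = [
        _pdb_line(1, "CA", " ", "ALA", "A", 1, (0.0, 0.0, 0.0), 1.0, "C"),
        _pdb_line(2, "HA", " ", "ALA", "A", 1, (0.5, 0.5, 0.5), 1.0, "H"),
        _pdb_line(3, "CA", "A", "GLY", "A", 2, (3.8, 0.0, 0.0), 0.6, "C"),
        _pdb_line(4, "CA", "B", "GLY", "A", 2, (4.8, 0.0, 0.0), 0.4, "C"),
        _pdb_line(5, "CA", " ", "SER", "A", 3, (7.6, 0.0, 0.0), 1.0, "C"),
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadStructure:
    def test_residue_count_preserved(self, toy_pdb):
        protein = read_structure(toy_pdb)
        assert len(protein) == 3
        assert protein.keys() == [("A", 1, ""), ("A", 2, ""), ("A", 3, "")]

    def test_hydrogens_excluded(self, toy_pdb):
        protein = read_structure(toy_pdb)
        elements = {a.element for r in protein.residues for a in r.atoms}
        assert "H" not in elements
        assert len(protein.residue(("A", 1, "")).atoms) == 1

    def test_altloc_resolved_to_highest_occupancy(self, toy_pdb):
        protein = read_structure(toy_pdb)
        res2 = protein.residue(("A", 2, ""))
        assert len(res2.atoms) == 1
        np.testing.assert_allclose(res2.atoms[0].coords, [3.8, 0.0, 0.0])

    def test_unparseable_file_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_bytes(b"\x00\xff not a pdb \x00")
        with pytest.raises((FormatError, EmptyInputError)):
            read_structure(bad)

    def test_no_residues_is_empty_input_error(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyInputError):
            read_structure(empty)

    def test_element_radii_from_table(self, toy_pdb):
        protein = read_structure(toy_pdb, radii={"C": 2.0})
        assert protein.residues[0].atoms[0].radius == 2.0


def _table_text(rows, columns=FEATURE_TABLE_COLUMNS):
    return "\n".join(["\t".join(columns)] + rows) + "\n"


def _row(resnum, value=0.5):
    prefix = ["prot", "A", str(resnum), "-", "G", "10.0", "12.0", "40.0"]
    return "\t".join(prefix + [f"{value}"] * N_ATTRIBUTES)


class TestFeatureTable:
    def test_well_formed_table(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(_table_text([_row(1), _row(2)]))
        table = read_feature_table(path)
        assert len(table) == 2
        assert not table.pssm_only
        row = table[("A", 1, "")]
        assert row.attributes.shape == (N_ATTRIBUTES,)
        assert row.asa_unbound == 12.0

    def test_missing_pssm_column_is_format_error(self, tmp_path):
        columns = [c for c in FEATURE_TABLE_COLUMNS if c != "pssm_W"]
        path = tmp_path / "t.tsv"
        path.write_text(_table_text([], columns=tuple(columns)))
        with pytest.raises(FormatError):
            read_feature_table(path)

    def test_absent_strcn_column_sets_pssm_only(self, tmp_path):
        columns = tuple(c for c in FEATURE_TABLE_COLUMNS if c != "strcn")
        prefix = ["prot", "A", "1", "-", "G", "10.0", "12.0", "40.0"]
        row = "\t".join(prefix + ["0.5"] * (N_ATTRIBUTES - 1))
        path = tmp_path / "t.tsv"
        path.write_text(_table_text([row], columns=columns))
        table = read_feature_table(path)
        assert table.pssm_only
        # the missing attribute is carried as 0 to keep the 26-vector shape
        assert table[("A", 1, "")].attributes[ATTRIBUTE_NAMES.index("strcn")] == 0.0

    def test_wrong_cell_count_names_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(_table_text([_row(1) + "\textra"]))
        with pytest.raises(FormatError, match="row 1"):
            read_feature_table(path)

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(_table_text([_row(1), _row(2, value="oops")]))
        with pytest.raises(FormatError, match="row 2"):
            read_feature_table(path)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = {
            ("A", i, ""): FeatureRow(
                protein_id="p", aa="K",
                attributes=np.round(rng.random(N_ATTRIBUTES), 4),
                asa_complex=10.0, asa_unbound=12.5, rel_acc=33.25,
            )
            for i in range(1, 5)
        }
        path = tmp_path / "t.tsv"
        write_feature_table(FeatureTable(rows=rows), path)
        first = path.read_text()
        back = read_feature_table(path)
        assert set(back.rows) == set(rows)
        for key in rows:
            np.testing.assert_allclose(back[key].attributes, rows[key].attributes)
        write_feature_table(back, tmp_path / "t2.tsv")
        assert (tmp_path / "t2.tsv").read_text() == first


class TestNormalizer:
    def _protein_with_attr0(self, values):
        n = len(values)
        coords = [(4.0 * i, 0.0, 0.0) for i in range(n)]
        attrs = np.full((n, N_ATTRIBUTES), 0.5)
        attrs[:, 0] = values
        return make_protein(coords, attrs)

    def test_min_max_definition(self):
        protein = self._protein_with_attr0([2.0, 4.0, 6.0])
        out = fit_normalizer(protein).transform(protein)
        np.testing.assert_allclose([r.attributes[0] for r in out.residues],
                                   [0.0, 0.5, 1.0])

    def test_constant_attribute_maps_to_zero(self):
        protein = self._protein_with_attr0([3.0, 3.0, 3.0])
        out = fit_normalizer(protein).transform(protein)
        assert all(r.attributes[0] == 0.0 for r in out.residues)

    def test_unseen_values_clip_into_unit_interval(self):
        train = self._protein_with_attr0([2.0, 6.0])
        norm = fit_normalizer(train)
        test = self._protein_with_attr0([8.0, 1.0])
        out = norm.transform(test)
        assert out.residues[0].attributes[0] == 1.0
        assert out.residues[1].attributes[0] == 0.0

    def test_unfitted_normalizer_is_state_error(self):
        from patchkernel.features import Normalizer

        with pytest.raises(StateError):
            Normalizer().transform(self._protein_with_attr0([1.0]))

    def test_application_is_idempotent(self):
        protein = self._protein_with_attr0([2.0, 4.0, 6.0])
        norm = fit_normalizer(protein)
        once = apply_normalizer(norm, protein)
        twice = apply_normalizer(norm, once)
        for a, b in zip(once.residues, twice.residues):
            np.testing.assert_array_equal(a.attributes, b.attributes)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.data())
    def test_output_always_in_unit_interval(self, data):
        rng_seed = data.draw(st.integers(0, 2**31 - 1))
        rng = np.random.default_rng(rng_seed)
        n_train, n_test = rng.integers(1, 8, size=2)
        scale = rng.uniform(0.1, 100.0)
        train = make_protein(
            [(4.0 * i, 0.0, 0.0) for i in range(n_train)],
            scale * rng.standard_normal((n_train, N_ATTRIBUTES)),
        )
        test = make_protein(
            [(4.0 * i, 0.0, 0.0) for i in range(n_test)],
            scale * rng.standard_normal((n_test, N_ATTRIBUTES)),
        )
        out = fit_normalizer(train).transform(test)
        for res in out.residues:
            assert np.all(res.attributes >= 0.0)
            assert np.all(res.attributes <= 1.0)


def test_key_string_round_trip():
    for key in [("A", 12, ""), ("B", 5, "A"), ("AB", -3, "")]:
        assert str_to_key(key_to_str(key)) == key
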