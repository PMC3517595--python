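"""PDB reading/writing, completeness checking, segment extraction."""

import numpy as np
import pytest

from motifstruct.errors import (
    EmptyStructureError,
    ExtractionError,
    PDBFormatError,
    StructureLookupError,
)
from motifstruct.structure_io import (
    AtomRecord,
    CompletenessPolicy,
    StructureModel,
    check_completeness,
    extract_segment,
    read_pdb,
    segment_to_model,
    write_pdb,
)


def _atom(chain, num, resname, name, pos, **kw):
    return AtomRecord(chain=chain, residue_number=num, insertion_code="",
                      residue_name=resname, atom_name=name, position=pos,
                      **kw)


@pytest.fixture
def model(three_residue_pdb):
    return read_pdb(three_residue_pdb, "FIX1")


class TestReadPDB:
    def test_residues_and_coordinates(self, model):
        assert model.chains == ["A"]
        res = model.residues("A")
        assert [r.name for r in res] == ["ALA", "GLY", "TYR"]
        np.testing.assert_allclose(res[0].atoms["CA"].position,
                                   (1.458, 0.0, 0.0))
        assert model.sequence("A") == "AGY"

    def test_altloc_highest_occupancy_kept(self):
        text = (
            "ATOM      1  CA BALA A   1      21.000  22.000  23.000  0.40\n"
            "ATOM      2  CA AALA A   1      11.000  12.000  13.000  0.60\n"
            "END\n")
        m = read_pdb(text, "ALT")
        assert len(m.atoms) == 1
        assert m.atoms[0].altloc == "A"
        np.testing.assert_allclose(m.atoms[0].position, (11.0, 12.0, 13.0))

    def test_altloc_tie_prefers_A(self):
        text = (
            "ATOM      1  CA BALA A   1      21.000  22.000  23.000  0.50\n"
            "ATOM      2  CA AALA A   1      11.000  12.000  13.000  0.50\n"
            "END\n")
        m = read_pdb(text, "ALT")
        assert m.atoms[0].altloc == "A"

    def test_model_one_only(self):
        text = (
            "MODEL        1\n"
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00\n"
            "ATOM      2  CA  ALA A   2       4.000   5.000   6.000  1.00\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      3  CA  ALA A   1       9.000   9.000   9.000  1.00\n"
            "ATOM      4  CA  ALA A   2       8.000   8.000   8.000  1.00\n"
            "ENDMDL\nEND\n")
        # independent text scan: 2 atoms in model 1
        n_model1 = 0
        in_model1 = False
        for line in text.splitlines():
            if line.startswith("MODEL"):
                in_model1 = line.split()[1] == "1"
            if line.startswith("ATOM") and in_model1:
                n_model1 += 1
        m = read_pdb(text, "NMR")
        assert len(m.atoms) == n_model1 == 2
        np.testing.assert_allclose(m.atoms[0].position, (1.0, 2.0, 3.0))

    def test_empty_structure_raises(self):
        with pytest.raises(EmptyStructureError):
            read_pdb("REMARK nothing here\nEND\n")

    def test_malformed_line_skipped_with_warning(self, three_residue_pdb):
        broken = three_residue_pdb.replace(
            "ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00",
            "ATOM      5  N   GLY A   2       3.332   garbage")
        with pytest.warns(UserWarning, match="malformed"):
            m = read_pdb(broken, "BRK")
        assert "N" not in {r.name: r for r in m.residues("A")}.get("GLY").atoms

    def test_hydrogens_ignored(self):
        text = (
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00\n"
            "ATOM      2  H   ALA A   1       1.500   2.500   3.500  1.00"
            "           H\n"
            "END\n")
        assert len(read_pdb(text, "HYD").atoms) == 1


class TestCompleteness:
    def test_ca_only_minimal(self, model):
        rep = check_completeness(model, "A", 1, 3,
                                 CompletenessPolicy(frozenset({"CA"}),
                                                    frozenset({"CA"})))
        assert rep.complete and not rep.missing_preferred

    def test_missing_ca_reported(self, three_residue_pdb):
        text = "\n".join(l for l in three_residue_pdb.splitlines()
                         if not ("CA  GLY" in l)) + "\n"
        m = read_pdb(text, "NOCA")
        rep = check_completeness(m, "A", 1, 3)
        assert not rep.complete
        assert ("A", 2, "CA") in rep.missing_minimal

    def test_gly_cb_excused(self, model):
        policy = CompletenessPolicy(frozenset({"CA"}),
                                    frozenset({"N", "CA", "C", "CB"}))
        rep = check_completeness(model, "A", 1, 3, policy)
        assert rep.complete
        assert ("A", 2) in rep.gly_exceptions
        assert all(entry[2] != "CB" or entry[1] != 2
                   for entry in rep.missing_preferred)

    def test_missing_range_raises(self, model):
        with pytest.raises(StructureLookupError):
            check_completeness(model, "A", 1, 9)
        with pytest.raises(StructureLookupError):
            check_completeness(model, "Z", 1, 3)


class TestExtract:
    def test_counts_with_gly_exception(self, model):
        seg = extract_segment(model, "A", 1, 3)
        # 3 residues x 4 atoms, minus the Gly CB
        assert seg.n_atoms == 11
        assert seg.exceptions == (1,)
        assert seg.residue_sequence == "AGY"

    def test_deterministic_order(self, model):
        seg = extract_segment(model, "A", 1, 1, ("N", "CA", "C", "CB"))
        np.testing.assert_allclose(seg.coordinates[1], (1.458, 0.0, 0.0))

    def test_missing_selected_atom_raises(self, model):
        with pytest.raises(ExtractionError, match="missing selected atom O"):
            extract_segment(model, "A", 1, 3, ("CA", "CB", "O"))

    def test_modified_residue_maps_to_parent(self):
        text = (
            "HETATM    1  N   PTR A   1       0.000   0.000   0.000  1.00\n"
            "HETATM    2  CA  PTR A   1       1.458   0.000   0.000  1.00\n"
            "HETATM    3  C   PTR A   1       2.009   1.420   0.000  1.00\n"
            "HETATM    4  CB  PTR A   1       1.980  -0.770  -1.210  1.00\n"
            "END\n")
        m = read_pdb(text, "PTR")
        seg = extract_segment(m, "A", 1, 1)
        assert seg.residue_sequence == "Y"


class TestWritePDB:
    def test_round_trip_identity(self, model):
        again = read_pdb(write_pdb(model), "FIX1")
        assert len(again.atoms) == len(model.atoms)
        for a, b in zip(model.atoms, again.atoms):
            assert (a.chain, a.residue_number, a.residue_name,
                    a.atom_name) == (b.chain, b.residue_number,
                                     b.residue_name, b.atom_name)
            np.testing.assert_allclose(a.position, b.position, atol=5e-4)

    def test_segment_written_as_atom_lines(self, model):
        seg = extract_segment(model, "A", 1, 1, ("N", "CA", "C"))
        text = write_pdb(segment_to_model(seg))
        atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == 3
        assert text.rstrip().endswith("END")

    def test_long_chain_id_rejected(self):
        m = StructureModel("BAD", [_atom("AB", 1, "ALA", "CA", (0, 0, 0))])
        with pytest.raises(PDBFormatError):
            write_pdb(m)

    def test_out_of_range_coordinate_rejected(self):
        m = StructureModel("BAD", [_atom("A", 1, "ALA", "CA",
                                         (123456.0, 0, 0))])
        with pytest.raises(PDBFormatError):
            write_pdb(m)
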