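"""PDB/FASTA I/O, the coordinate model and atom selections."""

import io

import numpy as np
import pytest

from linkerlens import structio, synthdata
from linkerlens.structio import Atom, AtomSelection, PdbParseError

TOY_PDB = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       2.500   2.000   3.000  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60 10.00           C
ATOM      2  CA BALA A   1       1.000   0.000   0.000  0.40 10.00           C
END
"""


class TestReadPdb:
    def test_two_atom_toy(self):
        s = structio.read_pdb(TOY_PDB)
        assert len(s.chains) == 1
        assert len(s.chains[0].residues) == 1
        res = s.chains[0].residues[0]
        assert len(res.atoms) == 2
        assert res.resname == "ALA" and res.resseq == 1
        np.testing.assert_allclose(res.atoms[1].coords, [2.5, 2.0, 3.0])

    def test_altloc_highest_occupancy_wins(self):
        s = structio.read_pdb(ALTLOC_PDB)
        atoms = s.chains[0].residues[0].atoms
        assert len(atoms) == 1
        np.testing.assert_allclose(atoms[0].coords, [0.0, 0.0, 0.0])

    def test_altloc_tie_prefers_alphabetical(self):
        tie = ALTLOC_PDB.replace("0.60", "0.50").replace("0.40", "0.50")
        s = structio.read_pdb(tie)
        atoms = s.chains[0].residues[0].atoms
        assert len(atoms) == 1
        np.testing.assert_allclose(atoms[0].coords, [0.0, 0.0, 0.0])

    def test_malformed_record_names_line(self):
        bad = TOY_PDB.replace("2.500", "xx.yy")
        with pytest.raises(PdbParseError, match="line 2"):
            structio.read_pdb(bad)

    def test_empty_input_is_an_error(self):
        with pytest.raises(PdbParseError):
            structio.read_pdb("REMARK nothing here\nEND\n")

    def test_element_inferred_from_name_when_column_absent(self):
        no_elem = "\n".join(line[:66] for line in TOY_PDB.splitlines()) + "\n"
        s = structio.read_pdb(no_elem)
        assert [a.element for a in s.atoms()] == ["N", "C"]


class TestWritePdb:
    def test_single_atom_emits_one_atom_line(self):
        s = structio.read_pdb(TOY_PDB)
        s.chains[0].residues[0].atoms = s.chains[0].residues[0].atoms[:1]
        text = structio.write_pdb(s)
        atom_lines = [l for l in text.splitlines() if l.startswith("ATOM")]
        assert len(atom_lines) == 1
        assert text.rstrip().endswith("END")

    def test_resseq_renders_right_justified_in_columns_23_26(self):
        s = synthdata.build_helix(1, start_resseq=300)
        line = structio.write_pdb(s).splitlines()[0]
        assert line[22:26] == " 300"

    def test_roundtrip_preserves_fields(self):
        pdb = TOY_PDB.replace("ALA A   1 ", "ALA A   1A")  # insertion code A
        s = structio.read_pdb(pdb)
        s2 = structio.read_pdb(structio.write_pdb(s))
        r, r2 = s.chains[0].residues[0], s2.chains[0].residues[0]
        assert (r.resseq, r.icode, r.resname) == (r2.resseq, r2.icode, r2.resname)
        for a, a2 in zip(r.atoms, r2.atoms):
            assert a.name == a2.name
            np.testing.assert_allclose(a.coords, a2.coords, atol=5e-4)
            assert a.occupancy == a2.occupancy and a.bfactor == a2.bfactor

    def test_roundtrip_identity_on_synthetic_structure(self):
        s = synthdata.build_helix(25, start_resseq=290)
        text = structio.write_pdb(s)
        text2 = structio.write_pdb(structio.read_pdb(text))
        assert text == text2  # read∘write∘read is the identity

    def test_gemmi_agrees_on_chain_residue_atom_counts(self):
        gemmi = pytest.importorskip("gemmi")
        s = synthdata.build_helix(12, start_resseq=300)
        g = gemmi.read_pdb_string(structio.write_pdb(s))
        chain = g[0]["A"]
        assert len(chain) == 12
        assert chain[0].seqid.num == 300
        np.testing.assert_allclose(
            [chain[0][0].pos.x, chain[0][0].pos.y, chain[0][0].pos.z],
            s.chains[0].residues[0].atoms[0].coords,
            atol=5e-4,
        )

    def test_multi_model_round_trip(self):
        s1 = synthdata.build_helix(4)
        s2 = synthdata.build_helix(4, radius=2.5)
        text = structio.write_pdb([s1, s2], times_ns=[0.0, 1.0])
        models = structio.read_pdb_models(text)
        assert len(models) == 2
        np.testing.assert_allclose(models[1].coords(), s2.coords(), atol=5e-4)


class TestSelection:
    @pytest.fixture
    def mixed_residue_structure(self):
        res_atoms = [Atom("N", "N", [0, 0, 0]), Atom("CA", "C", [1, 0, 0]),
                     Atom("C", "C", [2, 0, 0]), Atom("O", "O", [3, 0, 0]),
                     Atom("CB", "C", [4, 0, 0])]
        h_atoms = [Atom(f"H{i}", "H", [5 + i, 0, 0]) for i in range(4)]
        res = structio.Residue("ALA", 1, atoms=res_atoms + h_atoms)
        return structio.Structure("toy", [structio.Chain("A", [res])])

    def test_heavy_filter_drops_hydrogens(self, mixed_residue_structure):
        atoms = structio.resolve_selection(
            mixed_residue_structure, AtomSelection("A", atom_filter="heavy")
        )
        assert len(atoms) == 5
        assert all(a.is_heavy for a in atoms)

    def test_heavy_and_hydrogen_partition_the_atom_set(self, mixed_residue_structure):
        s = mixed_residue_structure
        all_atoms = structio.resolve_selection(s, AtomSelection("A"))
        heavy = structio.resolve_selection(s, AtomSelection("A", atom_filter="heavy"))
        assert len(all_atoms) == len(heavy) + sum(1 for a in all_atoms if not a.is_heavy)

    def test_inclusive_residue_range_counts_20(self):
        # a 515-residue chain numbered from 1: range 300-319 selects 20 Cα
        s = synthdata.build_helix(515, start_resseq=1)
        atoms = structio.resolve_selection(
            s, AtomSelection("A", resseq_range=(300, 319), atom_filter="ca")
        )
        assert len(atoms) == 20

    def test_ca_filter_returns_one_atom_per_residue(self, ideal_helix20):
        atoms = structio.resolve_selection(
            ideal_helix20, AtomSelection("A", atom_filter="ca")
        )
        assert len(atoms) == 20
        assert all(a.name == "CA" for a in atoms)

    def test_unknown_chain_raises(self, ideal_helix20):
        with pytest.raises(KeyError):
            structio.resolve_selection(ideal_helix20, AtomSelection("Z"))

    def test_empty_result_is_not_an_error(self, ideal_helix20):
        atoms = structio.resolve_selection(
            ideal_helix20, AtomSelection("A", resseq_range=(1, 2))
        )
        assert atoms == []

    def test_resolution_is_idempotent_and_order_stable(self, ideal_helix20):
        sel = AtomSelection("A", resseq_range=(305, 310), atom_filter="ca")
        a1 = structio.resolve_selection(ideal_helix20, sel)
        a2 = structio.resolve_selection(ideal_helix20, sel)
        assert [id(x) for x in a1] == [id(x) for x in a2]
        assert [x.coords[2] for x in a1] == sorted(x.coords[2] for x in a1)


class TestFasta:
    def test_roundtrip(self):
        records = [("seq1", "MAREGQ" * 15), ("seq2", "PLP")]
        parsed = structio.read_fasta(structio.write_fasta(records))
        assert parsed == records

    def test_data_before_header_raises(self):
        with pytest.raises(ValueError):
            structio.read_fasta("MARELK\n>late\nMM\n")
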