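import numpy as np
import pytest

from conftest import TOY_PDB, backbones_of
from oracles import ks_assign, sampled_asa

from rinstab.datasets import make_fixture_structure
from rinstab.structure_io import (
    Structure,
    StructureError,
    assign_secondary_structure,
    classify_exposure,
    compute_rsa,
    parse_pdb,
    residue_table,
    write_pdb,
)


class TestParsePDB:
    def test_toy_readback(self):
        s = parse_pdb(TOY_PDB, "A")
        assert s.length == 3
        assert [r.aa for r in s.residues] == ["ALA", "GLY", "ALA"]
        assert s.sequence == "AGA"
        np.testing.assert_allclose(s.residues[0].atom("CA").coord, [1.458, 0, 0])

    def test_altloc_keeps_highest_occupancy(self):
        lines = []
        for line in TOY_PDB.splitlines():
            if line.startswith("ATOM") and " GLY A   2 " in line:
                a = line[:16] + "A" + line[17:54] + "  0.60" + line[60:]
                b = line[:16] + "B" + line[17:30] + f"{float(line[30:38]) + 0.5:8.3f}" + line[38:54] + "  0.40" + line[60:]
                lines += [a, b]
            else:
                lines.append(line)
        s = parse_pdb("\n".join(lines), "A")
        res2 = s.residues[1]
        assert all(a.occupancy == pytest.approx(0.6) for a in res2.atoms)
        # altloc A coordinates retained (x not shifted by +0.5)
        assert res2.atom("CA").coord[0] == pytest.approx(3.984)

    def test_model_selection(self):
        shifted = TOY_PDB.replace("END\n", "").replace("TER\n", "TER\nENDMDL\n")
        model2 = TOY_PDB.replace("0.000   0.000   0.000", "9.000   0.000   0.000")
        two_models = ("MODEL     1\n" + shifted + "MODEL     2\n"
                      + model2.replace("END\n", "ENDMDL\nEND\n"))
        s0 = parse_pdb(two_models, "A", model_index=0)
        s1 = parse_pdb(two_models, "A", model_index=1)
        assert s0.residues[0].atom("N").coord[0] == pytest.approx(0.0)
        assert s1.residues[0].atom("N").coord[0] == pytest.approx(9.0)

    def test_missing_chain(self):
        with pytest.raises(StructureError, match="chain not found"):
            parse_pdb(TOY_PDB, "B")

    def test_hetatm_and_waters_excluded(self):
        text = TOY_PDB.replace(
            "TER", "HETATM   15  O   HOH A   9       0.000   9.000   0.000  1.00  0.00           O\nTER")
        assert parse_pdb(text, "A").length == 3

    def test_format_error_reports_line(self):
        bad = TOY_PDB.replace("1.458", "xx.xx")
        with pytest.raises(StructureError, match="line 2"):
            parse_pdb(bad, "A")

    def test_roundtrip_preserves_geometry(self, helix):
        s, pdb_text = helix
        s2 = parse_pdb(pdb_text, "A")
        assert s2.length == s.length
        assert s2.sequence == s.sequence
        for r1, r2 in zip(s.residues, s2.residues):
            for a1 in r1.atoms:
                np.testing.assert_allclose(r2.atom(a1.name).coord, a1.coord, atol=1e-3)


class TestSecondaryStructure:
    @pytest.mark.parametrize("kind,n", [("helix", 15), ("extended", 15), ("hairpin", 16)])
    def test_matches_independent_oracle(self, kind, n):
        s, _ = make_fixture_structure(kind, n)
        assign_secondary_structure(s)
        expected = ks_assign(backbones_of(s), {i for i, r in enumerate(s.residues)
                                               if r.aa == "PRO"})
        assert [r.ss for r in s.residues] == expected

    def test_helix_core_is_helical(self):
        s, _ = make_fixture_structure("helix", 15)
        assign_secondary_structure(s)
        assert all(s.residues[i].ss == "H" for i in range(2, 12))

    def test_extended_chain_is_coil(self):
        s, _ = make_fixture_structure("extended", 15)
        assign_secondary_structure(s)
        assert all(r.ss == "C" for r in s.residues)

    def test_hairpin_strands_are_strand(self):
        s, _ = make_fixture_structure("hairpin", 16)
        assign_secondary_structure(s)
        labels = [r.ss for r in s.residues]
        assert labels.count("E") >= 6
        assert "H" not in labels

    def test_tiny_chain_all_coil(self):
        s = parse_pdb(TOY_PDB, "A")
        assign_secondary_structure(s)
        assert [r.ss for r in s.residues] == ["C", "C", "C"]


class TestRSA:
    def test_lone_residue_fully_exposed(self, helix):
        s, _ = helix
        lone = Structure("x", "A", [s.residues[7]])
        compute_rsa(lone)
        assert 0.9 <= lone.residues[0].rsa <= 1.0

    def test_caged_residue_buried(self):
        s, _ = make_fixture_structure("cage")
        compute_rsa(s)
        assert s.residues[0].rsa < 0.05

    def test_agrees_with_sampled_asa(self, helix):
        s, _ = helix
        compute_rsa(s)
        atoms = [(a.coord, a.element, i) for i, r in enumerate(s.residues)
                 for a in r.heavy_atoms()]
        coords = np.array([a[0] for a in atoms])
        est = sampled_asa(coords, [a[1] for a in atoms], seed=5)
        per_res = np.zeros(s.length)
        for (_, _, i), asa in zip(atoms, est):
            per_res[i] += asa
        ours = np.array([r.asa for r in s.residues])
        np.testing.assert_allclose(ours, per_res, rtol=0.15, atol=4.0)

    def test_removing_occluder_never_decreases_asa(self):
        s, _ = make_fixture_structure("cage")
        compute_rsa(s)
        asa_full = s.residues[0].asa
        s_fewer = Structure(s.pdb_id, "A", [s.residues[0]] + s.residues[2:])
        compute_rsa(s_fewer)
        assert s_fewer.residues[0].asa >= asa_full - 1e-9

    def test_rsa_bounds(self, annotated_helix):
        assert all(0.0 <= r.rsa <= 1.0 for r in annotated_helix.residues)
        assert all(r.asa >= 0.0 for r in annotated_helix.residues)

    def test_exposure_boundary(self):
        assert classify_exposure(0.25) == "buried"
        assert classify_exposure(0.26) == "exposed"


def test_residue_table_columns(annotated_helix):
    df = residue_table(annotated_helix)
    assert list(df.columns) == ["chain", "seq_id", "aa", "ss", "asa", "rsa"]
    assert len(df) == annotated_helix.length
    assert set(df["ss"]) <= {"H", "E", "C"}


def test_write_pdb_is_valid_pdb(annotated_helix):
    text = write_pdb(annotated_helix)
    s2 = parse_pdb(text, "A")
    assert s2.sequence == annotated_helix.sequence


def test_dssp_file_override(tmp_path):
    from rinstab.structure_io import assign_from_dssp

    s = parse_pdb(TOY_PDB, "A")

    def dssp_line(num, resnum, chain, aa, ss, acc):
        line = f"{num:5d}{resnum:5d} {chain} {aa}  {ss}"
        return line.ljust(34) + f"{acc:4d}"

    dssp_text = "\n".join([
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC",
        dssp_line(1, 1, "A", "A", "H", 75),
        dssp_line(2, 2, "A", "G", "E", 40),
        dssp_line(3, 3, "A", "A", "T", 110),
    ]) + "\n"
    path = tmp_path / "toy.dssp"
    path.write_text(dssp_text)
    assign_from_dssp(s, path)
    assert [r.ss for r in s.residues] == ["H", "E", "C"]  # T maps to coil
    assert s.residues[0].asa == 75.0
    assert s.residues[0].rsa == pytest.approx(75.0 / 106.0)  # maxASA(ALA)
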