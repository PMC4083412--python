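import math

import numpy as np
import pytest

from rinstab.datasets import make_fixture_structure
from rinstab.profiles import (
    MSA,
    acp,
    build_reference_stats,
    conservation,
    default_reference_stats,
    evo_profile,
    load_external_scores,
    map_msa_to_structure,
    mutual_information,
    potential_scores,
    read_msa,
    ReferenceStats,
)
from rinstab.rin import build_rin
from rinstab.structure_io import compute_rsa


def _write_fasta(tmp_path, rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    path = tmp_path / "aln.fasta"
    path.write_text("".join(f">{i}\n{r}\n" for i, r in zip(ids, rows)))
    return path


class TestReadMSA:
    def test_basic(self, tmp_path):
        msa = read_msa(_write_fasta(tmp_path, ["ACD", "ACD", "ACD"]), "s0")
        assert msa.n_rows == 3 and msa.n_cols == 3 and msa.query_row == 0

    def test_gap_skipping_column_map(self, tmp_path):
        msa = read_msa(_write_fasta(tmp_path, ["A-CD", "AACD"]), "s0")
        assert msa.query_columns() == [0, 2, 3]

    def test_ragged_alignment_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format error"):
            read_msa(_write_fasta(tmp_path, ["ACDE", "ACDEF"]), "s0")

    def test_missing_query(self, tmp_path):
        with pytest.raises(ValueError, match="not found"):
            read_msa(_write_fasta(tmp_path, ["ACD"]), "nope")

    def test_structure_mismatch_names_position(self, tmp_path):
        s, _ = make_fixture_structure("helix", 4, sequence="ACDE")
        msa = read_msa(_write_fasta(tmp_path, ["AGDE"]), "s0")
        with pytest.raises(ValueError, match="position 2"):
            map_msa_to_structure(msa, s)


class TestConservation:
    def test_single_type_fully_conserved(self):
        msa = MSA(["a", "b"], ["A", "A"], 0)
        assert conservation(msa, 0) == 1.0

    def test_uniform_column_zero(self):
        rows = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
        msa = MSA([str(i) for i in range(20)], rows, 0)
        assert conservation(msa, 0) == pytest.approx(0.0)

    def test_two_state_column(self):
        msa = MSA(list("abcd"), ["A", "A", "C", "C"], 0)
        assert conservation(msa, 0) == pytest.approx(1 - 1 / math.log2(20), abs=1e-9)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDE"), 5)) for _ in range(30)]
        msa = MSA([str(i) for i in range(30)], rows, 0)
        perm = [rows[i] for i in rng.permutation(30)]
        msa_p = MSA([str(i) for i in range(30)], perm, 0)
        for col in range(5):
            assert conservation(msa, col) == pytest.approx(conservation(msa_p, col))


class TestMutualInformation:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.choice(list("ACDE"), 10000)
        b = rng.choice(list("ACDE"), 10000)
        rows = ["".join(p) for p in zip(a, b)]
        msa = MSA([str(i) for i in range(len(rows))], rows, 0)
        assert mutual_information(msa, 0, 1) < 0.01

    def test_copied_column_equals_entropy(self):
        rows = ["AA"] * 5 + ["CC"] * 5  # H = 1 bit
        msa = MSA([str(i) for i in range(10)], rows, 0)
        assert mutual_information(msa, 0, 1) == pytest.approx(1.0)

    def test_symmetry_nonnegativity_and_entropy_bound(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rows = ["".join(rng.choice(list("ACDEF"), 4)) for _ in range(40)]
            msa = MSA([str(i) for i in range(40)], rows, 0)
            i, j = rng.choice(4, 2, replace=False)
            mij = mutual_information(msa, int(i), int(j))
            mji = mutual_information(msa, int(j), int(i))
            assert mij == pytest.approx(mji, abs=1e-12)
            assert mij >= 0.0
            h_i = -sum(p * math.log2(p) for p in
                       np.unique([r[i] for r in rows], return_counts=True)[1] / 40)
            assert mij <= h_i + 1e-9

    def test_too_few_rows_zero(self):
        msa = MSA(["a", "b"], ["A-", "-C"], 0)
        assert mutual_information(msa, 0, 1) == 0.0


class TestACP:
    def test_deterministic_partner_full_purity(self):
        rows = ["AC", "AC", "AC", "DG"]
        msa = MSA(list("abcd"), rows, 0)
        assert acp(msa, 0, [1]) == 1.0

    def test_mixed_partner_lower_purity(self):
        rows = ["AC", "AG", "AC", "AG"]
        msa = MSA(list("abcd"), rows, 0)
        assert acp(msa, 0, [1]) == pytest.approx(0.5)

    def test_no_partners_defaults_to_one(self):
        msa = MSA(["a"], ["A"], 0)
        assert acp(msa, 0, []) == 1.0


class TestEvoProfile:
    def test_no_msa_neutral_defaults(self):
        s, _ = make_fixture_structure("helix", 6)
        with pytest.warns(UserWarning, match="no alignment"):
            evo = evo_profile(None, s)
        assert np.all(evo.conservation == 1.0)
        assert np.all(evo.mi == 0.0)
        assert np.all(evo.acp == 1.0)

    def test_profile_aligned_to_structure(self, tmp_path):
        s, _ = make_fixture_structure("helix", 4, sequence="ACDE")
        rows = ["ACDE", "AC-E", "GCDE"]
        path = tmp_path / "a.fasta"
        path.write_text("".join(f">s{i}\n{r}\n" for i, r in enumerate(rows)))
        msa = read_msa(path, "s0")
        evo = evo_profile(msa, s)
        assert len(evo) == 4
        assert np.all(np.isfinite(evo.conservation))
        assert evo.conservation[1] == 1.0  # column of all C


class TestPotentials:
    def test_uniform_reference_gives_zero_pairwise(self):
        s, _ = make_fixture_structure("helix", 8, sequence="ACDEFGHI")
        compute_rsa(s)
        net = build_rin(s)
        uniform = ReferenceStats(
            contact_obs=np.full((20, 20), 1 / 400),
            contact_exp=np.full((20, 20), 1 / 400),
            burial_given_aa=np.full(20, 0.5),
            aa_freq=np.full(20, 1 / 20),
        )
        scores = potential_scores(s, net, uniform)
        np.testing.assert_allclose(scores.pairwise, 0.0, atol=1e-12)
        np.testing.assert_allclose(scores.solvation, 0.0, atol=1e-12)

    def test_no_contacts_zero_pairwise(self):
        s, _ = make_fixture_structure("extended", 5)
        compute_rsa(s)
        net = build_rin(s)
        isolated = [i for i, r in enumerate(s.residues)
                    if not any(r.key in (e.u, e.v) for e in net.edges)]
        scores = potential_scores(s, net, default_reference_stats())
        for i in isolated:
            assert scores.pairwise[i] == 0.0

    def test_solvation_log_ratio(self):
        s, _ = make_fixture_structure("cage")  # central ALA is fully buried
        compute_rsa(s)
        net = build_rin(s)
        # reference where buried ALA is twice as common as background
        from rinstab._aa import AA_INDEX

        burial = np.full(20, 0.5)
        freq = np.full(20, 1 / 20)
        ref = ReferenceStats(np.full((20, 20), 1 / 400), np.full((20, 20), 1 / 400),
                             burial, freq)
        # P(aa|buried) uniform = background => solvation 0; now skew ALA
        burial2 = burial.copy()
        burial2[AA_INDEX["ALA"]] = 1.0  # ALA always buried
        ref2 = ReferenceStats(np.full((20, 20), 1 / 400), np.full((20, 20), 1 / 400),
                              burial2, freq)
        s0 = potential_scores(s, net, ref)
        s2 = potential_scores(s, net, ref2)
        p_buried = ref2.p_aa_given_state(True)[AA_INDEX["ALA"]]
        expected = -math.log(p_buried / (1 / 20))
        assert s0.solvation[0] == pytest.approx(0.0, abs=1e-12)
        assert s2.solvation[0] == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        # cutoff chosen away from any exact inter-atomic distance of the
        # fixture so float rotation noise cannot flip boundary contacts
        s, _ = make_fixture_structure("hairpin", 12, sequence="ACDEFGHIKLMN")
        compute_rsa(s)
        scores = potential_scores(s, build_rin(s, contact_cutoff=4.9),
                                  default_reference_stats())
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        s2, _ = make_fixture_structure("hairpin", 12, sequence="ACDEFGHIKLMN")
        for r in s2.residues:
            for a in r.atoms:
                a.coord = rot @ a.coord + shift
        compute_rsa(s2)
        scores2 = potential_scores(s2, build_rin(s2, contact_cutoff=4.9),
                                   default_reference_stats())
        np.testing.assert_allclose(scores2.pairwise, scores.pairwise, atol=1e-9)
        np.testing.assert_allclose(scores2.solvation, scores.solvation, atol=1e-9)

    def test_reference_stats_probabilities(self):
        stats = default_reference_stats()
        assert stats.contact_obs.sum() == pytest.approx(1.0)
        assert np.all(stats.contact_obs > 0)
        assert np.all((stats.burial_given_aa > 0) & (stats.burial_given_aa < 1))

    def test_external_override(self, tmp_path):
        s, _ = make_fixture_structure("helix", 4)
        path = tmp_path / "scores.tsv"
        path.write_text("position\tname\tvalue\n2\tpairwise\t-1.5\n2\tsolvation\t0.7\n")
        scores = load_external_scores(path, s)
        assert scores.pairwise[1] == -1.5
        assert scores.solvation[1] == 0.7
        assert scores.pairwise[0] == 0.0
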