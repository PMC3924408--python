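"""Composition encodings against brute-force oracles and invariants."""

import numpy as np
import pytest

from plaspred.features import (
    AMINO_ACIDS,
    ConfigurationError,
    DIMENSIONS,
    PSIBLAST_COLUMNS,
    PSSMProfile,
    amino_acid_composition,
    dipeptide_composition,
    encode,
    hybrid_composition,
    mock_pssm,
    parse_pssm,
    pssm_composition,
    pssm_provider,
    write_ascii_pssm,
    write_svmlight,
)
from plaspred.seqio import ProteinSequence, ValidationError

from conftest import random_protein

AA_IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def oracle_ac(residues):
    v = np.zeros(20)
    for ch in residues:
        v[AA_IDX[ch]] += 1
    return v / len(residues)


def oracle_dc(residues):
    v = np.zeros(400)
    for i in range(len(residues) - 1):
        v[20 * AA_IDX[residues[i]] + AA_IDX[residues[i + 1]]] += 1
    return v / (len(residues) - 1)


def oracle_pssm(profile, residues):
    """Brute-force double loop over positions and profile columns."""
    v = np.zeros((20, 20))
    for p, ch in enumerate(residues):
        for col, col_aa in enumerate(PSIBLAST_COLUMNS):
            s = 1.0 / (1.0 + np.exp(-float(profile.scores[p, col])))
            v[AA_IDX[ch], AA_IDX[col_aa]] += s
    return v.ravel() / len(residues)


class TestAminoAcidComposition:
    @pytest.mark.parametrize("residues,expected", [
        ("AAAA", {"A": 1.0}),
        (AMINO_ACIDS, {aa: 0.05 for aa in AMINO_ACIDS}),
        ("AAC", {"A": 2 / 3, "C": 1 / 3}),
    ])
    def test_examples(self, residues, expected):
        fv = amino_acid_composition(ProteinSequence("x", residues))
        for aa in AMINO_ACIDS:
            assert fv.values[AA_IDX[aa]] == pytest.approx(
                expected.get(aa, 0.0))

    def test_permutation_invariance(self, rng):
        seq = random_protein(rng, 80)
        perm = "".join(rng.permutation(list(seq.residues)))
        v1 = amino_acid_composition(seq).values
        v2 = amino_acid_composition(ProteinSequence("p", perm)).values
        np.testing.assert_allclose(v1, v2)


class TestDipeptideComposition:
    @pytest.mark.parametrize("residues,pairs", [
        ("AA", {"AA": 1.0}),
        ("ACA", {"AC": 0.5, "CA": 0.5}),
    ])
    def test_examples(self, residues, pairs):
        fv = dipeptide_composition(ProteinSequence("x", residues))
        for pair, frac in pairs.items():
            i = 20 * AA_IDX[pair[0]] + AA_IDX[pair[1]]
            assert fv.values[i] == pytest.approx(frac)
        assert fv.values.sum() == pytest.approx(1.0)

    def test_length_one_rejected(self):
        with pytest.raises(ValidationError):
            dipeptide_composition(ProteinSequence("x", "A"))

    def test_matches_brute_force_tally(self, rng):
        seq = random_protein(rng, 50)
        np.testing.assert_allclose(dipeptide_composition(seq).values,
                                   oracle_dc(seq.residues))

    def test_reversal_transposes(self, rng):
        seq = random_protein(rng, 60)
        rev = ProteinSequence("r", seq.residues[::-1])
        fwd = dipeptide_composition(seq).values.reshape(20, 20)
        bwd = dipeptide_composition(rev).values.reshape(20, 20)
        np.testing.assert_allclose(bwd, fwd.T)


class TestHybrid:
    def test_aa_pair(self):
        fv = hybrid_composition(ProteinSequence("x", "AA"))
        assert fv.values.shape == (420,)
        assert fv.values[AA_IDX["A"]] == 1.0
        assert fv.values[20 + 0] == 1.0  # AA dipeptide slot
        assert fv.values.sum() == pytest.approx(2.0)

    def test_is_concatenation(self, rng):
        seq = random_protein(rng, 45)
        fv = hybrid_composition(seq).values
        np.testing.assert_array_equal(
            fv[:20], amino_acid_composition(seq).values)
        np.testing.assert_array_equal(
            fv[20:], dipeptide_composition(seq).values)


class TestInvariants:
    def test_dimensions_and_sums(self, rng):
        for _ in range(100):
            seq = random_protein(rng, int(rng.integers(2, 120)))
            for method in ("AC", "DC", "PSSM", "HYBRID"):
                fv = encode(seq, method, pssm_seed=3)
                assert fv.values.shape == (DIMENSIONS[method],)
            assert encode(seq, "AC").values.sum() == pytest.approx(
                1.0, abs=1e-9)
            assert encode(seq, "DC").values.sum() == pytest.approx(
                1.0, abs=1e-9)


class TestPSSMParsing:
    def test_roundtrip(self, tmp_path, rng):
        seq = random_protein(rng, 4)
        prof = mock_pssm(seq, seed=5)
        path = tmp_path / f"{seq.id}.pssm"
        write_ascii_pssm(prof, path)
        back = parse_pssm(path)
        np.testing.assert_array_equal(back.scores, prof.scores)
        assert back.consensus == seq.residues

    def test_truncated_row_errors_with_line(self, tmp_path):
        path = tmp_path / "bad.pssm"
        path.write_text(
            "\nLast position-specific scoring matrix computed\n"
            "            " + "   ".join(PSIBLAST_COLUMNS) + "\n"
            "    1 A  " + " ".join(["1"] * 20) + "\n"
            "    2 C  1 2 3\n")
        with pytest.raises(ValidationError, match=":5"):
            parse_pssm(path)

    def test_row_count_must_match_sequence(self, rng):
        seq = random_protein(rng, 10)
        prof = mock_pssm(seq, seed=1)
        short = ProteinSequence("s", seq.residues[:5])
        with pytest.raises(ValidationError):
            pssm_composition(prof, short)


class TestPSSMComposition:
    def test_zero_profile_homopolymer(self):
        seq = ProteinSequence("a", "AAAA")
        prof = PSSMProfile("a", np.zeros((4, 20), dtype=int), "AAAA")
        v = pssm_composition(prof, seq).values.reshape(20, 20)
        np.testing.assert_allclose(v[AA_IDX["A"]], 0.5)
        mask = np.ones(20, bool)
        mask[AA_IDX["A"]] = False
        assert np.all(v[mask] == 0)

    def test_zero_profile_two_residues(self):
        seq = ProteinSequence("x", "AC")
        prof = PSSMProfile("x", np.zeros((2, 20), dtype=int), "AC")
        v = pssm_composition(prof, seq).values.reshape(20, 20)
        np.testing.assert_allclose(v[AA_IDX["A"]], 0.25)
        np.testing.assert_allclose(v[AA_IDX["C"]], 0.25)

    def test_matches_brute_force(self, rng):
        seq = random_protein(rng, 30)
        scores = rng.integers(-8, 9, size=(30, 20))
        prof = PSSMProfile(seq.id, scores, seq.residues)
        np.testing.assert_allclose(pssm_composition(prof, seq).values,
                                   oracle_pssm(prof, seq.residues),
                                   atol=1e-12)

    def test_saturated_profile_tends_to_ac(self, rng):
        seq = random_protein(rng, 40)
        prof = PSSMProfile(seq.id,
                           np.full((40, 20), 20, dtype=int), seq.residues)
        v = pssm_composition(prof, seq).values.reshape(20, 20)
        ac = amino_acid_composition(seq).values
        # sigma(20) ~ 1, so every column of row a approaches AC_a
        np.testing.assert_allclose(v, np.tile(ac[:, None], (1, 20)),
                                   atol=1e-6)


class TestPSSMProvider:
    def test_mock_deterministic(self):
        seq = ProteinSequence("m", "AAA")
        p1 = pssm_provider(seq, "mock", seed=1)
        p2 = pssm_provider(seq, "mock", seed=1)
        np.testing.assert_array_equal(p1.scores, p2.scores)
        p3 = pssm_provider(seq, "mock", seed=2)
        assert not np.array_equal(p1.scores, p3.scores)

    def test_mock_diagonal_bias(self, rng):
        seq = random_protein(rng, 400)
        prof = mock_pssm(seq, seed=9)
        col_idx = {aa: i for i, aa in enumerate(PSIBLAST_COLUMNS)}
        own = np.array([prof.scores[p, col_idx[ch]]
                        for p, ch in enumerate(seq.residues)], dtype=float)
        other = (prof.scores.sum(axis=1) - own) / 19.0
        # +4 self bias over a zero-mean base: clear gap in expectation
        assert own.mean() - other.mean() > 2.5

    def test_precomputed_missing_profile(self, tmp_path, rng):
        seq = random_protein(rng, 8, "absent")
        with pytest.raises(ConfigurationError, match="absent"):
            pssm_provider(seq, "precomputed", profile_dir=tmp_path)

    def test_precomputed_roundtrip(self, tmp_path, rng):
        seq = random_protein(rng, 8, "here")
        prof = mock_pssm(seq, seed=2)
        write_ascii_pssm(prof, tmp_path / "here.pssm")
        back = pssm_provider(seq, "precomputed", profile_dir=tmp_path)
        np.testing.assert_array_equal(back.scores, prof.scores)


class TestExports:
    def test_svmlight_format(self, tmp_path):
        X = np.array([[0.0, 0.5], [1.0, 0.0]])
        path = tmp_path / "feat.svml"
        write_svmlight(X, [1, -1], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("+1 2:0.5")
        assert lines[1].startswith("-1 1:1")
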