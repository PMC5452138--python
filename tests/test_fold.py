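import numpy as np
import pytest

from _oracles import brute_max_pairs, enumerate_structures
from itsfold.energy import SCALE, default_model, load_energy_model
from itsfold.fold import (
    SecondaryStructure,
    StructureError,
    dotbracket_to_pairs,
    evaluate_energy,
    fold_mfe,
    fold_suboptimal,
    nussinov_maxpairs,
    pairs_to_dotbracket,
    read_ct,
    write_ct,
)


class TestEnergyModel:
    def test_tables_well_formed(self, model):
        assert model.min_hairpin_loop == 3
        # Watson-Crick stacks negative
        from itsfold.energy import PAIRS
        wc = [PAIRS.index(p) for p in ("AU", "CG", "GC", "UA")]
        for i in wc:
            for j in wc:
                assert model.stack[i, j] < 0
        assert (model.hairpin[3:31] > 0).all()
        assert (model.bulge[1:31] > 0).all()
        assert (model.internal[2:31] > 0).all()

    def test_logarithmic_extrapolation(self, model):
        import math
        e30 = model.hairpin[30] / SCALE
        e60 = model.hairpin[60] / SCALE
        assert e60 == pytest.approx(e30 + model.coef * math.log(2), abs=0.02)

    def test_custom_parameter_file_roundtrip(self, tmp_path):
        from importlib import resources
        text = resources.files("itsfold.data").joinpath("nn_params.txt").read_text()
        p = tmp_path / "params.txt"
        p.write_text(text)
        m = load_energy_model(p)
        assert np.array_equal(m.stack, default_model().stack)


class TestNussinov:
    def test_derived_maximum_for_short_hairpin(self):
        n_pairs, structure = nussinov_maxpairs("GCGAAACGC")
        assert n_pairs == 3 == brute_max_pairs("GCGAAACGC")
        assert len(structure.pairs) == 3

    def test_no_allowed_pairs(self):
        n_pairs, structure = nussinov_maxpairs("AAAA")
        assert n_pairs == 0
        assert structure.dotbracket == "...."

    def test_single_legal_pair(self):
        n_pairs, structure = nussinov_maxpairs("GAAAC")
        assert n_pairs == 1
        assert structure.pairs == [(1, 5)]

    def test_matches_bruteforce_on_random_set(self, random_short_sequences):
        for seq in random_short_sequences[:150]:
            n_pairs, structure = nussinov_maxpairs(seq)
            assert n_pairs == brute_max_pairs(seq), seq
            assert len(structure.pairs) == n_pairs

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError):
            nussinov_maxpairs("ACGRU")


class TestFoldMfe:
    def test_open_chain(self):
        s = fold_mfe("AAAAAAA")
        assert s.dotbracket == "......."
        assert s.energy == 0.0

    def test_hand_evaluated_hairpin(self, model):
        # two GC-on-GC stacks (-3.3 each) + tetraloop hairpin penalty (+5.6)
        s = fold_mfe("GGGAAAACCC")
        assert s.dotbracket == "(((....)))"
        assert s.energy == pytest.approx(-3.3 - 3.3 + 5.6)

    def test_energy_consistent_with_loop_decomposition(self, folded_short_sequences):
        for seq, s in folded_short_sequences:
            assert evaluate_energy(seq, s) == s.energy, seq

    def test_beats_nussinov_structure_energy(self, model):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGU"), size=40))
            mfe = fold_mfe(seq, model)
            _, nus = nussinov_maxpairs(seq)
            assert mfe.energy <= evaluate_energy(seq, nus, model) + 1e-9

    def test_deterministic(self):
        seq = "GCAUCGCGGAUACGGAUUCGCGAUGC"
        assert fold_mfe(seq).dotbracket == fold_mfe(seq).dotbracket

    def test_t_u_equivalence(self):
        dna = "GCATCGCGGATACGGATTCGCGATGC"
        rna = dna.replace("T", "U")
        assert fold_mfe(dna).energy == fold_mfe(rna).energy
        assert fold_mfe(dna).dotbracket == fold_mfe(rna).dotbracket

    def test_rejects_non_nucleotide(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGTN")


class TestEvaluateEnergy:
    def test_open_chain_is_zero(self):
        s = SecondaryStructure.from_dotbracket(".....")
        assert evaluate_energy("GAAAC", s) == 0.0

    def test_single_pair_is_hairpin_penalty(self, model):
        s = SecondaryStructure.from_dotbracket("(...)")
        assert evaluate_energy("GAAAC", s) == model.hairpin[3] / SCALE

    def test_multiloop_decomposition(self, model):
        # outer helix closing two inner hairpins -> a + 2b multiloop with one
        # unpaired base (position 10); summed by hand from the tables
        seq = "GGCGAAACGGCGAAACGCC"
        pairs = [(1, 19), (2, 18), (3, 9), (4, 8), (11, 17), (12, 16)]
        s = SecondaryStructure.from_pairs(len(seq), pairs)
        e = evaluate_energy(seq, s, model)
        expected = (
            model.stack[2, 2] / SCALE          # GC on GC (outer 1-19 over 2-18)
            + (model.ml_a + 2 * model.ml_b + model.ml_c * 1) / SCALE
            + 2 * (model.stack[1, 2] / SCALE)  # CG on GC in each inner helix
            + 2 * (model.hairpin[3] / SCALE)
        )
        assert e == pytest.approx(expected)

    def test_rejects_disallowed_pair(self):
        s = SecondaryStructure.from_dotbracket("(...)")
        with pytest.raises(StructureError):
            evaluate_energy("GAAAG", s)

    def test_rejects_short_loop(self):
        with pytest.raises(StructureError):
            evaluate_energy("GAC", SecondaryStructure.from_pairs(3, [(1, 3)]))


class TestFoldSuboptimal:
    def test_open_chain_single_structure(self):
        fr = fold_suboptimal("AAAAAAA")
        assert fr.n_structures == 1
        assert fr.structures[0].dotbracket == "......."

    def test_first_structure_is_mfe(self):
        seq = "GGGAAAACCC"
        fr = fold_suboptimal(seq)
        mfe = fold_mfe(seq)
        assert fr.structures[0].dotbracket == mfe.dotbracket
        assert fr.les == mfe.energy

    def test_contracts_on_random_sequences(self, model):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), size=60))
            fr = fold_suboptimal(seq, model, percent_window=25.0,
                                 max_structures=20,
                                 min_pair_distance_between_structures=3)
            assert 1 <= fr.n_structures <= 20
            energies = [s.energy for s in fr.structures]
            assert energies == sorted(energies)
            assert fr.les == energies[0]
            if fr.les < 0:
                thr = fr.les * (1 - 25.0 / 100)
                assert all(e <= thr + 1e-9 for e in energies)
            sets = [s.pair_set() for s in fr.structures]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    assert len(sets[a] ^ sets[b]) >= 3
            # reported energies re-derive exactly by loop decomposition
            for s in fr.structures:
                assert evaluate_energy(seq, s, model) == s.energy

    def test_cap_respected(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGU"), size=80))
        fr = fold_suboptimal(seq, max_structures=5, percent_window=50.0)
        assert fr.n_structures <= 5

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            fold_suboptimal("GGGAAAACCC", percent_window=0)


class TestExternalCrossCheck:
    def test_mfe_rank_agrees_with_viennarna(self):
        """Simplified-model MFEs should rank sequences like RNAfold does
        (external cross-check; exact energy agreement is a non-goal)."""
        import shutil
        import subprocess

        from scipy.stats import spearmanr

        if shutil.which("RNAfold") is None:
            pytest.skip("RNAfold not on PATH")
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGU"), size=120)) for _ in range(15)]
        res = subprocess.run(
            ["RNAfold", "--noPS"], input="\n".join(seqs),
            capture_output=True, text=True, check=True,
        )
        vienna = [
            float(line.rsplit("(", 1)[1].rstrip(")").strip())
            for line in res.stdout.splitlines()
            if line and not set(line) <= set("ACGU")
        ]
        ours = [fold_mfe(s).energy for s in seqs]
        rho = spearmanr(ours, vienna).statistic
        assert rho > 0.7


class TestStructureContainers:
    def test_dotbracket_pair_roundtrip(self):
        db = "..((..((...))..))."
        assert pairs_to_dotbracket(len(db), dotbracket_to_pairs(db)) == db

    def test_crossing_pairs_rejected(self):
        with pytest.raises(StructureError):
            pairs_to_dotbracket(10, [(1, 6), (3, 9)])

    def test_unbalanced_dotbracket_rejected(self):
        with pytest.raises(StructureError):
            dotbracket_to_pairs("((..)")

    def test_ct_roundtrip(self, tmp_path):
        seq = "GGGAAAACCC"
        s = fold_mfe(seq)
        p = tmp_path / "s.ct"
        write_ct(seq, s, p, title="demo")
        seq2, s2 = read_ct(p)
        assert seq2 == seq
        assert s2.pairs == s.pairs
        assert s2.energy == pytest.approx(s.energy)
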