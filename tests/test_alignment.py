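import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itsfold.alignment import (
    Alignment,
    code_gaps_binary,
    gc_content,
    remove_ambiguous_columns,
    variable_and_pi_sites,
)
from itsfold.records import SequenceRecord


def aln(*rows):
    return Alignment(labels=[f"r{i}" for i in range(len(rows))], rows=list(rows))


class TestVariableAndPiSites:
    @pytest.mark.parametrize(
        "rows,n_var,n_pi",
        [
            (("AT", "AT", "GC", "GC"), 2, 2),
            (("AA", "AA", "AA"), 0, 0),
            (("AT", "AT", "AT", "AC"), 1, 0),   # singleton state is not PI
            (("A-", "AT", "AN", "AT"), 0, 0),   # gaps/ambiguity are not states
        ],
    )
    def test_known_cases(self, rows, n_var, n_pi):
        stats = variable_and_pi_sites(aln(*rows))
        assert (stats.n_variable, stats.n_pi) == (n_var, n_pi)
        assert stats.pct_variable == pytest.approx(100 * n_var / len(rows[0]))

    def test_rejects_single_row(self):
        with pytest.raises(ValueError):
            Alignment(labels=["a"], rows=["ACGT"])

    def test_agrees_with_bruteforce_on_random_alignments(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            rows = ["".join(rng.choice(list("ACGT-N"), size=20)) for _ in range(6)]
            stats = variable_and_pi_sites(aln(*rows))
            n_var = n_pi = 0
            for j in range(20):
                col = [r[j] for r in rows if r[j] in "ACGTU"]
                states = {c: col.count(c) for c in set(col)}
                if len(states) >= 2:
                    n_var += 1
                    if sum(1 for v in states.values() if v >= 2) >= 2:
                        n_pi += 1
            assert (stats.n_variable, stats.n_pi) == (n_var, n_pi)
            assert stats.n_pi <= stats.n_variable


class TestRemoveAmbiguousColumns:
    def test_ambiguity_column_removed(self):
        out, col_map = remove_ambiguous_columns(aln("ART", "AAT"))
        assert out.rows == ["AT", "AT"]
        assert col_map == {1: 1, 3: 2}

    def test_identity_without_ambiguity(self):
        out, col_map = remove_ambiguous_columns(aln("ACGT", "ACGT"))
        assert out.rows == ["ACGT", "ACGT"]
        assert col_map == {1: 1, 2: 2, 3: 3, 4: 4}

    def test_mask_removes_clean_column(self):
        out, _ = remove_ambiguous_columns(aln("ACG", "ACG"), mask=[(1, 1)])
        assert out.rows == ["CG", "CG"]

    def test_mask_out_of_bounds(self):
        with pytest.raises(ValueError):
            remove_ambiguous_columns(aln("ACG", "ACG"), mask=[(1, 9)])


class TestCodeGapsBinary:
    def test_single_shared_span(self):
        m = code_gaps_binary(aln("A--T", "A--T", "ACGT"))
        assert m.characters == [(2, 3)]
        assert [row[0] for row in m.states] == [1, 1, 0]

    def test_no_gaps_no_characters(self):
        m = code_gaps_binary(aln("ACGT", "ACGT"))
        assert m.characters == []

    def test_containment_scores_missing(self):
        m = code_gaps_binary(aln("A--T", "AC-T", "ACGT"))
        assert m.characters == [(2, 3), (3, 3)]
        by_char = {c: [row[k] for row in m.states] for k, c in enumerate(m.characters)}
        assert by_char[(3, 3)] == [None, 1, 0]  # row with 2-3 span: missing
        assert by_char[(2, 3)] == [1, None, 0]

    def test_terminal_gaps_not_coded(self):
        m = code_gaps_binary(aln("--GT", "ACGT", "AC--"))
        assert m.characters == []

    def test_nexus_block_renders_missing_as_question_mark(self):
        from itsfold.alignment import indel_matrix_as_nexus_block

        m = code_gaps_binary(aln("A--T", "AC-T", "ACGT"))
        block = indel_matrix_as_nexus_block(m)
        assert "NCHAR=2" in block
        assert "r0 1?" in block and "r1 ?1" in block and "r2 00" in block


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
    def test_known_values(self, seq, expected):
        values, mean = gc_content([SequenceRecord(id="a", residues=seq)])
        assert values == [expected]
        assert mean == expected

    def test_s_counts_as_gc(self):
        values, _ = gc_content([SequenceRecord(id="a", residues="ASAT")])
        assert values[0] == pytest.approx(0.25)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="countable"):
            gc_content([SequenceRecord(id="a", residues="NNNN")])

    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_reverse_complement(self, seq):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
        rc = "".join(comp[c] for c in reversed(seq))
        (v1,), _ = gc_content([SequenceRecord(id="a", residues=seq)])
        (v2,), _ = gc_content([SequenceRecord(id="b", residues=rc)])
        assert v1 == pytest.approx(v2)
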