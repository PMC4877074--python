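import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnacurve import (
    CharacteristicSequence,
    SecondaryStructure,
    encode,
    parse_bpseq,
    parse_characteristic,
    parse_ct,
    parse_dot_bracket,
    write_characteristic,
)
from rnacurve.structure_io import (
    NonCanonicalPairError,
    NonCanonicalPairWarning,
    StructureFormatError,
    iter_characteristic,
    iter_dot_bracket,
)

from conftest import DIALECT, random_dialect


class TestSecondaryStructure:
    def test_normalizes_t_and_case(self):
        s = SecondaryStructure(name="x", sequence="acgt")
        assert s.sequence == "ACGU"

    def test_rejects_illegal_base(self):
        with pytest.raises(StructureFormatError, match="position 2"):
            SecondaryStructure(name="x", sequence="ANG")

    def test_rejects_empty(self):
        with pytest.raises(StructureFormatError):
            SecondaryStructure(name="x", sequence="")

    def test_rejects_out_of_range_pair(self):
        with pytest.raises(StructureFormatError, match="out of range"):
            SecondaryStructure(name="x", sequence="AU", pairs=frozenset({(1, 3)}))

    def test_rejects_position_in_two_pairs(self):
        with pytest.raises(StructureFormatError, match="more than one pair"):
            SecondaryStructure(name="x", sequence="AUGC", pairs=frozenset({(1, 2), (2, 3)}))

    def test_pseudoknot_detection(self):
        knotted = SecondaryStructure(name="x", sequence="ACGU", pairs=frozenset({(1, 3), (2, 4)}))
        nested = SecondaryStructure(name="x", sequence="ACGU", pairs=frozenset({(1, 4), (2, 3)}))
        assert knotted.is_pseudoknotted()
        assert not nested.is_pseudoknotted()


class TestDotBracket:
    def test_single_pair(self):
        assert parse_dot_bracket("AU\n()").pairs == {(1, 2)}

    def test_nested(self):
        assert parse_dot_bracket("GCAUGC\n((..))").pairs == {(1, 6), (2, 5)}

    def test_crossing_families_accepted(self):
        # ([)] pairs each family independently: 1-3 and 2-4 cross
        s = parse_dot_bracket("ACGUACGU\n([)]....")
        assert s.pairs == {(1, 3), (2, 4)}
        assert s.is_pseudoknotted()

    def test_letter_brackets(self):
        s = parse_dot_bracket("ACGUAC\n(A)a..")
        assert s.pairs == {(1, 3), (2, 4)}

    def test_header_and_multirecord(self):
        text = ">one\nAU\n()\n>two\nGC\n()"
        records = list(iter_dot_bracket(text))
        assert [r.name for r in records] == ["one", "two"]

    def test_length_mismatch(self):
        with pytest.raises(StructureFormatError, match="length mismatch"):
            parse_dot_bracket("AUG\n()")

    def test_unbalanced_open(self):
        with pytest.raises(StructureFormatError, match="never closed"):
            parse_dot_bracket("AUG\n(..")

    def test_unbalanced_close_reports_position(self):
        with pytest.raises(StructureFormatError, match="position 1"):
            parse_dot_bracket("AUG\n)..")

    def test_illegal_structure_char(self):
        with pytest.raises(StructureFormatError, match="illegal structure character"):
            parse_dot_bracket("AUG\n(_)")


CT_6ROW = """6 GCAUGC
1 G 0 2 6 1
2 C 1 3 5 2
3 A 2 4 0 3
4 U 3 5 0 4
5 G 4 6 2 5
6 C 5 0 1 6
"""


class TestCT:
    def test_two_row(self):
        text = "2 x\n1 A 0 2 2 1\n2 U 1 0 1 2\n"
        assert parse_ct(text).pairs == {(1, 2)}

    def test_non_reciprocal(self):
        text = "2 x\n1 A 0 2 2 1\n2 U 1 0 0 2\n"
        with pytest.raises(StructureFormatError, match="non-reciprocal"):
            parse_ct(text)

    def test_six_row_fixture(self):
        s = parse_ct(CT_6ROW)
        assert s.sequence == "GCAUGC"
        assert s.pairs == {(1, 6), (2, 5)}

    def test_row_count_mismatch(self):
        with pytest.raises(StructureFormatError, match="declares 3 rows"):
            parse_ct("3 x\n1 A 0 2 0 1\n2 U 1 0 0 2\n")


BPSEQ_CROSSING = "1 A 3\n2 C 4\n3 U 1\n4 G 2\n"


class TestBPSEQ:
    def test_single_pair(self):
        assert parse_bpseq("1 A 2\n2 U 1\n").pairs == {(1, 2)}

    def test_unpaired(self):
        assert parse_bpseq("1 A 0\n").pairs == frozenset()

    def test_crossing_pairs_kept(self):
        s = parse_bpseq(BPSEQ_CROSSING)
        assert s.pairs == {(1, 3), (2, 4)}

    def test_duplicate_index(self):
        with pytest.raises(StructureFormatError, match="duplicate"):
            parse_bpseq("1 A 0\n1 U 0\n")

    def test_gap_in_index(self):
        with pytest.raises(StructureFormatError, match="gap|outside"):
            parse_bpseq("1 A 0\n3 U 0\n")


def test_parsers_agree_on_equivalent_fixtures():
    db = parse_dot_bracket("GCAUGC\n((..))")
    ct = parse_ct(CT_6ROW)
    bp = parse_bpseq("1 G 6\n2 C 5\n3 A 0\n4 U 0\n5 G 2\n6 C 1\n")
    assert db.sequence == ct.sequence == bp.sequence
    assert db.pairs == ct.pairs == bp.pairs


class TestEncode:
    def test_single_pair(self):
        s = SecondaryStructure(name="x", sequence="AU", pairs=frozenset({(1, 2)}))
        assert encode(s).symbols == ("A'", "U'")

    def test_priming_rule(self):
        s = SecondaryStructure(name="x", sequence="GCAUGC", pairs=frozenset({(1, 6), (2, 5)}))
        assert encode(s).symbols == ("G'", "C'", "A", "U", "G'", "C'")
        assert encode(s).dialect == "gcAUgc"

    def test_strict_rejects_noncanonical(self):
        s = SecondaryStructure(name="x", sequence="AA", pairs=frozenset({(1, 2)}))
        with pytest.raises(NonCanonicalPairError, match=r"non-canonical pair A-A at \(1, 2\)"):
            encode(s, strict_pairs=True)

    def test_lenient_warns_and_primes(self):
        s = SecondaryStructure(name="x", sequence="AA", pairs=frozenset({(1, 2)}))
        with pytest.warns(NonCanonicalPairWarning):
            cs = encode(s)
        assert cs.symbols == ("A'", "A'")

    def test_unprime_recovers_sequence(self, random_structures):
        for s in random_structures:
            cs = encode(s)
            assert cs.unprimed_sequence() == s.sequence
            assert cs.name == s.name

    def test_primed_count_is_twice_pairs(self, random_structures):
        for s in random_structures:
            cs = encode(s)
            primed = sum(cs.primed(i) for i in range(1, len(cs) + 1))
            assert primed == 2 * len(s.pairs)


class TestCharacteristicDialect:
    def test_parse(self):
        assert parse_characteristic("AuG").symbols == ("A", "U'", "G")

    def test_write(self):
        cs = CharacteristicSequence(name="x", symbols=("G'", "C'", "A"))
        assert write_characteristic(cs) == "gcA"

    def test_illegal_character(self):
        with pytest.raises(StructureFormatError, match="position 2"):
            parse_characteristic("AxG")

    def test_fasta_like_records(self):
        records = list(iter_characteristic(">a\nAu\nG\n>b\ncc\n"))
        assert [(r.name, r.dialect) for r in records] == [("a", "AuG"), ("b", "cc")]

    def test_round_trip_1000_random(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            text = random_dialect(rng, int(rng.integers(1, 80)))
            assert write_characteristic(parse_characteristic(text)) == text

    @given(st.text(alphabet=DIALECT, min_size=1, max_size=200))
    def test_round_trip_property(self, text):
        assert write_characteristic(parse_characteristic(text)) == text

    def test_empty_input(self):
        with pytest.raises(StructureFormatError):
            parse_characteristic("")
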