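import random

import pytest
from hypothesis import given, settings, strategies as st

from ysrna.core_model import WT_DOTBRACKET, default_reference
from ysrna.structure import (
    LoopElement,
    SecondaryStructure,
    StemElement,
    StructureError,
    StructureRuleError,
    cut_offset,
    fold,
    fold_score,
    locate_stem_S3,
    parse_elements,
    read_dotbracket_file,
    ro60_site_intact,
    structure_distance,
    upstream_loop_size,
    write_dotbracket_file,
)

WEIGHTS = {"GC": 3, "AU": 2, "GU": 1}


def pair_weight(a, b):
    p = a + b
    if p in ("GC", "CG"):
        return WEIGHTS["GC"]
    if p in ("AU", "UA"):
        return WEIGHTS["AU"]
    if p in ("GU", "UG"):
        return WEIGHTS["GU"]
    return 0


def brute_force_best(seq, lo=0, hi=None, min_hairpin=3):
    """Independent oracle: exhaustive enumeration (no memoization) of all
    nested structures, returning the maximum total pair weight."""
    if hi is None:
        hi = len(seq) - 1
    if lo >= hi:
        return 0
    best = brute_force_best(seq, lo + 1, hi, min_hairpin)
    for k in range(lo + min_hairpin + 1, hi + 1):
        w = pair_weight(seq[lo], seq[k])
        if w:
            cand = (
                w
                + brute_force_best(seq, lo + 1, k - 1, min_hairpin)
                + brute_force_best(seq, k + 1, hi, min_hairpin)
            )
            best = max(best, cand)
    return best


class TestFold:
    def test_gc_hairpin(self):
        s = fold("GGGAAACCC")
        assert s.dotbracket == "(((...)))"
        assert fold_score(s) == 9

    def test_no_legal_pairs(self):
        assert fold("AAAAA").dotbracket == "....."

    def test_min_hairpin_forbids_short_loops(self):
        assert fold("GCGC").dotbracket == "...."

    def test_invalid_alphabet(self):
        with pytest.raises(ValueError):
            fold("ACGX")

    def test_structure_is_valid_and_canonical(self):
        s = fold(default_reference().sequence)
        for i, j in s.pairs():
            assert j - i - 1 >= 3  # hairpin constraint
        # SecondaryStructure __post_init__ already enforced canonical pairs

    def test_fold_matches_exhaustive_enumeration(self):
        rng = random.Random(42)
        for _ in range(40):
            n = rng.randint(4, 14)
            seq = "".join(rng.choice("ACGU") for _ in range(n))
            s = fold(seq)
            assert fold_score(s) == brute_force_best(seq)

    def test_fold_deterministic(self):
        seq = default_reference().sequence
        assert fold(seq).dotbracket == fold(seq).dotbracket


class TestDotBracketParsing:
    def test_unbalanced_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure("ACGUA", "((..)", check_pairs=False)
        with pytest.raises(StructureError):
            SecondaryStructure("ACGUA", "(..))", check_pairs=False)

    def test_other_bracket_types_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure("ACGUA", "[...]", check_pairs=False)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            SecondaryStructure("ACGU", ".....", check_pairs=False)

    def test_non_canonical_pair_rejected_by_default(self):
        with pytest.raises(StructureError):
            SecondaryStructure("CAAAC", "(...)")
        # but admitted for imposed structures
        s = SecondaryStructure("CAAAC", "(...)", check_pairs=False)
        assert s.partner(1) == 5

    def test_pair_table_symmetric(self):
        s = SecondaryStructure("GGGAAACCC", "(((...)))")
        for i in range(1, 10):
            j = s.partner(i)
            if j:
                assert s.partner(j) == i


class TestParseElements:
    def test_simple_hairpin(self):
        els = parse_elements(SecondaryStructure("GGGAAACCC", "(((...)))"))
        stems = [e for e in els if isinstance(e, StemElement)]
        loops = [e for e in els if isinstance(e, LoopElement)]
        assert len(stems) == 1 and stems[0].length == 3
        assert len(loops) == 1 and loops[0].kind == "hairpin" and loops[0].size == 3

    def test_internal_loop_two_stems(self):
        s = SecondaryStructure("GGAAGGAAACCAACC", "((..((...))..))", check_pairs=False)
        els = parse_elements(s)
        stems = [e for e in els if isinstance(e, StemElement)]
        internal = [e for e in els if isinstance(e, LoopElement) and e.kind == "internal"]
        hairpins = [e for e in els if isinstance(e, LoopElement) and e.kind == "hairpin"]
        assert [st.length for st in stems] == [2, 2]
        assert len(internal) == 1 and internal[0].size == 4
        assert len(internal[0].spans) == 2
        assert len(hairpins) == 1 and hairpins[0].size == 3

    def test_one_bp_stems_and_symmetric_internal_loop(self):
        s = SecondaryStructure("GAGAAACAC", "(.(...).)", check_pairs=False)
        els = parse_elements(s)
        stems = [e for e in els if isinstance(e, StemElement)]
        assert [st.length for st in stems] == [1, 1]
        internal = [e for e in els if isinstance(e, LoopElement) and e.kind == "internal"]
        assert len(internal) == 1 and internal[0].size == 2

    def test_partition_property_on_reference(self):
        ref = default_reference()
        s = SecondaryStructure(ref.sequence, WT_DOTBRACKET)
        els = parse_elements(s)
        covered = sum(
            2 * e.length if isinstance(e, StemElement) else e.size for e in els
        )
        assert covered == len(ref)

    @settings(max_examples=30, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=40))
    def test_partition_property_on_folds(self, seq):
        s = fold(seq)
        els = parse_elements(s)
        covered = sum(
            2 * e.length if isinstance(e, StemElement) else e.size for e in els
        )
        assert covered == len(seq)


class TestCleavageGeometry:
    def test_stem_s3_located_on_wildtype(self, reference):
        s = SecondaryStructure(reference.sequence, WT_DOTBRACKET)
        stem = locate_stem_S3(s, reference.landmark("cut3_region"))
        assert stem.start == 52
        assert stem.length == 6
        assert stem.gc_fraction == 1.0
        assert upstream_loop_size(s, stem) == 9

    def test_no_stem_signals_error(self):
        s = SecondaryStructure("ACGUACGUAC", "..........")
        with pytest.raises(StructureRuleError):
            locate_stem_S3(s, (3, 5))

    def test_shifted_stem_located(self, reference):
        from ysrna.synthetic_data import shifted_stem_dotbracket

        db = shifted_stem_dotbracket(reference, WT_DOTBRACKET, 2)
        s = SecondaryStructure(reference.sequence, db, check_pairs=False)
        stem = locate_stem_S3(s, reference.landmark("cut3_region"))
        assert stem.start == 50

    @pytest.mark.parametrize("cut,expected", [(49, 2), (51, 0), (47, 4)])
    def test_cut_offsets(self, reference, cut, expected):
        s = SecondaryStructure(reference.sequence, WT_DOTBRACKET)
        stem = locate_stem_S3(s, reference.landmark("cut3_region"))
        assert cut_offset(cut, stem) == expected

    def test_cut_at_or_after_stem_rejected(self, reference):
        s = SecondaryStructure(reference.sequence, WT_DOTBRACKET)
        stem = locate_stem_S3(s, reference.landmark("cut3_region"))
        with pytest.raises(StructureRuleError):
            cut_offset(52, stem)

    def test_cut_offset_translation_invariant(self):
        # same geometry at shifted coordinates gives the same offset
        for pad in (0, 3, 7):
            seq = "A" * pad + "ACAUC" + "GGGC" + "AAA" + "GCCC" + "A" * 2
            db = "." * pad + "....." + "((((" + "..." + "))))" + ".."
            s = SecondaryStructure(seq, db, check_pairs=False)
            stem = locate_stem_S3(s, (pad + 1, pad + 3))
            assert cut_offset(pad + 3, stem) == 2


class TestRo60Site:
    def test_wildtype_intact(self, reference):
        s = SecondaryStructure(reference.sequence, WT_DOTBRACKET)
        assert ro60_site_intact(s, reference.landmarks)

    def test_unpaired_anchor_breaks_site(self, reference):
        db = list(WT_DOTBRACKET)
        db[7] = "."  # position 8
        db[67] = "."  # position 68
        s = SecondaryStructure(reference.sequence, "".join(db), check_pairs=False)
        assert not ro60_site_intact(s, reference.landmarks)

    def test_mutated_bulge_breaks_site(self, reference):
        seq = list(reference.sequence)
        seq[8] = "A"  # bulge position 9: C -> A
        s = SecondaryStructure("".join(seq), WT_DOTBRACKET, check_pairs=False)
        assert not ro60_site_intact(s, reference.landmarks)

    def test_non_gc_anchor_breaks_site(self, reference):
        seq = list(reference.sequence)
        seq[7] = "U"  # position 8: C -> U (U:G is not G:C)
        s = SecondaryStructure("".join(seq), WT_DOTBRACKET, check_pairs=False)
        assert not ro60_site_intact(s, reference.landmarks)


class TestStructureDistance:
    def test_identical_structures(self):
        s = SecondaryStructure("GGGAAACCC", "(((...)))")
        assert structure_distance(s, s) == 0

    def test_all_pairs_removed(self):
        s1 = SecondaryStructure("GGGAAACCC", "(((...)))")
        s2 = SecondaryStructure("GGGAAACCC", ".........")
        assert structure_distance(s1, s2) == 3

    def test_single_pair_difference(self):
        s1 = SecondaryStructure("GGGAAACCC", "(((...)))")
        s2 = SecondaryStructure("GGGAAACCC", "((.....))")
        assert structure_distance(s1, s2) == 1

    def test_length_mismatch(self):
        s1 = SecondaryStructure("GGGAAACCC", "(((...)))")
        s2 = SecondaryStructure("AAAA", "....")
        with pytest.raises(StructureError):
            structure_distance(s1, s2)


class TestDotBracketIO:
    def test_roundtrip(self, tmp_path, reference):
        path = tmp_path / "structs.dbn"
        s = SecondaryStructure(reference.sequence, WT_DOTBRACKET)
        write_dotbracket_file([("wt", s)], str(path))
        records = read_dotbracket_file(str(path))
        assert len(records) == 1
        name, s2 = records[0]
        assert name == "wt"
        assert s2.dotbracket == WT_DOTBRACKET
        assert structure_distance(s, s2) == 0

    def test_truncated_record_rejected(self, tmp_path):
        path = tmp_path / "bad.dbn"
        path.write_text(">x\nACGU\n")
        with pytest.raises(StructureError):
            read_dotbracket_file(str(path))
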