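import numpy as np
import pandas as pd
import pytest

from heatmir.mirna_discovery import (
    CategoryEvidence,
    ClassificationError,
    HairpinStructure,
    KnownMatch,
    VariantDescriptor,
    apply_variant,
    classify_category,
    first_base_preference,
    hairpin_filter,
    match_known,
    positional_base_composition,
)
from heatmir.synthetic_data import revcomp

# a real mature miRNA sequence (Medicago miR167a), DNA alphabet
MIR167A = "TGAAGCTGCCAGCATGATCTA"
# synthetic stand-in reference for a miR2118-family mature (21 nt, T at
# position 18 so the printed-style substitution name is reproducible)
MIR2118A = "TTCCTGCTCCACCCATTTCTA"


class TestMatchKnown:
    def test_identity_gives_empty_descriptor(self):
        m = match_known(MIR167A, {"mtr-miR167a": MIR167A})
        assert m.name == "mtr-miR167a"
        assert str(m.descriptor) == ""

    def test_three_prime_extension_named_r_plus_1(self):
        m = match_known(MIR167A + "T", {"mtr-miR167a": MIR167A})
        assert str(m.descriptor) == "R + 1"
        assert m.name == "mtr-miR167a_R + 1"

    def test_extension_plus_substitution(self):
        read = list(MIR2118A + "A")
        read[17] = "G"  # reference position 18 is T
        assert MIR2118A[17] == "T"
        m = match_known("".join(read), {"gma-miR2118a-3p": MIR2118A})
        assert m.name == "gma-miR2118a-3p_R + 1_1ss18TG"

    def test_left_trim_right_extension(self):
        read = MIR167A[2:] + "CA"
        m = match_known(read, {"mtr-miR167a": MIR167A})
        assert str(m.descriptor) == "L-2R + 2"

    def test_no_match_beyond_edit_budget(self):
        assert match_known("G" * 21, {"mtr-miR167a": MIR167A}) is None

    def test_tie_breaks_to_lexicographically_smallest(self):
        db = {"bbb-miR1": MIR167A, "aaa-miR1": MIR167A}
        m = match_known(MIR167A, db)
        assert m.reference_name == "aaa-miR1"

    def test_requires_database(self):
        with pytest.raises(ValueError):
            match_known(MIR167A, {})

    @pytest.mark.parametrize(
        "descriptor",
        [
            VariantDescriptor(right=1, right_bases="T"),
            VariantDescriptor(left=-2, right=2, right_bases="CA"),
            VariantDescriptor(left=1, left_bases="C", substitutions=((6, "G", "A"),)),
        ],
    )
    def test_round_trip(self, descriptor):
        read = apply_variant(MIR167A, descriptor)
        m = match_known(read, {"mtr-miR167a": MIR167A})
        assert apply_variant(MIR167A, m.descriptor) == read


def perfect_hairpin(mature_len=22, loop_len=8, mfe=-30.0):
    mature = ("TGAAGCTGCCAGCATGATCTAGCATG")[:mature_len]
    loop = "AACCAAGG"[:loop_len] * (loop_len // min(loop_len, 8) or 1)
    loop = (loop + "AACCAAGG" * 25)[:loop_len]
    seq = mature + loop + revcomp(mature)
    db = "(" * mature_len + "." * loop_len + ")" * mature_len
    return HairpinStructure(seq, db, mfe, 1, mature_len)


class TestHairpinFilter:
    def test_perfect_hairpin_passes_all(self):
        report = hairpin_filter(perfect_hairpin(22, 8))
        assert report.passed
        assert report.failed_criteria() == []

    def test_weak_mfe_fails_only_energy_criterion(self):
        report = hairpin_filter(perfect_hairpin(22, 8, mfe=-10.0))
        assert report.failed_criteria() == [5]

    def test_mature_errors_fail_pairing_criterion(self):
        # 22-nt mature with 5 unpaired positions at its start
        mature_len, loop_len = 22, 8
        h = perfect_hairpin(mature_len, loop_len)
        db = "." * 5 + "(" * 17 + "." * loop_len + ")" * 17 + "." * 5
        h2 = HairpinStructure(h.precursor_sequence, db, h.mfe, 1, mature_len)
        report = hairpin_filter(h2)
        assert 10 in report.failed_criteria()

    def test_short_hairpin_fails_length(self):
        h = perfect_hairpin(18, 8)  # 44 nt total < 50
        assert 3 in hairpin_filter(h).failed_criteria()

    def test_mature_outside_stem_scores_zero_percent(self):
        # mature region placed entirely in a long terminal loop
        stem = 20
        loop = 30
        seq = "ACGT" * ((2 * stem + loop) // 4 + 1)
        seq = seq[: 2 * stem + loop]
        db = "(" * stem + "." * loop + ")" * stem
        h = HairpinStructure(seq, db, -30.0, stem + 5, stem + 24)
        report = hairpin_filter(h).table.set_index("criterion")
        assert report.loc[11, "value"] == 0.0
        assert not report.loc[11, "passed"]

    def test_structure_validation(self):
        with pytest.raises(ValueError):
            HairpinStructure("ACGT", "((..", -5.0, 1, 2)
        with pytest.raises(ValueError):
            HairpinStructure("ACGT", "....", -5.0, 3, 9)

    def test_pure_function(self):
        h = perfect_hairpin()
        r1 = hairpin_filter(h)
        r2 = hairpin_filter(h)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_folding_oracle_agrees_on_constructed_hairpin(self):
        """An independent thermodynamic folder confirms the constructed
        precursor folds into a criteria-passing hairpin."""
        RNA = pytest.importorskip("RNA")
        mature = "TGAAGCTGCCAGCATGATCTA"
        seq = mature + "CTCTCTTCTCTC" + revcomp(mature)
        structure, mfe = RNA.fold(seq.replace("T", "U"))
        h = HairpinStructure(seq, structure, mfe, 1, len(mature))
        assert hairpin_filter(h).passed


ARM = "TGAAGCTGCCAGCATGATCTAG"  # 22-nt arm used to assemble structures
LOOP8 = "AACCAAGG"


def _hp(db, seq, mfe=-40.0, mstart=1, mend=22):
    assert len(db) == len(seq), (len(db), len(seq))
    return HairpinStructure(seq, db, mfe, mstart, mend)


def single_violation_cases():
    """Eleven structures, each engineered to violate exactly one criterion.

    The filter reads only the dot-bracket, MFE, and mature coordinates, so
    sequence content just needs the right length.
    """
    cases = {}
    star = revcomp(ARM)

    # 1: 13-nt one-sided bulge in the star arm (outside the mature region)
    seq = ARM + LOOP8 + star[:11] + "T" * 13 + star[11:]
    db = "(" * 22 + "." * 8 + ")" * 11 + "." * 13 + ")" * 11
    cases[1] = _hp(db, seq)

    # 2: only 15 stem pairs; hairpin kept >= 50 nt by a 30-nt loop; the
    # mature region runs 2 nt into the loop (2 errors, still in bounds)
    seq = ARM[:15] + "A" * 30 + revcomp(ARM[:15])
    db = "(" * 15 + "." * 30 + ")" * 15
    cases[2] = _hp(db, seq, mend=17)

    # 3: hairpin of 48 nt (< 50)
    seq = ARM[:20] + LOOP8 + revcomp(ARM[:20])
    db = "(" * 20 + "." * 8 + ")" * 20
    cases[3] = _hp(db, seq, mend=20)

    # 4: terminal loop of 201 nt (> 200)
    seq = ARM + "A" * 201 + star
    db = "(" * 22 + "." * 201 + ")" * 22
    cases[4] = _hp(db, seq)

    # 5: MFE above the -15 kcal/mol cutoff
    seq = ARM + LOOP8 + star
    db = "(" * 22 + "." * 8 + ")" * 22
    cases[5] = _hp(db, seq, mfe=-10.0)

    # 6: 6-nt symmetric internal loop straddling the mature-region edge:
    # the bulge is 6 nt (> 4) but only 4 of its bases are mature errors
    seq = (
        ARM[:12] + "TTTTTT" + ARM[12:20] + LOOP8
        + revcomp(ARM[12:20]) + "GGGGGG" + revcomp(ARM[:12])
    )
    db = "(" * 12 + "." * 6 + "(" * 8 + "." * 8 + ")" * 8 + "." * 6 + ")" * 12
    cases[6] = _hp(db, seq, mend=16)

    # 7: three 1-nt biased bulges inside the mature region
    seq = ARM[:5] + "A" + ARM[5:10] + "A" + ARM[10:15] + "A" + ARM[15:] + LOOP8 + star
    db = "(" * 5 + "." + "(" * 5 + "." + "(" * 5 + "." + "(" * 7 + "." * 8 + ")" * 22
    cases[7] = _hp(db, seq, mend=25)

    # 8: one biased bulge of 3 nt (> 2) in the mature region
    seq = ARM[:11] + "AAA" + ARM[11:] + LOOP8 + star
    db = "(" * 11 + "." * 3 + "(" * 11 + "." * 8 + ")" * 22
    cases[8] = _hp(db, seq, mend=25)

    # 9: mature region of 13 nt with 11 paired (< 12) and 2 errors (<= 4)
    seq = ARM[:6] + "AA" + ARM[6:] + LOOP8 + star
    db = "(" * 6 + ".." + "(" * 16 + "." * 8 + ")" * 22
    cases[9] = _hp(db, seq, mend=13)

    # 10: two symmetric internal loops of 2 and 3 nt inside the mature
    # region: 5 errors (> 4) with every single bulge <= 4 and none biased
    seq = (
        ARM[:5] + "TT" + ARM[5:12] + "TTT" + ARM[12:] + LOOP8
        + star[:10] + "GGG" + star[10:17] + "GG" + star[17:]
    )
    db = (
        "(" * 5 + ".." + "(" * 7 + "..." + "(" * 10 + "." * 8
        + ")" * 10 + "..." + ")" * 7 + ".." + ")" * 5
    )
    cases[10] = _hp(db, seq, mend=27)

    # 11: mature region of 18 nt with a 4-nt unpaired 5' tail: 14/18 = 78%
    # of the mature region sits in the stem (< 80%) while the 4 tail
    # errors stay within the criterion-10 budget
    seq = "ACGT" + ARM[:20] + LOOP8 + revcomp(ARM[:20])
    db = "." * 4 + "(" * 20 + "." * 8 + ")" * 20
    cases[11] = _hp(db, seq, mend=18)

    return cases


class TestSingleCriterionViolations:
    @pytest.mark.parametrize("criterion", list(range(1, 12)))
    def test_violates_exactly_one(self, criterion):
        h = single_violation_cases()[criterion]
        report = hairpin_filter(h)
        assert report.failed_criteria() == [criterion]


class TestClassifyCategory:
    @pytest.mark.parametrize(
        "evidence,expected",
        [
            (CategoryEvidence(matched_mature_cotton=True, matched_precursor_cotton=True), "gp1a"),
            (CategoryEvidence(matched_mature_cotton=True, genome_mappable=True), "gp1b"),
            (CategoryEvidence(matched_mature_other=True, matched_precursor_cotton=True), "gp2a"),
            (CategoryEvidence(matched_mature_other=True, genome_mappable=True), "gp2b"),
            (CategoryEvidence(matched_mature_other=True, genome_mappable=False), "gp3"),
            (CategoryEvidence(novel_hairpin_passed=True), "gp4"),
        ],
    )
    def test_definitions(self, evidence, expected):
        assert classify_category(evidence) == expected

    def test_contradictory_evidence_raises(self):
        with pytest.raises(ClassificationError):
            classify_category(CategoryEvidence())
        with pytest.raises(ClassificationError):
            classify_category(
                CategoryEvidence(novel_hairpin_passed=True, genome_mappable=False)
            )


class TestBaseBias:
    def test_all_u_first_bases(self):
        seqs = ["TGAAGCTGCCAGCATGATCTA", "TTCCTGCTCCACCCATTCCTA"]
        table = first_base_preference(seqs)
        assert table.loc[21, "U"] == 1.0
        assert table.loc[21, ["A", "C", "G"]].sum() == 0.0

    def test_half_half_split(self):
        seqs = ["TAAAGCTGCCAGCATGATCTA", "CAAAGCTGCCAGCATGATCTA"]
        table = first_base_preference(seqs)
        assert table.loc[21, "U"] == pytest.approx(0.5)
        assert table.loc[21, "C"] == pytest.approx(0.5)

    def test_rows_sum_to_one(self, study):
        table = first_base_preference(list(study.genome.loci["mature_sequence"]))
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_generator_bias_recovered(self, study):
        """First-base proportions of planted matures should track the
        configured bias within binomial error."""
        seqs = list(study.genome.loci["mature_sequence"])
        lengths = pd.Series([len(s) for s in seqs]).value_counts()
        table = first_base_preference(seqs)
        bias = study.config.first_base_bias
        for length, n in lengths.items():
            if n < 5:
                continue
            expected = bias[length]["T"]
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(table.loc[length, "U"] - expected) <= 4 * se + 1e-9

    def test_positional_single_sequence_unit_rows(self):
        table = positional_base_composition(["TGAAG"])
        assert np.allclose(table.sum(axis=1), 1.0)
        assert table.loc[1, "U"] == 1.0
        assert table.loc[2, "G"] == 1.0

    def test_positional_split_at_first_base_only(self):
        a = "TGAAGCTGCCAGCATGATCTA"
        b = "AGAAGCTGCCAGCATGATCTA"
        table = positional_base_composition([a, b])
        assert table.loc[1, "U"] == pytest.approx(0.5)
        assert table.loc[1, "A"] == pytest.approx(0.5)
        assert (table.loc[2:].max(axis=1) == 1.0).all()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            first_base_preference([])
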