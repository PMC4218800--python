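"""Known-miRNA mapping, variant naming, flank extraction, hairpin metrics
and the 11-criterion screen."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirforge.fold import fold
from mirforge.identify import (
    CriteriaMetrics,
    CriteriaThresholds,
    HairpinCandidate,
    MiRNAVariantName,
    assign_family,
    classify_arm,
    compute_metrics,
    extract_flanks,
    format_variant_name,
    map_to_matures,
    parse_variant_name,
    passes_criteria,
    revcomp,
)
from mirforge.simulate import make_precursor


class TestVariantNaming:
    @pytest.mark.parametrize(
        "name,base,left,right,sub",
        [
            ("osa-miR5072_L-4_1ss13GA", "osa-miR5072", -4, 0, (13, "G", "A")),
            ("ppt-miR166m_R-3", "ppt-miR166m", 0, -3, None),
            ("smo-miR396_R+1_1ss7GA", "smo-miR396", 0, 1, (7, "G", "A")),
            ("xxx-miR1", "xxx-miR1", 0, 0, None),
        ],
    )
    def test_published_names_parse(self, name, base, left, right, sub):
        v = parse_variant_name(name)
        assert (v.base, v.left_offset, v.right_offset, v.substitution) == (
            base, left, right, sub,
        )
        assert format_variant_name(v) == name

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        base=st.sampled_from(["ath-miR156a", "osa-miR5072", "ppt-miR166m-5p"]),
        left=st.integers(-4, 4),
        right=st.integers(-4, 4),
        sub=st.one_of(
            st.none(),
            st.tuples(
                st.integers(1, 25),
                st.sampled_from("ACGT"),
                st.sampled_from("ACGT"),
            ),
        ),
    )
    def test_roundtrip_identity(self, base, left, right, sub):
        v = MiRNAVariantName(base, left, right, sub)
        assert parse_variant_name(format_variant_name(v)) == v

    def test_malformed_segment_reported(self):
        with pytest.raises(ValueError, match="1ss"):
            parse_variant_name("osa-miR1_1ssXX")


class TestMapToMatures:
    MAT = {"smi-miR1": "ACGATCGATTGCACTGGATCA"}
    PREC = {"smi-miR1": "GGGTT" + "ACGATCGATTGCACTGGATCA" + "CCAAA"}

    def test_identical_tag(self):
        hits = map_to_matures(self.MAT["smi-miR1"], self.MAT)
        assert hits[0] == MiRNAVariantName("smi-miR1", 0, 0, None)

    def test_three_prime_trim_names_r_minus_3(self):
        tag = self.MAT["smi-miR1"][:-3]
        hits = map_to_matures(tag, self.MAT)
        assert format_variant_name(hits[0]) == "smi-miR1_R-3"

    def test_extension_requires_precursor(self):
        tag = self.MAT["smi-miR1"] + "C"  # one extra 3' base
        assert map_to_matures(tag, self.MAT) == []
        hits = map_to_matures(tag, self.MAT, self.PREC)
        assert format_variant_name(hits[0]) == "smi-miR1_R+1"

    def test_one_internal_substitution_allowed(self):
        tag = list(self.MAT["smi-miR1"])
        tag[12] = "A" if tag[12] != "A" else "G"
        hits = map_to_matures("".join(tag), self.MAT)
        assert hits and hits[0].substitution[0] == 13

    def test_two_substitutions_rejected(self):
        tag = list(self.MAT["smi-miR1"])
        for k in (5, 12):
            tag[k] = "A" if tag[k] != "A" else "G"
        assert map_to_matures("".join(tag), self.MAT) == []


class TestExtractFlanks:
    GENOME = {"c1": "T" * 500 + "ACGATCGATTGCACTGGATCA" + "G" * 500}

    def test_two_windows_per_hit(self):
        tag = "ACGATCGATTGCACTGGATCA"
        ws = extract_flanks(self.GENOME, tag, flank=120)
        sides = {w.side for w in ws if w.strand == "+"}
        assert sides == {"downstream", "upstream"}
        down = next(w for w in ws if w.strand == "+" and w.side == "downstream")
        assert len(down.sequence) == len(tag) + 120
        assert down.sequence.startswith(tag)

    def test_clipping_at_contig_start(self):
        genome = {"c1": "ACGATCGATTGCACTGGATCA" + "G" * 300}
        ws = extract_flanks(genome, "ACGATCGATTGCACTGGATCA")
        up = next(w for w in ws if w.strand == "+" and w.side == "upstream")
        assert len(up.sequence) == 21  # upstream flank fully clipped

    def test_minus_strand_window_is_reverse_complemented(self):
        tag = "ACGATCGATTGCACTGGATCA"
        genome = {"c1": "T" * 200 + revcomp(tag) + "G" * 200}
        ws = extract_flanks(genome, tag)
        minus = [w for w in ws if w.strand == "-"]
        assert minus
        for w in minus:
            assert w.sequence[w.tag_offset : w.tag_offset + len(tag)] == tag

    def test_repetitive_tag_skipped(self):
        genome = {"c1": ("ACGATCGATTGCACTGGATCA" + "T" * 30) * 25}
        assert extract_flanks(genome, "ACGATCGATTGCACTGGATCA", max_loci=20) == []


def _candidate(seq: str, structure: str, span):
    return HairpinCandidate("c", 1, len(seq), "+", seq, structure, -30.0, span)


class TestComputeMetrics:
    def test_perfect_stem(self):
        seq = "G" * 24 + "A" * 8 + "C" * 24
        st_ = "(" * 24 + "." * 8 + ")" * 24
        m = compute_metrics(_candidate(seq, st_, (0, 20)))
        assert m.stem_base_pairs == 24
        assert m.loop_length_nt == 8
        assert m.hairpin_length_nt == 56
        assert m.mature_errors == 0
        assert m.mature_base_pairs == 21
        assert m.mature_pct_in_stem == 100.0
        assert m.arm == "5p"

    def test_large_stem_bulge_measured(self):
        # 13-nt bulge on the 3' arm between stem pairs 20 and 21
        seq = "G" * 24 + "A" * 8 + "C" * 4 + "A" * 13 + "C" * 20
        st_ = "(" * 24 + "." * 8 + ")" * 4 + "." * 13 + ")" * 20
        m = compute_metrics(_candidate(seq, st_, (0, 20)))
        assert m.max_stem_bulge_nt == 13
        assert m.stem_base_pairs == 24

    def test_mature_overlapping_loop(self):
        seq = "G" * 24 + "A" * 8 + "C" * 24
        st_ = "(" * 24 + "." * 8 + ")" * 24
        m = compute_metrics(_candidate(seq, st_, (9, 29)))  # 6 nt in the loop
        assert m.mature_pct_in_stem == pytest.approx(71.4, abs=0.05)

    def test_no_hairpin_returns_zero_stem(self):
        m = compute_metrics(_candidate("A" * 30, "." * 30, (0, 20)))
        assert m.stem_base_pairs == 0


class TestPassesCriteria:
    def _metrics(self, **overrides):
        base = dict(
            max_stem_bulge_nt=0, stem_base_pairs=24, free_energy_kcal=-40.0,
            hairpin_length_nt=56, loop_length_nt=8, max_mature_bulge_nt=0,
            mature_biased_errors_in_one_bulge=0, mature_biased_bulges=0,
            mature_errors=0, mature_base_pairs=21, mature_pct_in_stem=100.0,
        )
        base.update(overrides)
        return CriteriaMetrics(**base)

    def test_all_pass(self):
        ok, verdicts = passes_criteria(self._metrics())
        assert ok and all(verdicts.values())

    @pytest.mark.parametrize(
        "override,failing",
        [
            ({"max_stem_bulge_nt": 13}, "stem_bulge"),
            ({"stem_base_pairs": 14}, "stem_pairs"),
            ({"free_energy_kcal": -10.0}, "free_energy"),
            ({"hairpin_length_nt": 49}, "hairpin_length"),
            ({"loop_length_nt": 201}, "loop_length"),
            ({"max_mature_bulge_nt": 5}, "mature_bulge"),
            ({"mature_biased_errors_in_one_bulge": 3}, "mature_biased_errors"),
            ({"mature_biased_bulges": 3}, "mature_biased_bulges"),
            ({"mature_errors": 5}, "mature_errors"),
            ({"mature_base_pairs": 11}, "mature_pairs"),
            ({"mature_pct_in_stem": 79.9}, "mature_pct_in_stem"),
        ],
    )
    def test_single_criterion_fails(self, override, failing):
        ok, verdicts = passes_criteria(self._metrics(**override))
        assert not ok
        assert [k for k, v in verdicts.items() if not v] == [failing]

    def test_boundaries_inclusive(self):
        ok, _ = passes_criteria(
            self._metrics(
                max_stem_bulge_nt=12, stem_base_pairs=16, free_energy_kcal=-15.0,
                hairpin_length_nt=50, loop_length_nt=200, max_mature_bulge_nt=4,
                mature_biased_errors_in_one_bulge=2, mature_biased_bulges=2,
                mature_errors=4, mature_base_pairs=12, mature_pct_in_stem=80.0,
            )
        )
        assert ok

    def test_thresholds_configurable(self):
        m = self._metrics(free_energy_kcal=-12.0)
        assert passes_criteria(m)[0] is False
        loose = CriteriaThresholds(max_free_energy_kcal=-10.0)
        assert passes_criteria(m, loose)[0] is True


def test_compensatory_pair_never_weakens_stem_criterion():
    prev = None
    for k in range(16, 25):
        seq, _ = make_precursor(k, 8, min(k, 21), seed=7)
        structure, energy = fold(seq)
        m = compute_metrics(
            HairpinCandidate("c", 1, len(seq), "+", seq, structure, energy,
                             (0, min(k, 21) - 1))
        )
        if prev is not None:
            assert m.stem_base_pairs >= prev
        assert passes_criteria(m)[1]["stem_pairs"]
        prev = m.stem_base_pairs


class TestClassifyArm:
    STRUCT = "(" * 24 + "." * 8 + ")" * 24

    def test_tag_on_annotated_arm_is_known(self):
        assert classify_arm((0, 20), self.STRUCT, (0, 20)) == "known"

    def test_opposite_arm_is_novel_3p(self):
        assert classify_arm((33, 53), self.STRUCT, (0, 20)) == "novel_3p"

    def test_opposite_arm_is_novel_5p(self):
        assert classify_arm((0, 20), self.STRUCT, (33, 53)) == "novel_5p"

    def test_loop_spanning_tag_excluded(self):
        assert classify_arm((20, 35), self.STRUCT, (0, 19)) == "loop"


@pytest.mark.parametrize(
    "name,family",
    [
        ("ppt-miR166m_R-3", "miR166"),
        ("osa-miR5072_L-4_1ss13GA", "miR5072"),
        ("aly-miR858-5p_L-1R+1_1ss5GA", "miR858"),
        ("PC-3p-115345_10", None),
        ("totally-unrelated", None),
    ],
)
def test_family_assignment(name, family):
    assert assign_family(name) == family
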