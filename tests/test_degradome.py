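"""Degradome gating, T-plots, complementarity scoring and category rules."""

import itertools

import pytest

from mirforge.degradome import (
    TPlot,
    build_tplots,
    categorize,
    find_sites,
    gate_and_trim,
    render_tplot,
    score_alignment,
)
from mirforge.identify import revcomp


class TestGateAndTrim:
    def test_adaptor_gated_and_trimmed(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        tags = gate_and_trim(["CAGCAG" + insert], tag_len=20)
        assert tags[0].sequence == insert[:20]

    def test_read_without_adaptor_discarded(self):
        assert gate_and_trim(["ACGTACGTACGTACGTACGTACGT"]) == []

    def test_duplicates_collapse_with_counts(self):
        read = "CAGCAG" + "ACGTACGTACGTACGTACGT"
        tags = gate_and_trim([read, read])
        assert len(tags) == 1 and tags[0].count == 2

    def test_short_insert_dropped(self):
        assert gate_and_trim(["CAGCAG" + "ACGT"]) == []


class TestBuildTPlots:
    TX = {"t1": "T" * 49 + "ACGTACGTACGTACGTACGTGGCC" + "T" * 100}

    def test_single_match_position_and_count(self):
        tags = gate_and_trim(["CAGCAG" + "ACGTACGTACGTACGTACGT"] * 3)
        plots = build_tplots(tags, self.TX)
        assert plots["t1"].profile == {50: 3}

    def test_unmatched_tag_contributes_nothing(self):
        tags = gate_and_trim(["CAGCAG" + "G" * 20])
        assert build_tplots(tags, self.TX)["t1"].profile == {}

    def test_count_conservation_over_mapped_tags(self):
        reads = ["CAGCAG" + "ACGTACGTACGTACGTACGT"] * 4
        reads += ["CAGCAG" + "C" * 20] * 2  # unmapped
        plots = build_tplots(gate_and_trim(reads), self.TX)
        assert sum(plots["t1"].profile.values()) == 4

    def test_empty_transcripts_rejected(self):
        with pytest.raises(ValueError):
            build_tplots([], {})


class TestScoreAlignment:
    MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt

    def test_perfect_complement_scores_zero(self):
        window = revcomp(self.MIRNA).replace("T", "U")
        score, marks = score_alignment(self.MIRNA, window)
        assert score == 0.0
        assert marks == "|" * 21

    def test_gu_wobble_in_core_scores_one(self):
        # miRNA position 5 is G; put U opposite it (window position 21-5+1)
        window = list(revcomp(self.MIRNA).replace("T", "U"))
        assert self.MIRNA[4] == "G"
        window[21 - 5] = "U"
        score, marks = score_alignment(self.MIRNA, "".join(window))
        assert score == pytest.approx(1.0)  # 0.5 doubled in positions 2-13
        assert marks[4] == "o"

    def test_mismatch_outside_core_scores_one(self):
        window = list(revcomp(self.MIRNA).replace("T", "U"))
        window[21 - 20] = "C" if window[21 - 20] != "C" else "G"
        score, marks = score_alignment(self.MIRNA, "".join(window))
        assert score == pytest.approx(1.0)
        assert marks[19] == "."

    def test_mismatch_in_core_doubled(self):
        window = list(revcomp(self.MIRNA).replace("T", "U"))
        pos = 7
        target = window[21 - pos]
        window[21 - pos] = {"A": "C", "C": "A", "G": "A", "U": "C"}[target]
        score, _ = score_alignment(self.MIRNA, "".join(window))
        assert score == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_alignment(self.MIRNA, "ACGU")

    def test_symmetry_under_duplex_reversal(self):
        # reading the duplex from the other strand preserves Watson-Crick
        # pairs and mismatches; windows without wobble score identically
        mirna = "ACGGAUCCGGAAUUCCGGAUC"
        window = revcomp(mirna).replace("T", "U")
        s1, _ = score_alignment(mirna, window)
        s2, _ = score_alignment(window, mirna)
        assert s1 == s2 == 0.0


def brute_force_category(c: int, profile: dict[int, int]) -> int:
    """Independent restatement of the five category rules."""
    import statistics

    values = sorted(profile.values())
    M = max(values)
    med = statistics.median(values)
    if c == 1:
        return 4
    if c == M:
        return 0 if values.count(M) == 1 else 1
    if med < c < M:
        return 2
    return 3


class TestCategorize:
    @pytest.mark.parametrize(
        "profile,pos,cat",
        [
            ({10: 5, 20: 1, 30: 1}, 10, 0),
            ({10: 3, 20: 3, 30: 1}, 10, 1),
            ({10: 3, 20: 9, 30: 1, 40: 1}, 10, 2),
            ({10: 2, 20: 3, 30: 3, 40: 3}, 10, 3),
            ({10: 1, 20: 9}, 10, 4),
        ],
    )
    def test_rule_examples(self, profile, pos, cat):
        assert categorize(pos, TPlot("t", 100, profile)) == cat

    def test_unoccupied_position_is_error(self):
        with pytest.raises(ValueError):
            categorize(55, TPlot("t", 100, {10: 3}))

    def test_partition_property_against_brute_force(self):
        """Every occupied-position profile with <= 6 positions and counts
        <= 5 maps each position to exactly one category, matching an
        independent classifier."""
        for npos in range(1, 7):
            positions = [10 * (k + 1) for k in range(npos)]
            for counts in itertools.product(range(1, 6), repeat=npos):
                profile = dict(zip(positions, counts))
                tp = TPlot("t", 100, profile)
                for pos in positions:
                    got = categorize(pos, tp)
                    assert got in (0, 1, 2, 3, 4)
                    assert got == brute_force_category(profile[pos], profile)


class TestFindSites:
    MIRNA = "TGGAGCTCCCTTCATTCCAAT"

    def _transcript(self):
        return "T" * 60 + revcomp(self.MIRNA) + "T" * 60

    def test_planted_site_recovered_at_register_10(self):
        t = self._transcript()
        cleavage = 60 + len(self.MIRNA) - 9  # 1-based, paired to position 10
        tp = TPlot("t1", len(t), {cleavage: 5, 10: 1})
        sites = find_sites("m", self.MIRNA, "t1", t, tp)
        assert len(sites) == 1
        assert sites[0].cleavage_position == cleavage
        assert sites[0].score == 0.0
        assert sites[0].category == 0

    def test_no_degradome_signal_no_site(self):
        t = self._transcript()
        tp = TPlot("t1", len(t), {10: 3})
        assert find_sites("m", self.MIRNA, "t1", t, tp) == []

    def test_score_cutoff_enforced(self):
        t = self._transcript()
        cleavage = 60 + len(self.MIRNA) - 9
        tp = TPlot("t1", len(t), {cleavage: 5})
        assert find_sites("m", self.MIRNA, "t1", t, tp, score_cutoff=-1.0) == []


class TestRenderTPlot:
    def test_empty_profile_renders(self, tmp_path):
        out = render_tplot(TPlot("t", 100, {}), path=tmp_path / "empty.svg")
        assert out.exists()

    def test_deterministic_output(self, tmp_path):
        tp = TPlot("t", 200, {50: 9, 120: 2})
        site = None
        a = render_tplot(tp, site, tmp_path / "a.svg")
        b = render_tplot(tp, site, tmp_path / "b.svg")
        assert a.read_bytes() == b.read_bytes()
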