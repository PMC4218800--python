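"""Synthetic-data generator: determinism, conservation, constructability of
criterion-targeted precursors, and plant/recover guarantees."""

import pandas as pd
import pytest

from mirforge.degradome import build_tplots, gate_and_trim
from mirforge.expression import delta_delta_ct
from mirforge.fold import fold
from mirforge.identify import (
    HairpinCandidate,
    compute_metrics,
    passes_criteria,
)
from mirforge.preprocess import is_junk, run_preprocess, trim_adapter
from mirforge.simulate import (
    SimulationConfig,
    build_ground_truth,
    make_precursor,
    simulate_degradome,
    simulate_qpcr,
    simulate_srna_libraries,
)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(contaminant_fractions={"rRNA": 1.2})
        with pytest.raises(ValueError):
            SimulationConfig(
                contaminant_fractions={"rRNA": 0.6, "junk": 0.5}
            )

    def test_depth_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(library_depth=0)


class TestMakePrecursor:
    def test_perfect_archetype_passes_all_criteria(self):
        seq, moff = make_precursor(24, 8, 21, seed=3)
        structure, energy = fold(seq)
        cand = HairpinCandidate(
            "c", 1, len(seq), "+", seq, structure, energy, (moff, moff + 20)
        )
        ok, verdicts = passes_criteria(compute_metrics(cand))
        assert ok, verdicts

    def test_infeasible_mature_rejected(self):
        with pytest.raises(ValueError, match="does not fit"):
            make_precursor(10, 8, 25, seed=0)

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError, match="loop"):
            make_precursor(20, 2, 15, seed=0)

    def test_requested_bulge_realized(self):
        seq, moff = make_precursor(24, 8, 21, bulges=[(22, 0, 13)], seed=3)
        structure, energy = fold(seq)
        m = compute_metrics(
            HairpinCandidate("c", 1, len(seq), "+", seq, structure, energy,
                             (moff, moff + 20))
        )
        assert m.max_stem_bulge_nt == 13
        assert m.stem_base_pairs == 24


class TestCriterionSuite:
    def test_each_construct_fails_exactly_its_criterion(self, criterion_suite):
        assert len(criterion_suite) == 12
        for d in criterion_suite:
            structure, energy = fold(d["sequence"])
            cand = HairpinCandidate(
                "c", 1, len(d["sequence"]), "+", d["sequence"], structure,
                energy, d["mature_span"],
            )
            _, verdicts = passes_criteria(compute_metrics(cand))
            assert verdicts == d["expected_verdicts"], d["label"]


class TestSrnaLibraries:
    def test_depth_conservation(self, small_config, libraries):
        libs, _ = libraries
        assert all(len(r) == small_config.library_depth for r in libs.values())

    def test_determinism_same_seed(self, small_config, truth):
        a, _ = simulate_srna_libraries(small_config, truth)
        b, _ = simulate_srna_libraries(small_config, truth)
        assert a == b

    def test_tissue_exclusive_reads_confined(self, small_config, truth, libraries):
        _, prov = libraries
        exclusive = {
            name: [t for t, w in ab.items() if w > 0]
            for name, _seq, ab in truth.planted_matures
            if sum(1 for w in ab.values() if w > 0) == 1
        }
        assert exclusive, "expected at least one tissue-exclusive miRNA"
        mirna_reads = prov[prov["class"] == "mirna"]
        for name, tissues in exclusive.items():
            seen = set(mirna_reads[mirna_reads["detail"] == name]["library"])
            assert seen <= set(tissues)

    def test_no_contaminants_means_all_mirna_reads(self):
        cfg = SimulationConfig(
            seed=5, library_depth=500, n_known_mirnas=5, n_novel_loci=1,
            n_background_loci=0, background_tag_fraction=0.0,
            contaminant_fractions={},
        )
        truth = build_ground_truth(cfg)
        libs, prov = simulate_srna_libraries(cfg, truth)
        assert set(prov["class"]) == {"mirna"}
        planted = {s for _n, s, _a in truth.planted_matures}
        for reads in libs.values():
            for read in reads:
                insert = trim_adapter(read, cfg.adapter3)
                assert insert in planted


class TestDegradomeSimulation:
    def test_planted_categories_realized(self, small_config, truth):
        reads, tx = simulate_degradome(small_config, truth)
        assert len(truth.planted_cleavages) == small_config.n_cleavage_sites
        cats = {c for *_, c in truth.planted_cleavages}
        assert cats == {0, 1, 2, 3, 4}

    def test_pure_cleavage_fraction_only_planted_positions(self):
        cfg = SimulationConfig(
            seed=6, n_known_mirnas=5, n_novel_loci=1, n_cleavage_sites=1,
            cleavage_fraction=1.0,
        )
        truth = build_ground_truth(cfg)
        reads, tx = simulate_degradome(cfg, truth)
        plots = build_tplots(gate_and_trim(reads), tx)
        occupied = {
            (t, p) for t, tp in plots.items() for p in tp.profile
        }
        planted = {(t, p) for _m, t, p, _c in truth.planted_cleavages}
        assert occupied == planted

    def test_adaptorless_reads_gated_out(self, small_config, truth):
        reads, _tx = simulate_degradome(small_config, truth)
        gated = gate_and_trim(reads, small_config.degradome_adaptor)
        n_with = sum(
            1 for r in reads if r.startswith(small_config.degradome_adaptor)
        )
        assert sum(t.count for t in gated) == n_with
        assert n_with < len(reads)


class TestQpcrSimulation:
    FOLDS = {"miR1": {"root": 1.0, "leaf": 4.0, "stem": 0.5}}

    def test_noise_free_recovery_exact(self):
        ct = simulate_qpcr(self.FOLDS, noise_sd=0.0, seed=0)
        rel = delta_delta_ct(ct, calibrator="root")
        by = rel.set_index("sample")["relative_expression"]
        assert by["root"] == pytest.approx(1.0)
        assert by["leaf"] == pytest.approx(4.0)
        assert by["stem"] == pytest.approx(0.5)

    def test_noise_recovery_within_three_se(self):
        # Ct noise sd=0.1 over 3 replicates; on the log2 scale the ddCt
        # combines four mean-Ct terms: se = 0.1 * sqrt(4/3)
        import numpy as np

        ct = simulate_qpcr(self.FOLDS, noise_sd=0.1, seed=2)
        rel = delta_delta_ct(ct, calibrator="root")
        by = rel.set_index("sample")["relative_expression"]
        se_log2 = 0.1 * np.sqrt(4 / 3)
        assert abs(np.log2(by["leaf"]) - 2.0) < 3 * se_log2

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            simulate_qpcr({"g": {"a": 0.0}})


class TestPlantRecover:
    @pytest.mark.parametrize("seed", range(20))
    def test_planted_matures_recovered_and_no_background_novel(self, seed):
        """Noise-free plant/recover: every planted mature survives the
        cascade as a clean tag and maps back to its reference; random
        background tags never yield a criteria-passing hairpin."""
        from mirforge.identify import evaluate_window, extract_flanks, map_to_matures

        cfg = SimulationConfig(
            seed=100 + seed, library_depth=800, n_known_mirnas=6,
            n_novel_loci=1, n_background_loci=4,
        )
        truth = build_ground_truth(cfg)
        libs, prov = simulate_srna_libraries(cfg, truth)
        tags, _report = run_preprocess(
            libs, truth.contaminants, adapter3=cfg.adapter3
        )
        clean = {t.sequence for t in tags if t.annotation == "clean"}
        for name, seq, ab in truth.planted_matures:
            if name in truth.known_matures:
                assert seq in clean
                assert map_to_matures(seq, truth.known_matures)[0].base == name
        # background tags: mapped to the genome and folded, never accepted
        bg = set(prov[prov["class"] == "background"]["detail"])
        for tag in bg:
            for w in extract_flanks(truth.genome, tag):
                assert not evaluate_window(w)[2]
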