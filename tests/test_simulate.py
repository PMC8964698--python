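"""Simulator: determinism, truth bookkeeping, closed-form expectations."""

import dataclasses

import numpy as np
import pytest

from bewindow.readprep import ReadPair, merge_pair, read_fastq_pairs
from bewindow.simulate import (SimulationConfig, SimulationConfigError,
                               pool_to_fastq, scenario_presets,
                               simulate_allele_pool, truth_selectivity_fold,
                               zero_noise)
from bewindow.targets import window_partition


def config(cbe_target, **kw):
    defaults = dict(target=cbe_target, edit_prob={4: 0.4}, coverage=500, seed=3)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_non_editable_position_rejected(self, cbe_target):
        with pytest.raises(SimulationConfigError):
            config(cbe_target, edit_prob={2: 0.1})  # position 2 is T

    def test_probability_ranges(self, cbe_target):
        with pytest.raises(SimulationConfigError):
            config(cbe_target, edit_prob={4: 1.5})
        with pytest.raises(SimulationConfigError):
            config(cbe_target, coedit_correlation=1.0)

    def test_read_length_overlap_guard(self, cbe_target):
        with pytest.raises(SimulationConfigError):
            config(cbe_target, read_length=60)  # 2*60 - 120 < 11

    def test_treated_probs_attenuated(self, cbe_target):
        cfg = config(cbe_target, edit_prob={4: 0.4, 1: 0.2},
                     inhibition={1: 0.9, 4: 0.1})
        assert cfg.effective_probs("treated")[1] == pytest.approx(0.02)
        assert cfg.effective_probs("treated")[4] == pytest.approx(0.36)


class TestAllelePool:
    def test_all_zero_probs_all_unedited(self, cbe_target):
        pool = simulate_allele_pool(config(cbe_target, edit_prob={}))
        assert pool.class_fractions["unedited"] == 1.0
        assert len(pool.alleles) == 1
        assert pool.alleles[0][0] == cbe_target.amplicon_seq

    def test_certain_edit_all_perfect(self, cbe_target):
        pool = simulate_allele_pool(config(cbe_target, edit_prob={4: 1.0}))
        assert pool.class_fractions["perfect"] == 1.0
        assert pool.realized_freqs[3] == 1.0

    def test_closed_form_perfect_of_total(self, cbe_target):
        """Independent edits at p4 (intended, 0.4) and p1 (bystander, 0.2):
        perfect-of-total expectation 0.4 * 0.8 = 0.32."""
        cfg = config(cbe_target, edit_prob={4: 0.4, 1: 0.2}, coverage=10000)
        pool = simulate_allele_pool(cfg)
        assert pool.expected_class_fractions["perfect"] == pytest.approx(0.32)
        sd = np.sqrt(0.32 * 0.68 / 10000)
        assert abs(pool.class_fractions["perfect"] - 0.32) < 3 * sd

    def test_marginals_preserved_under_correlation(self, cbe_target):
        cfg = config(cbe_target, edit_prob={4: 0.4, 1: 0.2},
                     coedit_correlation=0.8, coverage=20000)
        pool = simulate_allele_pool(cfg)
        for p, prob in cfg.edit_prob.items():
            sd = np.sqrt(prob * (1 - prob) / cfg.coverage)
            assert abs(pool.realized_freqs[p - 1] - prob) < 4 * sd

    def test_seed_reproducibility(self, cbe_target):
        cfg = config(cbe_target, edit_prob={4: 0.3, 1: 0.1}, indel_rate=0.02)
        p1 = simulate_allele_pool(cfg)
        p2 = simulate_allele_pool(cfg)
        assert p1.alleles == p2.alleles
        assert p1.class_fractions == p2.class_fractions

    def test_indel_rate_reflected(self, cbe_target):
        cfg = config(cbe_target, indel_rate=0.5, coverage=4000)
        pool = simulate_allele_pool(cfg)
        assert abs(pool.class_fractions["indel_allele"] - 0.5) < 0.05


class TestFastqEmission:
    def test_same_seed_byte_identical(self, cbe_target, tmp_path):
        cfg = config(cbe_target, seq_error_rate=0.01, coverage=200)
        pool = simulate_allele_pool(cfg)
        for tag in ("a", "b"):
            pool_to_fastq(pool, cfg, tmp_path / f"{tag}.R1.fq",
                          tmp_path / f"{tag}.R2.fq")
        assert (tmp_path / "a.R1.fq").read_bytes() == (tmp_path / "b.R1.fq").read_bytes()
        assert (tmp_path / "a.R2.fq").read_bytes() == (tmp_path / "b.R2.fq").read_bytes()

    def test_error_free_consensus_equals_alleles(self, cbe_target, tmp_path):
        cfg = zero_noise(config(cbe_target, edit_prob={4: 0.5, 1: 0.2},
                                coverage=100))
        pool = simulate_allele_pool(cfg)
        pool_to_fastq(pool, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        allele_seqs = {seq for seq, _ in pool.alleles}
        n = 0
        for pair in read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"):
            cons = merge_pair(pair)
            assert cons is not None and cons.seq in allele_seqs
            n += 1
        assert n == 100

    def test_round_trip_preserves_sequence_and_quality(self, cbe_target, tmp_path):
        cfg = config(cbe_target, seq_error_rate=0.005, coverage=50)
        pool = simulate_allele_pool(cfg)
        pool_to_fastq(pool, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        pairs = list(read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"))
        assert len(pairs) == 50
        assert all(len(p.r1_seq) == cfg.read_length for p in pairs)
        assert all(2 <= p.r1_qual.min() and p.r1_qual.max() <= 41 for p in pairs)

    def test_observed_error_rate_matches(self, cbe_target, tmp_path):
        cfg = config(cbe_target, edit_prob={}, seq_error_rate=0.01, coverage=600)
        pool = simulate_allele_pool(cfg)
        pool_to_fastq(pool, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        amp = cbe_target.amplicon_seq
        mismatches = bases = 0
        for pair in read_fastq_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq"):
            ref1 = amp[:cfg.read_length]
            mismatches += sum(a != b for a, b in zip(pair.r1_seq, ref1))
            bases += len(ref1)
        sd = np.sqrt(0.01 * 0.99 / bases)
        assert abs(mismatches / bases - 0.01) < 3 * sd


class TestPresets:
    def test_presets_validate_and_are_seeded(self):
        presets = scenario_presets()
        assert {"broad-window-cbe", "focused-inhibitor", "abe"} <= set(presets)
        seeds = {cfg.seed for cfg in presets.values()}
        assert len(seeds) == len(presets)

    def test_focused_inhibitor_construction_fold(self):
        cfg = scenario_presets()["focused-inhibitor"]
        part = window_partition("CBE")
        assert truth_selectivity_fold(cfg, part) == pytest.approx(9.0)

    def test_abe_window_is_max_frequency_region(self, tmp_path):
        """Full pipeline on the ABE preset: the four highest editing
        frequencies sit at the 4-7 on-target window."""
        from bewindow.pipeline import (SampleSheetEntry, Thresholds,
                                       quantify_sample)
        cfg = dataclasses.replace(scenario_presets()["abe"], coverage=800)
        pool = simulate_allele_pool(cfg)
        pool_to_fastq(pool, cfg, tmp_path / "r1.fq", tmp_path / "r2.fq")
        entry = SampleSheetEntry("s", "demo_abe", "control", 1,
                                 str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq"))
        sq = quantify_sample(entry, cfg.target, Thresholds())
        freqs = sq.profile.freqs
        top4 = set(np.argsort(np.nan_to_num(freqs, nan=-1))[-4:] + 1)
        assert top4 == {4, 5, 6, 7}
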