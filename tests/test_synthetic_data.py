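import filecmp

import numpy as np
import pytest

from crossvar.io_formats import Zygosity
from crossvar.synthetic_data import (
    ConfigError, SimConfig, designate_specific, simulate_bundle,
    simulate_chip, simulate_platform, simulate_reference, simulate_truth,
)

NO_ERROR = dict(
    genome_length=30_000, n_contigs=1, n_variant_sites=800,
    het_to_hom_base_rate=0.0, platform_specific_rate=0.0,
    chip_het_to_hom_error=0.0, low_mq_repeat_fraction=0.0,
    pileup_error_rate=0.0,
)


def no_error_config(seed=5, **overrides):
    from crossvar.synthetic_data import PlatformModel

    platforms = {
        "p1": PlatformModel(mean_depth=30, dropout_rate=0.0),
        "p2": PlatformModel(mean_depth=35, dropout_rate=0.0),
    }
    return SimConfig(seed=seed, platforms=platforms, **{**NO_ERROR, **overrides})


class TestReference:
    def test_repeat_fraction_within_band(self):
        cfg = SimConfig(seed=3, genome_length=10_000, n_contigs=1,
                        repeat_fraction=0.3, n_variant_sites=100)
        _, repeats = simulate_reference(cfg)
        assert 0.28 <= repeats.total_length() / 10_000 <= 0.32

    def test_zero_repeat_fraction_empty_regions(self):
        cfg = SimConfig(seed=3, genome_length=5_000, n_contigs=1,
                        repeat_fraction=0.0, n_variant_sites=10)
        seqs, repeats = simulate_reference(cfg)
        assert len(repeats) == 0
        assert len(seqs["contig1"]) == 5_000

    def test_same_seed_identical_sequence(self):
        cfg = SimConfig(seed=9, genome_length=5_000, n_contigs=2,
                        n_variant_sites=10)
        assert simulate_reference(cfg)[0] == simulate_reference(cfg)[0]

    def test_infeasible_repeat_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(repeat_fraction=0.95)


class TestTruth:
    def test_het_fraction_one_all_het(self):
        cfg = SimConfig(seed=2, genome_length=5_000, n_contigs=1,
                        n_variant_sites=200, het_fraction=1.0)
        ref, reps = simulate_reference(cfg)
        truth = simulate_truth(cfg, ref, reps)
        assert all(t.zygosity is Zygosity.HET for t in truth)

    def test_het_fraction_recovered(self, sim_world):
        truth = sim_world["truth"]
        het = sum(t.zygosity is Zygosity.HET for t in truth) / len(truth)
        assert het == pytest.approx(0.6, abs=0.02)

    def test_zero_sites_empty(self):
        cfg = SimConfig(seed=2, genome_length=5_000, n_contigs=1,
                        n_variant_sites=0)
        ref, reps = simulate_reference(cfg)
        assert simulate_truth(cfg, ref, reps) == []

    def test_sites_unique_and_match_reference(self, small_world):
        truth, ref = small_world["truth"], small_world["reference"]
        assert len({(t.contig, t.position) for t in truth}) == len(truth)
        assert all(ref[t.contig][t.position - 1] == t.ref_allele for t in truth)
        assert all(t.ref_allele != t.alt_allele for t in truth)


class TestPlatform:
    def test_no_error_limit_calls_equal_truth(self):
        cfg = no_error_config()
        ref, reps = simulate_reference(cfg)
        truth = simulate_truth(cfg, ref, reps)
        spec = designate_specific(cfg, truth)
        for pid in cfg.platforms:
            calls, *_ = simulate_platform(cfg, truth, ref, reps, pid, spec)
            called = {
                (c.contig, c.position, c.ref_allele, c.alt_allele, c.zygosity)
                for c in calls
            }
            expected = {
                (t.contig, t.position, t.ref_allele, t.alt_allele, t.zygosity)
                for t in truth
            }
            assert called == expected

    def test_depth_independent_het_to_hom_rate(self):
        # depth_scale -> infinity makes the error rate equal the base rate
        cfg = no_error_config(
            n_variant_sites=2500, het_fraction=1.0,
            het_to_hom_base_rate=0.5, het_to_hom_depth_scale=1e12,
        )
        ref, reps = simulate_reference(cfg)
        truth = simulate_truth(cfg, ref, reps)
        spec = designate_specific(cfg, truth)
        calls, *_ = simulate_platform(cfg, truth, ref, reps, "p1", spec)
        hom = sum(c.zygosity is Zygosity.HOM for c in calls)
        # binomial 99.9% interval around 0.5 at n=2500
        assert hom / len(calls) == pytest.approx(0.5, abs=0.033)

    def test_call_depth_matches_track(self, small_world):
        calls, depth, _, _ = small_world["platforms"]["p1"]
        assert all(depth.at(c.contig, c.position) == c.depth for c in calls)

    def test_truth_must_be_nonempty(self, small_world):
        cfg = small_world["config"]
        with pytest.raises(ValueError):
            simulate_platform(cfg, [], small_world["reference"],
                              small_world["repeats"], "p1")


class TestChip:
    def test_zero_error_chip_equals_truth(self):
        cfg = no_error_config()
        ref, reps = simulate_reference(cfg)
        truth = simulate_truth(cfg, ref, reps)
        chip = simulate_chip(cfg, truth)
        truth_by_site = {(t.contig, t.position): t for t in truth}
        for g in chip:
            t = truth_by_site[g.site]
            expected = (
                (t.alt_allele, t.alt_allele) if t.zygosity is Zygosity.HOM
                else tuple(sorted((t.ref_allele, t.alt_allele)))
            )
            assert g.genotype == expected

    def test_flip_fraction_matches_error_rate(self, sim_world):
        truth_by_site = {(t.contig, t.position): t for t in sim_world["truth"]}
        assayed_het = [
            g for g in sim_world["chip"]
            if truth_by_site[g.site].zygosity is Zygosity.HET
        ]
        hom_reported = sum(g.zygosity is Zygosity.HOM for g in assayed_het)
        assert hom_reported / len(assayed_het) == pytest.approx(0.10, abs=0.015)

    def test_zero_fraction_empty(self, small_world):
        cfg = SimConfig(seed=4, genome_length=5_000, n_contigs=1,
                        n_variant_sites=100, chip_site_fraction=0.0)
        ref, reps = simulate_reference(cfg)
        truth = simulate_truth(cfg, ref, reps)
        assert simulate_chip(cfg, truth) == set()


class TestBundle:
    def test_same_seed_byte_identical_bundle(self, tmp_path, small_config):
        a = simulate_bundle(small_config, tmp_path / "a")
        b = simulate_bundle(small_config, tmp_path / "b")
        assert set(a) == set(b)
        for key in a:
            assert filecmp.cmp(a[key], b[key], shallow=False), key

    def test_designated_specific_sets_disjoint(self, sim_world):
        spec = sim_world["specific"]
        s1, s2 = spec["p1"], spec["p2"]
        assert not (s1 & s2)
        k = round(0.15 * len(sim_world["truth"]))
        assert len(s1) == len(s2) == k
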