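"""Generator contracts: determinism, ground-truth consistency, and the
statistical structure the downstream analysis assumes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from euseq.errors import ParameterError
from euseq.simulate import (
    NascentSimConfig,
    ScreenSimConfig,
    simulate_coverage,
    simulate_nascent_counts,
    simulate_screen,
)


def small_cfg(**kw) -> NascentSimConfig:
    base = dict(n_genes=300, n_histone=10, depth_per_sample=5e5, seed=7)
    base.update(kw)
    return NascentSimConfig(**base)


class TestNascentCounts:
    def test_null_effect_config_has_unit_multipliers(self):
        cfg = small_cfg(effect_rdna=1, effect_histone=1, frac_up=0, frac_down=0)
        _, truth = simulate_nascent_counts(cfg)
        assert (truth.table["multiplier"] == 1.0).all()
        assert truth.global_ratio == 1.0

    def test_same_config_bit_identical(self):
        cfg = small_cfg()
        cm1, t1 = simulate_nascent_counts(cfg)
        cm2, t2 = simulate_nascent_counts(small_cfg())
        assert cm1.counts.to_csv() == cm2.counts.to_csv()
        assert t1.table.to_csv() == t2.table.to_csv()

    def test_pre_ir_rdna_share_near_target(self):
        cm, _ = simulate_nascent_counts(NascentSimConfig(seed=11))
        pre = cm.samples_for("pre_IR")
        rdna = cm.counts.loc[cm.gene_meta["class"] == "rDNA", pre].to_numpy().sum()
        nonspike = cm.counts.loc[~cm.spikein_mask, pre].to_numpy().sum()
        assert abs(rdna / nonspike - 0.7) < 0.03

    def test_spikein_truth_constant_across_conditions(self):
        _, truth = simulate_nascent_counts(small_cfg())
        spikes = truth.table[truth.table["class"] == "spikein"]
        assert (spikes["multiplier"] == 1.0).all()

    def test_total_counts_conserve_depth(self):
        # Poisson mode, no jitter: per-sample totals should sit within 5 sd
        # of depth over 20 draws
        depth = 2e5
        devs = []
        for seed in range(20):
            cfg = small_cfg(depth_jitter=(1, 1), depth_per_sample=depth,
                            effect_rdna=1, effect_histone=1, frac_up=0, frac_down=0,
                            seed=seed)
            cm, _ = simulate_nascent_counts(cfg)
            devs.extend((cm.counts.sum(axis=0) - depth) / np.sqrt(depth))
        assert np.all(np.abs(devs) < 5)

    def test_truth_global_ratio_consistency(self):
        _, truth = simulate_nascent_counts(small_cfg(frac_down=0.2, fc_down=0.4))
        t = truth.table[truth.table["class"] != "spikein"]
        expect = np.average(t["multiplier"], weights=t["baseline"])
        assert truth.global_ratio == pytest.approx(expect, abs=1e-12)

    def test_stratified_effects_put_repression_on_top_genes(self):
        _, truth = simulate_nascent_counts(small_cfg(stratified_effects=True))
        pc = truth.table[truth.table["class"] == "protein_coding"].sort_values(
            "baseline", ascending=False
        )
        n_down = int(round(0.10 * len(pc)))
        assert (pc["multiplier"].iloc[:n_down] == 0.5).all()

    @pytest.mark.parametrize(
        "bad", [dict(frac_up=0.7, frac_down=0.5), dict(rdna_read_fraction=1.2),
                dict(depth_per_sample=0), dict(fc_up=-1), dict(noise="gaussian")]
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ParameterError):
            simulate_nascent_counts(small_cfg(**bad))

    def test_nb_noise_runs_and_is_overdispersed(self):
        cfg = small_cfg(noise="nb", nb_dispersion=0.2, depth_jitter=(1, 1))
        cm, truth = simulate_nascent_counts(cfg)
        assert (cm.counts.to_numpy() >= 0).all()


class TestCoverageSim:
    def test_initiation_noiseless_is_uniform_half(self):
        sim = simulate_coverage(5, "initiation", 0.5, 0.0, seed=1)
        pre = sim.pre.to_frame().set_index(["chrom", "start", "end"])["value"]
        post = sim.post.to_frame().set_index(["chrom", "start", "end"])["value"]
        assert np.allclose(post.to_numpy(), 0.5 * pre.to_numpy())

    def test_elongation_noiseless_halves_three_prime_half(self):
        sim = simulate_coverage(4, "elongation", 0.5, 0.0, seed=2)
        for row in sim.genes.itertuples(index=False):
            L = row.end - row.start
            pre = sim.pre.depth(row.chrom, row.start, row.end)
            post = sim.post.depth(row.chrom, row.start, row.end)
            ratio = post / pre
            if row.strand == "-":
                ratio = ratio[::-1]
            # 5' 40% untouched, 3' 40% halved (middle ramp excluded)
            n = L
            five = ratio[: int(0.40 * n)]
            three = ratio[int(0.60 * n):]
            assert np.allclose(five, 1.0)
            assert np.allclose(three, 0.5)

    def test_same_seed_identical(self):
        a = simulate_coverage(3, "initiation", 0.3, 0.2, seed=5)
        b = simulate_coverage(3, "initiation", 0.3, 0.2, seed=5)
        pd.testing.assert_frame_equal(a.pre.to_frame(), b.pre.to_frame())
        pd.testing.assert_frame_equal(a.post.to_frame(), b.post.to_frame())

    @pytest.mark.parametrize("depletion", [0.0, 1.0, -0.2])
    def test_depletion_bounds(self, depletion):
        with pytest.raises(ParameterError):
            simulate_coverage(3, "initiation", depletion, 0.1, seed=0)


class TestScreenSim:
    def test_near_null_enrichment_gives_equal_expected_ratios(self):
        cfg = ScreenSimConfig(n_genes=100, n_hits=5, enrichment_factor=1 + 1e-12,
                              depth_unsorted=10**6, depth_high=10**6, seed=3)
        counts, truth = simulate_screen(cfg)
        # expected proportions agree to ~1e-12, so observed FCs scatter around 1
        fc = (counts.table["count_high"] + 1) / (counts.table["count_unsorted"] + 1)
        assert abs(np.log(fc).mean()) < 0.05

    def test_no_hits_means_identical_expected_proportions(self):
        cfg = ScreenSimConfig(n_genes=100, n_hits=0, seed=4,
                              depth_unsorted=10**5, depth_high=10**5)
        counts, truth = simulate_screen(cfg)
        assert truth.hit_genes == []
        assert (truth.guide_enrichment == 1.0).all()

    def test_enriched_guide_fold_change_recovers_factor(self):
        counts, truth = simulate_screen(ScreenSimConfig(seed=6))
        t = counts.table.set_index("guide_id")
        enriched = truth.guide_enrichment[truth.guide_enrichment > 1].index
        T_u, T_h = counts.total_unsorted, counts.total_high
        fc = (t.loc[enriched, "count_high"] / T_h) / (t.loc[enriched, "count_unsorted"] / T_u)
        assert abs(fc.mean() - 4.0) / 4.0 < 0.2

    def test_determinism_and_truth_size(self):
        a, ta = simulate_screen(ScreenSimConfig(n_genes=50, n_hits=3, seed=8,
                                                depth_unsorted=10**5, depth_high=10**5))
        b, tb = simulate_screen(ScreenSimConfig(n_genes=50, n_hits=3, seed=8,
                                                depth_unsorted=10**5, depth_high=10**5))
        assert a.table.to_csv() == b.table.to_csv()
        assert len(ta.hit_genes) == 3

    def test_invalid_config_rejected(self):
        with pytest.raises(ParameterError):
            simulate_screen(ScreenSimConfig(guides_per_gene=3, guides_enriched_per_hit=4))
        with pytest.raises(ParameterError):
            simulate_screen(ScreenSimConfig(enrichment_factor=0.9))
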