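"""Guide counting rules, the printed normalization/score formulas, enrichment
tests, and gene-level hit calling."""

import numpy as np
import pandas as pd
import pytest

from euseq.containers import GuideLibrary
from euseq.errors import AnalysisError
from euseq.screen import (
    GuideEnrichmentScorer,
    ScreenCounts,
    call_hit_genes,
    combine_bins,
    count_guides,
    guide_stats,
    normalize_guides,
)
from euseq.simulate import ScreenSimConfig, screen_reads, simulate_screen
from test_stats import pmf_sum_upper

G1 = "ACGTACGTACGTACGTACGT"
G2 = "TGCATGCATGCATGCATGCA"


@pytest.fixture
def lib():
    return GuideLibrary(
        pd.DataFrame(
            {"gene_id": ["geneA", "geneB"], "guide_id": ["gA_1", "gB_1"],
             "sequence": [G1, G2]}
        )
    )


def reads(*seqs):
    return [(f"r{i}", s, "I" * len(s)) for i, s in enumerate(seqs)]


class TestCounting:
    def test_anchored_exact_match_at_offset(self, lib):
        bc = count_guides(reads("TTTTT" + G1 + "CCC"), lib, offset=5)
        assert bc.counts["gA_1"] == 1 and bc.counts["gB_1"] == 0
        assert bc.n_unmatched == 0

    def test_scan_finds_guide_anywhere(self, lib):
        bc = count_guides(reads("GG" + G2 + "AAAA"), lib, search="scan")
        assert bc.counts["gB_1"] == 1

    def test_two_guides_in_one_read_ambiguous(self, lib):
        bc = count_guides(reads(G1 + G2), lib, search="scan")
        assert bc.n_ambiguous == 1
        assert bc.counts.sum() == 0

    def test_single_mismatch_unmatched(self, lib):
        near = "A" + G1[1:].replace("C", "G", 1)
        bc = count_guides(reads(near), lib, search="scan")
        assert bc.n_unmatched == 1 and bc.counts.sum() == 0

    def test_offset_beyond_read_unmatched(self, lib):
        bc = count_guides(reads("ACGT"), lib, offset=10)
        assert bc.n_unmatched == 1

    def test_counter_conservation_exact(self, lib):
        rds = reads("TT" + G1, G2, G1 + G2, "A" * 20, G2 + "TTT")
        bc = count_guides(rds, lib, search="scan")
        assert bc.conserved()
        assert bc.n_reads_seen == 5

    def test_empty_library_rejected(self):
        empty = GuideLibrary(pd.DataFrame({"gene_id": [], "guide_id": [], "sequence": []}))
        with pytest.raises(AnalysisError):
            count_guides(reads("ACGT"), empty)

    def test_fastq_roundtrip_counts_recovered(self, lib, tmp_path):
        from euseq import io as eio

        per_guide = pd.Series({"gA_1": 7, "gB_1": 3})
        eio.write_fastq(screen_reads(per_guide, lib, seed=1), tmp_path / "r.fastq")
        bc = count_guides(eio.iterate_fastq(tmp_path / "r.fastq"), lib, offset=10)
        assert bc.counts["gA_1"] == 7 and bc.counts["gB_1"] == 3


def screen_counts(pairs: dict) -> ScreenCounts:
    rows = [
        {"gene_id": g.rsplit("_", 1)[0], "guide_id": g,
         "count_unsorted": u, "count_high": h}
        for g, (u, h) in pairs.items()
    ]
    return ScreenCounts(table=pd.DataFrame(rows))


class TestNormalization:
    def test_printed_formula(self):
        sc = screen_counts({"a_1": (100, 100), "b_1": (10**6 - 100, 10**6 - 100)})
        norm = normalize_guides(sc)
        assert norm.set_index("guide_id").loc["a_1", "norm_unsorted"] == pytest.approx(101.0)

    def test_zero_reads_normalize_to_one(self):
        sc = screen_counts({"a_1": (0, 5), "b_1": (100, 100)})
        norm = normalize_guides(sc)
        assert norm.set_index("guide_id").loc["a_1", "norm_unsorted"] == 1.0

    def test_normalized_minus_one_sums_to_million(self):
        rng = np.random.default_rng(2)
        sc = screen_counts(
            {f"g{i}_1": (int(u), int(h))
             for i, (u, h) in enumerate(zip(rng.integers(0, 500, 50), rng.integers(0, 500, 50)))}
        )
        norm = normalize_guides(sc)
        assert (norm["norm_unsorted"] - 1).sum() == pytest.approx(1e6, rel=1e-6)
        assert (norm["norm_high"] - 1).sum() == pytest.approx(1e6, rel=1e-6)


class TestGuideStats:
    def test_worked_example(self):
        sc = screen_counts({"a_1": (100, 300), "pad_1": (10**6 - 100, 10**6 - 300)})
        st = guide_stats(sc).set_index("guide_id")
        row = st.loc["a_1"]
        assert row["norm_unsorted"] == pytest.approx(101.0)
        assert row["norm_high"] == pytest.approx(301.0)
        assert row["fc"] == pytest.approx(301 / 101, rel=1e-12)
        assert row["crispr_score"] == pytest.approx(np.log2(301 / 101), rel=1e-9)
        assert row["p"] == pytest.approx(pmf_sum_upper(300, 100.0), abs=1e-12)

    def test_equal_counts_fc_one_score_zero(self):
        sc = screen_counts({"a_1": (200, 200), "b_1": (50, 50)})
        st = guide_stats(sc).set_index("guide_id")
        assert st.loc["a_1", "fc"] == 1.0 and st.loc["a_1", "crispr_score"] == 0.0

    def test_score_is_log2_fc_for_every_guide(self):
        counts, _ = simulate_screen(ScreenSimConfig(n_genes=200, n_hits=5, seed=14,
                                                    depth_unsorted=10**5, depth_high=10**5))
        st = guide_stats(counts)
        assert np.allclose(st["crispr_score"], np.log2(st["fc"]), atol=1e-12)

    def test_depth_matched_lambda(self):
        # T_h = 2 T_u: a guide with equal raw counts is depleted 2x
        sc = screen_counts({"a_1": (100, 100), "pad_1": (10**6 - 100, 2 * 10**6 - 100)})
        st = guide_stats(sc).set_index("guide_id")
        T_u, T_h = 10**6, 2 * 10**6
        lam = 100 * T_h / T_u
        assert st.loc["a_1", "p"] == pytest.approx(pmf_sum_upper(100, lam), abs=1e-12)


class TestHitCalling:
    def stats_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "guide_id", "fc", "crispr_score", "q"]
        )

    def test_single_passing_guide_is_hit(self):
        st = self.stats_frame([("geneA", "gA_1", 1.6, np.log2(1.6), 0.005)])
        hits = call_hit_genes(st)
        assert hits.loc["geneA", "hit"] and not hits.loc["geneA", "robust"]

    def test_q_above_threshold_not_hit(self):
        st = self.stats_frame([("geneA", "gA_1", 3.0, np.log2(3.0), 0.02)])
        assert not call_hit_genes(st).loc["geneA", "hit"]

    def test_three_passing_guides_robust(self):
        st = self.stats_frame(
            [("geneA", f"gA_{i}", 2.0, 1.0, 0.001) for i in range(3)]
            + [("geneB", "gB_1", 1.0, 0.0, 0.9)]
        )
        hits = call_hit_genes(st)
        assert hits.loc["geneA", "n_passing"] == 3
        assert hits.loc["geneA", "robust"]
        assert not hits.loc["geneB", "hit"]

    def test_fc_gate_required(self):
        st = self.stats_frame([("geneA", "gA_1", 1.4, np.log2(1.4), 0.001)])
        assert not call_hit_genes(st).loc["geneA", "hit"]


def test_scorer_recovers_simulated_hits():
    counts, truth = simulate_screen(ScreenSimConfig(seed=0))
    sc = GuideEnrichmentScorer().fit(counts)
    called = set(sc.hit_genes_)
    true = set(truth.hit_genes)
    assert len(called & true) / len(true) >= 0.9
    assert len(called & true) / len(called) >= 0.8


def test_null_screen_calls_few_hits():
    fracs = []
    robust_fracs = []
    for seed in range(5):
        cfg = ScreenSimConfig(n_genes=1000, n_hits=0, seed=seed,
                              depth_unsorted=10**6, depth_high=10**6)
        counts, _ = simulate_screen(cfg)
        sc = GuideEnrichmentScorer().fit(counts)
        hits = sc.gene_hits_
        fracs.append(hits["hit"].mean())
        robust_fracs.append(hits["robust"].mean())
    assert sum(f <= 0.01 for f in fracs) >= 4
    assert max(robust_fracs) <= 0.001


def test_combine_bins_and_diagnostics(lib):
    u = count_guides(reads("TT" + G1, "TT" + G2, "TT" + G2), lib, offset=2)
    h = count_guides(reads("TT" + G1), lib, offset=2)
    sc = combine_bins(lib, u, h)
    assert sc.total_unsorted == 3 and sc.total_high == 1
    assert list(sc.diagnostics["n_matched"]) == [3, 1]
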