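import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from chroma3d import elements as ele
from chroma3d.io import StepTrack

GENES = pd.DataFrame({
    "gene_id": ["gp", "gm"], "chrom": ["c", "c"],
    "start": [5000, 20000], "end": [8000, 23000], "strand": ["+", "-"]})


def peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestClassifyAcrs:
    def test_promoter_window_overlap(self):
        out = ele.classify_acrs(peaks([("c", 2500, 3100)]), GENES)
        assert out["element_class"].tolist() == ["promoter_ACR"]

    def test_minus_strand_window_downstream_of_end(self):
        out = ele.classify_acrs(peaks([("c", 24000, 24500)]), GENES)
        assert out["element_class"].tolist() == ["promoter_ACR"]

    def test_gene_body_only_is_other(self):
        out = ele.classify_acrs(peaks([("c", 6000, 6400)]), GENES)
        assert out["element_class"].tolist() == ["other_ACR"]

    def test_promoter_takes_precedence_over_body(self):
        out = ele.classify_acrs(peaks([("c", 4000, 6000)]), GENES)
        assert out["element_class"].tolist() == ["promoter_ACR"]

    def test_nothing_overlapping_is_distal(self):
        out = ele.classify_acrs(peaks([("c", 15000, 15500)]), GENES)
        assert out["element_class"].tolist() == ["distal_ACR"]

    def test_window_clipped_at_chromosome_start(self):
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"],
                              "start": [1000], "end": [3000], "strand": ["+"]})
        out = ele.classify_acrs(peaks([("c", 0, 100)]), genes)
        assert out["element_class"].tolist() == ["promoter_ACR"]

    def test_classes_partition_all_peaks(self, default_dataset):
        ds = default_dataset
        out = ele.classify_acrs(ds.layers.atac_peaks_s1, ds.genome.genes,
                                chrom_sizes=ds.config.chrom_sizes)
        counts = out["element_class"].value_counts()
        assert counts.sum() == len(ds.layers.atac_peaks_s1)
        assert set(counts.index) <= {"promoter_ACR", "other_ACR", "distal_ACR"}

    def test_agrees_with_brute_force_overlap_oracle(self):
        rng = np.random.default_rng(11)
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(60)],
            "chrom": rng.choice(["c1", "c2"], 60),
            "start": (s := rng.integers(0, 90_000, 60)),
            "end": s + rng.integers(500, 4000, 60),
            "strand": rng.choice(["+", "-"], 60)})
        pk = pd.DataFrame({
            "chrom": rng.choice(["c1", "c2"], 1000),
            "start": (ps := rng.integers(0, 95_000, 1000)),
            "end": ps + rng.integers(100, 2000, 1000)})
        out = ele.classify_acrs(pk, genes)
        windows = []
        for g in genes.itertuples(index=False):
            if g.strand == "-":
                windows.append((g.chrom, g.end, g.end + 3000))
            else:
                windows.append((g.chrom, max(0, g.start - 3000), g.start))
        for row, got in zip(pk.itertuples(index=False), out["element_class"]):
            in_w = any(c == row.chrom and row.start < e and row.end > s
                       for c, s, e in windows)
            in_b = any(g.chrom == row.chrom and row.start < g.end
                       and row.end > g.start for g in genes.itertuples(index=False))
            want = ("promoter_ACR" if in_w else
                    "other_ACR" if in_b else "distal_ACR")
            assert got == want


class TestEnhancers:
    def test_one_bp_atac_overlap_marks_active(self):
        enh = ele.define_enhancers(peaks([("c", 15000, 16000)]), GENES)
        marked = ele.mark_active(enh, peaks([("c", 15999, 16500)]))
        assert marked["active"].tolist() == [True]
        marked = ele.mark_active(enh, peaks([("c", 16000, 16500)]))
        assert marked["active"].tolist() == [False]

    def test_promoter_h3k27ac_is_not_enhancer(self):
        enh = ele.define_enhancers(peaks([("c", 2500, 3500)]), GENES)
        assert enh.empty

    def test_fixture_active_fraction_exact(self, default_dataset):
        ds = default_dataset
        enh = ele.define_enhancers(ds.layers.h3k27ac_peaks, ds.genome.genes,
                                   chrom_sizes=ds.config.chrom_sizes)
        enh = ele.mark_active(enh, ds.layers.atac_peaks_s1)
        assert ele.active_fraction(enh) == pytest.approx(0.25)
        assert enh["active"].sum() <= len(enh)

    def test_fixture_h3k27ac_peaks_longer_than_atac(self, default_dataset):
        ds = default_dataset
        k27 = (ds.layers.h3k27ac_peaks["end"]
               - ds.layers.h3k27ac_peaks["start"]).mean()
        atac = (ds.layers.atac_peaks_s1["end"]
                - ds.layers.atac_peaks_s1["start"]).mean()
        assert k27 > atac


def loop_row(a1, a2):
    return {"chrom": "c", "bin_i": 0, "bin_j": 2,
            "anchor1_start": a1[0], "anchor1_end": a1[1],
            "anchor2_start": a2[0], "anchor2_end": a2[1]}


class TestLinkEnhancerGenes:
    enh = peaks([("c", 15000, 16000)])

    def test_enhancer_one_side_gene_other_side_links(self):
        loops = pd.DataFrame([loop_row((15000, 15500), (5000, 7000))])
        res = ele.link_enhancer_genes(self.enh, loops, GENES)
        assert len(res["links"]) == 1
        assert res["n_enhancer_anchors"] == 1
        assert res["n_genes_linked"] == 1

    def test_same_anchor_colocation_never_links(self):
        # enhancer overlapping anchor1 together with the gene; anchor2 empty
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c"],
                              "start": [14000], "end": [14800],
                              "strand": ["+"]})
        loops = pd.DataFrame([loop_row((14000, 16000), (50000, 51000))])
        res = ele.link_enhancer_genes(self.enh, loops, genes,
                                      chrom_sizes={"c": 60000})
        assert res["links"].empty

    def test_shared_anchor_deduplicated(self):
        loops = pd.DataFrame([loop_row((15000, 15500), (5000, 7000)),
                              loop_row((15000, 15500), (20000, 22000))])
        res = ele.link_enhancer_genes(self.enh, loops, GENES)
        assert res["n_enhancer_anchors"] == 1
        assert res["n_genes_linked"] == 2


class TestMetaprofiles:
    def test_uniform_depth_flat_tss_profile(self):
        tr = StepTrack(100, {"c": np.full(500, 3.0)})
        res = ele.tss_metaprofile(tr, GENES, flank=2000)
        np.testing.assert_allclose(res["profile"], 3.0)

    def test_planted_bump_peaks_at_tss(self):
        vals = np.zeros(500)
        tr = StepTrack(100, {"c": vals})
        genes = pd.DataFrame({"gene_id": ["a", "b"], "chrom": ["c", "c"],
                              "start": [10000, 30000], "end": [12000, 32000],
                              "strand": ["+", "+"]})
        for tss in (10000, 30000):
            x = np.arange(500) * 100
            vals += 5 * np.exp(-0.5 * ((x - tss) / 300) ** 2)
        res = ele.tss_metaprofile(tr, genes, flank=2000)
        assert abs(res["peak_offset"]) <= 100

    def test_minus_strand_profile_reversed(self):
        vals = np.zeros(500, dtype=float)
        vals[95:100] = 7.0  # just upstream (left) of position 10000
        tr = StepTrack(100, {"c": vals})
        plus = pd.DataFrame({"gene_id": ["a"], "chrom": ["c"],
                             "start": [10000], "end": [12000], "strand": ["+"]})
        minus = pd.DataFrame({"gene_id": ["a"], "chrom": ["c"],
                              "start": [8000], "end": [10001], "strand": ["-"]})
        pp = ele.tss_metaprofile(tr, plus, flank=1000)["profile"]
        pm = ele.tss_metaprofile(tr, minus, flank=1000)["profile"]
        np.testing.assert_allclose(pm, pp[::-1])

    def test_constant_methylation_flat_peak_profile(self):
        tr = StepTrack(200, {"c": np.full(200, 0.5)})
        res = ele.peak_metaprofile(tr, peaks([("c", 10000, 11000)]))
        np.testing.assert_allclose(res["body"], 0.5)
        assert res["body_mean"] == pytest.approx(0.5)

    def test_empty_peak_set_rejected(self):
        tr = StepTrack(200, {"c": np.full(200, 0.5)})
        with pytest.raises(ValueError):
            ele.peak_metaprofile(tr, peaks([]))

    def test_fixture_methylation_dip_in_peak_bodies(self, default_dataset):
        ds = default_dataset
        pk = ds.layers.atac_peaks_s1[["chrom", "start", "end"]]
        prof = ele.peak_methylation_profile(ds.layers.methylation, pk)
        for ctx in ("CG", "CHG", "CHH"):
            r = prof[ctx]
            assert r["body_mean"] < r["upstream_mean"]
            assert r["body_mean"] < r["downstream_mean"]


class TestPromoterAcrExpression:
    def test_planted_positive_effect_detected(self, default_dataset):
        ds = default_dataset
        acrs = ele.classify_acrs(ds.layers.atac_peaks_s1, ds.genome.genes,
                                 chrom_sizes=ds.config.chrom_sizes)
        prom = acrs[acrs["element_class"] == "promoter_ACR"]
        res = ele.promoter_acr_expression(ds.genome.genes, prom,
                                          ds.layers.expression,
                                          chrom_sizes=ds.config.chrom_sizes)
        assert res["median_with"] > res["median_without"]
        assert res["p_value"] < 0.05

    def test_null_distributions_mostly_non_significant(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(20):
            genes = pd.DataFrame({
                "gene_id": [f"g{i}" for i in range(200)],
                "chrom": "c", "start": np.arange(200) * 5000 + 3500,
                "end": np.arange(200) * 5000 + 4500, "strand": "+"})
            with_acr = rng.random(200) < 0.5
            prom = peaks([("c", int(s - 800), int(s - 200))
                          for s in genes.loc[with_acr, "start"]])
            expr = pd.DataFrame({"gene_id": genes["gene_id"],
                                 "expression": rng.lognormal(1, 0.5, 200)})
            res = ele.promoter_acr_expression(genes, prom, expr)
            hits += res["p_value"] < 0.05
        assert hits <= 2  # ~5% type-I at alpha 0.05

    def test_all_genes_with_acr_flagged(self):
        genes = GENES
        prom = peaks([("c", 2500, 3000), ("c", 23500, 24000)])
        expr = pd.DataFrame({"gene_id": genes["gene_id"],
                             "expression": [1.0, 2.0]})
        res = ele.promoter_acr_expression(genes, prom, expr)
        assert not res["defined"]


class TestDifferentialAccessibility:
    def make_tracks(self, v1, v2):
        return (StepTrack(100, {"c": np.array(v1, float)}),
                StepTrack(100, {"c": np.array(v2, float)}))

    def test_equal_counts_not_differential(self):
        d1, d2 = self.make_tracks([10] * 100, [10] * 100)
        out = ele.differential_accessibility(d1, d2, peaks([("c", 1000, 2000)]))
        assert out["log2_ratio"].iloc[0] == pytest.approx(0.0)
        assert not out["differential"].iloc[0]

    def test_four_fold_change_flagged(self):
        v1, v2 = np.ones(100), np.ones(100)
        v1[10:20] = 100.0
        v2[10:20] = 25.0
        v1[50:60] = 50.0  # equalise library sizes elsewhere
        v2[50:60] = 125.0
        d1, d2 = self.make_tracks(v1, v2)
        out = ele.differential_accessibility(d1, d2, peaks([("c", 1000, 2000)]))
        lfc = out["log2_ratio"].iloc[0]
        # pseudocount-adjusted log2 of 100x10 vs 25x10 at equal libraries
        assert lfc == pytest.approx(2.0, abs=0.1)
        assert out["differential"].iloc[0]
        # binomial tail oracle
        n, x = 1250, 1000
        p_orac = 2 * min(binom.cdf(x, n, 0.5), binom.sf(x - 1, n, 0.5))
        assert out["p_value"].iloc[0] == pytest.approx(min(p_orac, 1.0), rel=0.05)

    def test_zero_library_rejected(self):
        d1, d2 = self.make_tracks([0] * 10, [1] * 10)
        with pytest.raises(ValueError):
            ele.differential_accessibility(d1, d2, peaks([("c", 0, 500)]))

    def test_fixture_flags_exactly_planted_peaks(self, default_dataset):
        ds = default_dataset
        out = ele.differential_accessibility(ds.layers.atac_depth_s1,
                                             ds.layers.atac_depth_s2,
                                             ds.layers.atac_peaks_s1)
        flagged = ds.layers.atac_peaks_s1.loc[out[out["differential"]].index,
                                              "name"]
        assert sorted(flagged) == ["diff_0", "diff_1"]
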