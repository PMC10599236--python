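import filecmp
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from chroma3d import synthetic_data as syn


def small_config(**kw):
    defaults = dict(n_chromosomes=1, chrom_length_bp=1_000_000,
                    bin_size_bp=25_000, n_genes=104, n_snps=200,
                    n_enhancers_per_chrom=5, rng_seed=0)
    defaults.update(kw)
    return syn.SyntheticConfig(**defaults)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(chrom_length_bp=1_000_100),
        dict(plaid_amplitude=1.0),
        dict(tad_contrast=0.5),
        dict(coverage_scale=0.0),
        dict(snp_enrichment_factor=0.5),
        dict(loop_strength=0.0),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(syn.ConfigError):
            small_config(**kw)

    def test_too_many_enhancers_rejected(self):
        with pytest.raises(syn.ConfigError, match="enhancer"):
            syn.generate(small_config(n_enhancers_per_chrom=5000))


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for d in ("a", "b"):
            ds = syn.generate(syn.SyntheticConfig(rng_seed=42))
            syn.write_dataset(ds, tmp_path / d)
        files = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert files
        for name in files:
            h = [hashlib.sha256((tmp_path / d / name).read_bytes()).hexdigest()
                 for d in ("a", "b")]
            assert h[0] == h[1], name

    def test_different_seeds_differ(self):
        a = syn.generate(syn.SyntheticConfig(rng_seed=1))
        b = syn.generate(syn.SyntheticConfig(rng_seed=2))
        assert not np.array_equal(a.contacts["chr1"].counts,
                                  b.contacts["chr1"].counts)


class TestGenome:
    def test_gene_density_contrast_exact_when_divisible(self):
        # 16 A bins x weight 5 + 24 B bins x weight 1 = 104 = n_genes:
        # the per-bin quota echoes the weights exactly
        cfg = small_config()
        genome, truth = syn.make_genome(cfg)
        labs = truth.compartment_labels["chr1"]
        dens = genome.gene_density["chr1"]
        assert dens[labs == "A"].mean() == pytest.approx(
            5 * dens[labs == "B"].mean())

    def test_zero_genes_empty_annotation(self):
        cfg = small_config(n_genes=0, promoter_acr_fraction=0.0)
        genome, _ = syn.make_genome(cfg)
        assert genome.genes.empty
        assert all(v.sum() == 0 for v in genome.gene_density.values())

    def test_b_compartment_track_contrasts(self):
        genome, truth = syn.make_genome(syn.SyntheticConfig(rng_seed=3))
        for chrom in genome.chrom_sizes:
            a = truth.compartment_labels[chrom] == "A"
            assert genome.ltr[chrom][~a].mean() > genome.ltr[chrom][a].mean()
            assert genome.gc[chrom][~a].mean() > genome.gc[chrom][a].mean()

    def test_all_intervals_within_chromosome_bounds(self, default_dataset):
        ds = default_dataset
        for df in (ds.genome.genes, ds.layers.atac_peaks_s1,
                   ds.layers.h3k27ac_peaks):
            for row in df.itertuples(index=False):
                assert 0 <= row.start < row.end <= ds.config.chrom_sizes[row.chrom]


class TestTruthInvariants:
    def test_boundaries_strictly_increasing(self, default_dataset):
        for bounds in default_dataset.truth.tad_boundaries.values():
            assert all(a < b for a, b in zip(bounds, bounds[1:]))

    def test_loop_pixels_off_diagonal(self, default_dataset):
        for px in default_dataset.truth.loop_pixels.values():
            assert all(j - i >= 2 for i, j in px)

    def test_a_label_telomeric_b_pericentromeric(self, default_dataset):
        for labs in default_dataset.truth.compartment_labels.values():
            n = len(labs)
            assert (labs[: n // 10] == "A").all()
            assert (labs[-n // 10:] == "A").all()
            mid = n // 2
            assert (labs[mid - 5: mid + 5] == "B").all()


class TestSimulateContacts:
    def test_pure_decay_limit_matches_power_law(self):
        cfg = small_config(plaid_amplitude=0.0, tad_contrast=1.0,
                           coverage_scale=100.0, decay_exponent=1.0)
        truth = syn.plant_truth(cfg)
        truth.loop_pixels = {"chr1": []}
        truth.tad_boundaries = {"chr1": []}
        m = syn.simulate_contacts(truth, cfg)["chr1"]
        for d in (0, 1, 5, 10):
            diag = np.diagonal(m.counts, d)
            expect = 100.0 * (1 + d) ** -1.0
            assert diag.mean() == pytest.approx(
                expect, abs=4 * np.sqrt(expect / diag.size))

    def test_flat_limit_mean_equals_coverage(self):
        cfg = small_config(plaid_amplitude=0.0, tad_contrast=1.0,
                           decay_exponent=0.0, coverage_scale=30.0)
        truth = syn.plant_truth(cfg)
        truth.loop_pixels = {"chr1": []}
        truth.tad_boundaries = {"chr1": []}
        m = syn.simulate_contacts(truth, cfg)["chr1"]
        assert m.counts.mean() == pytest.approx(30.0, rel=0.05)

    def test_loop_pixel_enriched_by_strength_over_replicates(self):
        cfg = small_config(plaid_amplitude=0.0, tad_contrast=1.0,
                           loop_strength=5.0, coverage_scale=20.0)
        truth = syn.plant_truth(cfg)
        truth.tad_boundaries = {"chr1": []}
        truth.loop_pixels = {"chr1": [(10, 30)]}
        on, off = [], []
        for rep in range(200):
            cfg_r = small_config(plaid_amplitude=0.0, tad_contrast=1.0,
                                 loop_strength=5.0, coverage_scale=20.0,
                                 rng_seed=rep)
            m = syn.simulate_contacts(truth, cfg_r)["chr1"]
            on.append(m.counts[10, 30])
            off.append(m.counts[5, 25])  # same distance, off-loop
        assert np.mean(on) / np.mean(off) == pytest.approx(5.0, rel=0.1)

    def test_matrices_symmetric_nonnegative_integer(self, default_dataset):
        for m in default_dataset.contacts.values():
            np.testing.assert_array_equal(m.counts, m.counts.T)
            assert (m.counts >= 0).all()
            assert np.all(m.counts == np.round(m.counts))

    def test_truth_config_mismatch_rejected(self):
        cfg = small_config()
        truth = syn.plant_truth(small_config(chrom_length_bp=500_000))
        with pytest.raises(syn.ConfigError):
            syn.simulate_contacts(truth, cfg)


class TestFunctionalLayers:
    def test_snp_in_element_share_matches_closed_form(self):
        """Planted in-element rate f*L/G; the empirical share must sit
        within binomial error of it."""
        cfg = syn.SyntheticConfig(rng_seed=9, n_snps=4000)
        ds = syn.generate(cfg)
        flags = ds.truth.snp_in_element_flags
        from chroma3d import intervals as iv
        prom = ds.layers.atac_peaks_s1[
            ds.layers.atac_peaks_s1["name"].str.startswith("prom_")]
        enh = ds.layers.h3k27ac_peaks[
            ds.layers.h3k27ac_peaks["name"].str.startswith("enh_")]
        L = iv.total_length(pd.concat([prom[["chrom", "start", "end"]],
                                       enh[["chrom", "start", "end"]]]))
        G = sum(cfg.chrom_sizes.values())
        p = cfg.snp_enrichment_factor * L / G
        se = np.sqrt(p * (1 - p) / cfg.n_snps)
        assert flags.mean() == pytest.approx(p, abs=4 * se)

    def test_expression_means_ordered_by_planted_class(self, default_dataset):
        ds = default_dataset
        prof = pd.DataFrame({"gene_id": list(ds.truth.loops_per_gene),
                             "n_loops": list(ds.truth.loops_per_gene.values())})
        df = prof.merge(ds.layers.expression, on="gene_id")
        means = df.groupby(df["n_loops"].clip(upper=6))["expression"].mean()
        vals = means.loc[[0, 1, 3, 4, 6]].tolist()
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_differential_peak_log2_construction(self, default_dataset):
        ds = default_dataset
        pk = ds.layers.atac_peaks_s1
        diff = pk[pk["name"].str.startswith("diff_")]
        assert len(diff) == 2
        # planted 4-fold signal height ratio
        assert (pk.loc[diff.index, "score"] == 20.0).all()
        assert diff["name"].tolist() != []
        # sample-2 peak list lacks the differential peaks
        assert not ds.layers.atac_peaks_s2["name"].str.startswith("diff_").any()

    def test_methylation_in_unit_interval(self, default_dataset):
        for tr in default_dataset.layers.methylation.values():
            for v in tr.values.values():
                assert ((v >= 0) & (v <= 1)).all()
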