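"""Generator contracts: determinism, dosage, genotype rules, additivity."""

import numpy as np
import pandas as pd
import pytest

from poetools import simulate as sim
from poetools.io import write_alignments


def small_config(seed=3):
    cfg = sim.SimulationConfig(seed=seed)
    cfg.genome.n_contigs = 1
    cfg.genome.contig_length = 60_000
    cfg.genome.chloroplast_length = 20_000
    cfg.panel.n_genes = 60
    cfg.panel.n_tes = 30
    cfg.panel.n_mirna = 5
    cfg.panel.n_isr_mat = 6
    cfg.panel.n_isr_pat = 6
    cfg.srna.reads_per_library = 20_000
    cfg.mrna.n_mat_only = 6
    cfg.mrna.n_pat_only = 6
    cfg.mrna.n_antagonistic = 6
    cfg.mrna.n_weak_antagonistic = 8
    cfg.mrna.n_same_sign = 4
    cfg.mrna.n_meg = 4
    cfg.mrna.n_peg = 2
    cfg.nanopare.n_cleavage_targets = 6
    return cfg


class TestGenomeAndSnps:
    def test_fixed_seed_reproducible(self, tmp_path):
        g1, s1, a1, t1 = sim.simulate_genome_and_snps(small_config())
        g2, s2, a2, t2 = sim.simulate_genome_and_snps(small_config())
        assert g1 == g2 and s1 == s2 and a1 == a2
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        r1 = sim.simulate_srna_reads(t1, "WT", 0)
        r2 = sim.simulate_srna_reads(t2, "WT", 0)
        assert r1 == r2
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_alignments(r1, p1)
        write_alignments(r2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_adding_a_replicate_never_perturbs_existing_ones(self):
        _, _, _, truth = sim.simulate_genome_and_snps(small_config())
        rep0_alone = sim.simulate_srna_reads(truth, "WT", 0)
        rep1 = sim.simulate_srna_reads(truth, "WT", 1)
        rep0_again = sim.simulate_srna_reads(truth, "WT", 0)
        assert rep0_alone == rep0_again
        assert rep0_alone != rep1

    def test_zero_snp_rate_gives_empty_table(self):
        cfg = small_config()
        cfg.genome.snp_rate = 0.0
        _, snps, _, _ = sim.simulate_genome_and_snps(cfg)
        assert len(snps) == 0

    def test_snp_count_within_binomial_bounds(self):
        cfg = small_config(seed=5)
        cfg.genome.contig_length = 200_000
        cfg.genome.snp_rate = 1 / 200
        _, snps, _, _ = sim.simulate_genome_and_snps(cfg)
        expected = 1000
        sd = np.sqrt(200_000 * (1 / 200) * (1 - 1 / 200))
        # adjacent-position pruning removes a few, hence the one-sided slack
        assert expected - 4 * sd - 10 <= len(snps) <= expected + 4 * sd

    def test_no_adjacent_snps_and_none_on_chloroplast(self):
        _, snps, _, _ = sim.simulate_genome_and_snps(small_config())
        pos = [r.position for r in snps if r.contig == "chr1"]
        assert min(np.diff(pos)) > 1
        assert all(r.contig != "chrC" for r in snps)

    def test_annotations_non_overlapping_within_class(self):
        _, _, ann, _ = sim.simulate_genome_and_snps(small_config())
        by_class: dict = {}
        for f in ann:
            by_class.setdefault((f.contig, f.feature_class), []).append(f)
        for feats in by_class.values():
            feats.sort(key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                assert a.end <= b.start

    def test_overfull_panel_raises(self):
        cfg = small_config()
        cfg.panel.n_genes = 500
        with pytest.raises(ValueError, match="panel"):
            sim.simulate_genome_and_snps(cfg)


@pytest.fixture(scope="module")
def truth():
    return sim.simulate_genome_and_snps(small_config())[3]


class TestSrnaGenotypeRules:
    @staticmethod
    def reads_in(reads, row):
        return [r for r in reads
                if r.contig == row["contig"] and r.start < row["end"] and
                r.end > row["start"]]

    def test_poliv_loci_silent_in_null(self, truth):
        reads = sim.simulate_srna_reads(truth, "null", 0)
        non_bg = [r for r in reads if not r.read_id.split(".")[-1]
                  .startswith("bg")]
        poliv = truth.srna_loci[truth.srna_loci["cls"] == "polIV_biallelic"]
        for _, row in poliv.iterrows():
            assert self.reads_in(non_bg, row) == []

    def test_mat_memory_loci_follow_the_mother(self, truth):
        mat_loci = truth.srna_loci[truth.srna_loci["cls"] == "mat_memory"]
        active = sim.simulate_srna_reads(truth, "pat_het", 0)
        silent = sim.simulate_srna_reads(truth, "mat_het", 0)
        n_active = sum(len(self.reads_in(active, row))
                       for _, row in mat_loci.iterrows())
        n_silent = sum(len(self.reads_in(
            [r for r in silent if "bg" not in r.read_id], row))
            for _, row in mat_loci.iterrows())
        assert n_active > 50 * max(n_silent, 1)

    def test_mirna_loci_unaffected_by_genotype(self, truth):
        mirna = truth.srna_loci[truth.srna_loci["cls"] == "mirna"]
        totals = {}
        for genotype in sim.GENOTYPES:
            reads = sim.simulate_srna_reads(truth, genotype, 0)
            totals[genotype] = sum(len(self.reads_in(reads, row))
                                   for _, row in mirna.iterrows())
        vals = np.array(list(totals.values()), dtype=float)
        assert vals.min() > 0.5 * vals.max()

    def test_wt_maternal_fraction_matches_configured_bias(self, truth):
        """At biallelic loci the realized maternal fraction of reads drawn
        from the parental genomes tracks the per-locus bias truth."""
        reads = sim.simulate_srna_reads(truth, "WT", 0)
        poliv = truth.srna_loci[truth.srna_loci["cls"] == "polIV_biallelic"]
        n_mat = n_tot = 0
        expected = 0.0
        for _, row in poliv.iterrows():
            sub = self.reads_in(
                [r for r in reads if "bg" not in r.read_id], row)
            mat_seq = truth.maternal_sequence(row["contig"])
            pat_seq = truth.paternal_sequence(row["contig"])
            for r in sub:
                truly_mat = r.sequence == mat_seq[r.start:r.end]
                truly_pat = r.sequence == pat_seq[r.start:r.end]
                if truly_mat and not truly_pat:
                    n_mat += 1
                if not (truly_mat and truly_pat):
                    n_tot += 1
                    expected += row["maternal_bias"]
        frac = n_mat / n_tot
        se = np.sqrt(0.25 / n_tot)
        assert abs(frac - expected / n_tot) < 4 * se

    def test_unknown_genotype_rejected(self, truth):
        with pytest.raises(ValueError, match="genotype"):
            sim.simulate_srna_reads(truth, "het", 0)


class TestMrna:
    def test_noiseless_means_exactly_additive(self, truth):
        """log2 mean(null) - log2 mean(WT) = beta_mat + beta_pat, exactly."""
        for gene in truth.genes.index:
            lhs = np.log2(truth.mrna_mean(gene, "null")) - \
                np.log2(truth.mrna_mean(gene, "WT"))
            row = truth.genes.loc[gene]
            assert lhs == pytest.approx(row["beta_mat"] + row["beta_pat"],
                                        abs=1e-9)

    def test_null_gene_means_shared_across_genotypes(self, truth):
        quiet = truth.genes[(truth.genes["beta_mat"] == 0) &
                            (truth.genes["beta_pat"] == 0)].index[0]
        means = {g: truth.mrna_mean(quiet, g) for g in sim.GENOTYPES}
        assert len(set(means.values())) == 1

    def test_counts_follow_planted_fold_changes(self, truth):
        total, _, _ = sim.simulate_mrna_counts(truth)
        genes = truth.genes
        strong = genes[np.abs(genes["beta_mat"]) >= 1.5].index
        wt = total.counts.loc[strong, total.samples_for("WT")].mean(axis=1)
        mh = total.counts.loc[strong,
                              total.samples_for("mat_het")].mean(axis=1)
        observed = np.log2((mh + 0.5) / (wt + 0.5))
        assert np.corrcoef(observed,
                           genes.loc[strong, "beta_mat"])[0, 1] > 0.95

    def test_nonimprinted_maternal_fraction_near_two_thirds(self, truth):
        _, mat, pat = sim.simulate_mrna_counts(truth)
        ni = truth.genes.index[truth.genes["imprint"] == "none"]
        m = mat.counts.loc[ni].to_numpy().sum()
        p = pat.counts.loc[ni].to_numpy().sum()
        assert m / (m + p) == pytest.approx(2 / 3, abs=0.02)

    def test_imprinted_split_near_configured_bias(self, truth):
        _, mat, pat = sim.simulate_mrna_counts(truth)
        megs = truth.genes.index[truth.genes["imprint"] == "maternal"]
        m = mat.counts.loc[megs].to_numpy().sum()
        p = pat.counts.loc[megs].to_numpy().sum()
        assert m / (m + p) > 0.9

    def test_replicate_floor_enforced(self, truth):
        with pytest.raises(ValueError, match="replicates"):
            sim.simulate_mrna_counts(truth, n_replicates=1)


class TestMethylome:
    def test_perfect_conversion_unmethylated_chloroplast(self, truth):
        truth.config.methylome.conversion_rate = 1.0
        try:
            calls = sim.simulate_methylome(truth, "WT", 0, contigs=["chrC"])
        finally:
            truth.config.methylome.conversion_rate = 0.99
        assert calls["n_meth"].sum() == 0

    def test_incomplete_conversion_apparent_methylation(self, truth):
        calls = sim.simulate_methylome(truth, "WT", 0, contigs=["chrC"])
        apparent = calls["n_meth"].sum() / calls["n_total"].sum()
        assert apparent == pytest.approx(0.01, abs=0.002)

    def test_genomewide_maternal_read_fraction(self, truth):
        calls = sim.simulate_methylome(truth, "WT", 0, contigs=["chr1"])
        by_allele = calls.groupby("allele")["n_total"].sum()
        frac = by_allele["maternal"] / (by_allele["maternal"] +
                                        by_allele["paternal"])
        assert frac == pytest.approx(2 / 3, abs=0.005)

    def test_planted_chh_levels_by_genotype(self, truth):
        regions = truth.meth_regions
        mat_region = regions[regions["memory"] == "mat"].iloc[0]
        for genotype, expect in (("WT", 0.30), ("pat_het", 0.30),
                                 ("mat_het", 0.05), ("null", 0.05)):
            calls = sim.simulate_methylome(truth, genotype, 0,
                                           contigs=[mat_region["contig"]])
            inside = calls[(calls["pos"] >= mat_region["start"]) &
                           (calls["pos"] < mat_region["end"]) &
                           (calls["context"] == "CHH")]
            level = inside["n_meth"].sum() / inside["n_total"].sum()
            assert level == pytest.approx(expect, abs=0.04)


class TestNanopare:
    def test_tss_spike_scales_with_expression(self, truth):
        genes = truth.genes
        up = genes[(genes["beta_mat"] + genes["beta_pat"]) >= 1.5].index
        wt = sim.simulate_nanopare(truth, "WT", 0)
        null = sim.simulate_nanopare(truth, "null", 0)

        def tss_count(df, gene):
            g = genes.loc[gene]
            tss = int(g["start"]) if g["strand"] == "+" else int(g["end"]) - 1
            row = df[(df["contig"] == g["contig"]) & (df["pos"] == tss)]
            return row["count"].sum()

        ratios = [(tss_count(null, g) + 1) / (tss_count(wt, g) + 1)
                  for g in up]
        assert np.median(ratios) > 2.0

    def test_cleavage_spike_absent_in_null(self, truth):
        targets = truth.genes[truth.genes["cleavage_target"]]
        null = sim.simulate_nanopare(truth, "null", 0)
        for gene, g in targets.iterrows():
            site = int((g["start"] + g["end"]) // 2)
            row = null[(null["contig"] == g["contig"]) &
                       (null["pos"] == site)]
            assert row["count"].sum() <= 2  # at most sparse noise
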