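from collections import Counter

import numpy as np
import pytest
from scipy.stats import spearmanr

from holoseq.io import GeneModel, GenomicInterval
from holoseq.synthetic import (
    default_antisense_scenario,
    make_small_rna_refs,
    simulate_alignment_library,
    simulate_antisense_dataset,
    simulate_barcoded_library,
    simulate_dual_transcriptome,
    simulate_small_rna_pool,
)


class TestAlignmentLibrary:
    def test_uniform_profile_bin_counts(self, single_exon_gene):
        depth = 10_000
        reads, _ = simulate_alignment_library([single_exon_gene], "uniform", depth, seed=42)
        starts = np.array([r.interval.start for r in reads])
        bins = np.bincount(starts // 10, minlength=100)
        sigma = np.sqrt(depth * 0.01 * 0.99)
        assert np.abs(bins - 100).max() < 5 * sigma

    def test_carrier_fraction_binomial_bound(self, single_exon_gene):
        reads, _ = simulate_alignment_library(
            [single_exon_gene], depth=1000, carrier_fraction=0.5, seed=1
        )
        n_carrier = sum(1 for r in reads if r.source_ref == "carrier")
        assert abs(n_carrier - 500) < 5 * np.sqrt(1000 * 0.25)

    def test_carrier_reads_never_on_genome(self, single_exon_gene):
        reads, _ = simulate_alignment_library(
            [single_exon_gene], depth=500, carrier_fraction=0.4, seed=2
        )
        for r in reads:
            if r.source_ref == "carrier":
                assert r.interval.chrom == "carrier"

    def test_depth_conservation_and_determinism(self, single_exon_gene):
        a, _ = simulate_alignment_library([single_exon_gene], depth=777, seed=9)
        b, _ = simulate_alignment_library([single_exon_gene], depth=777, seed=9)
        assert len(a) == 777
        assert a == b

    def test_unknown_profile_rejected(self, single_exon_gene):
        with pytest.raises(ValueError, match="profile"):
            simulate_alignment_library([single_exon_gene], "sideways", 10, seed=0)

    def test_central_dropout_depletes_middle_of_long_genes(self):
        iv = GenomicInterval("chr1", 0, 15_000, "+")
        gene = GeneModel("big", iv, (iv,))
        reads, _ = simulate_alignment_library([gene], "central_dropout", 20_000, seed=3)
        starts = np.array([r.interval.start for r in reads])
        rel = starts / 15_000
        mid = ((rel > 0.4) & (rel < 0.6)).mean()
        edge = (rel < 0.2).mean()
        assert mid < edge / 2


class TestBarcodedLibrary:
    def test_no_cycles_one_barcode_per_template(self):
        _, truth = simulate_barcoded_library(
            n_positions=20, templates_per_position=1, cycles=0, seed=0
        )
        per_pos = Counter(key for key, _ in truth.barcode_lineage)
        assert all(v == 1 for v in per_pos.values())

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            simulate_barcoded_library(
                n_positions=2, templates_per_position=1, cycles=0, reads_sampled=3, seed=0
            )

    def test_cross_template_collision_rate_matches_birthday_product(self):
        from holoseq.quant import barcode_collision_probability

        n_positions = 20_000
        _, truth = simulate_barcoded_library(
            n_positions=n_positions, templates_per_position=10, cycles=0, seed=11
        )
        distinct: dict = {}
        for key, bc in truth.barcode_lineage:
            distinct.setdefault(key, set()).add(bc)
        n_collided = sum(1 for v in distinct.values() if len(v) < 10)
        p = barcode_collision_probability(10, 65536)
        sigma = np.sqrt(n_positions * p * (1 - p))
        assert abs(n_collided - n_positions * p) < 5 * sigma

    def test_determinism(self):
        a = simulate_barcoded_library(5, 3, 2, reads_sampled=40, seed=4)[0]
        b = simulate_barcoded_library(5, 3, 2, reads_sampled=40, seed=4)[0]
        assert a == b


class TestSmallRNAPool:
    def test_pure_mirna_composition(self):
        refs = make_small_rna_refs(seed=0)
        reads, truth = simulate_small_rna_pool(refs, {"miRNA": 1.0}, n_reads=200, seed=1)
        assert all(v == "miRNA" for v in truth.read_labels.values())
        assert all(len(seq) == 50 for _, seq in reads)

    def test_empty_pool(self):
        refs = make_small_rna_refs(seed=0)
        reads, _ = simulate_small_rna_pool(refs, {"miRNA": 1.0}, n_reads=0, seed=1)
        assert reads == []

    def test_composition_within_binomial_bound(self):
        refs = make_small_rna_refs(seed=0)
        comp = {"miRNA": 0.5, "tsRNA": 0.3, "snoRNA": 0.2}
        _, truth = simulate_small_rna_pool(refs, comp, n_reads=10_000, seed=2)
        counts = Counter(truth.read_labels.values())
        for cls, frac in comp.items():
            sigma = np.sqrt(10_000 * frac * (1 - frac))
            assert abs(counts[cls] - 10_000 * frac) < 5 * sigma

    def test_fractions_must_sum_to_one(self):
        refs = make_small_rna_refs(seed=0)
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_small_rna_pool(refs, {"miRNA": 0.5}, n_reads=10, seed=0)

    def test_mature_names_must_match(self):
        from holoseq.smallrna import SmallRNARefs

        with pytest.raises(ValueError, match="unknown pre-miRNA"):
            SmallRNARefs(pre_mirna={"mirA": "ACGT" * 20}, mature={"mirB": [(0, 22)]})

    def test_determinism(self):
        refs = make_small_rna_refs(seed=0)
        a = simulate_small_rna_pool(refs, {"snoRNA": 1.0}, n_reads=50, seed=6)[0]
        b = simulate_small_rna_pool(refs, {"snoRNA": 1.0}, n_reads=50, seed=6)[0]
        assert a == b


class TestDualTranscriptome:
    def test_no_repression_no_correlation(self):
        from holoseq.synthetic import default_repression_spec

        mrna, mirna, truth = simulate_dual_transcriptome(
            repression_spec=default_repression_spec(beta=0.0), seed=7
        )
        rhos = [
            spearmanr(mirna.values.loc[m], mrna.values.loc[g]).statistic
            for m, g, _ in truth.mirna_targets
        ]
        assert abs(np.mean(rhos)) < 0.2

    def test_strong_repression_all_negative(self):
        mrna, mirna, truth = simulate_dual_transcriptome(seed=8)
        for m, g, beta in truth.mirna_targets:
            assert beta >= 2
            rho = spearmanr(mirna.values.loc[m], mrna.values.loc[g]).statistic
            assert rho < 0

    def test_matrices_non_negative_and_deterministic(self):
        m1, mi1, _ = simulate_dual_transcriptome(seed=9)
        m2, mi2, _ = simulate_dual_transcriptome(seed=9)
        assert (m1.values.to_numpy() >= 0).all()
        assert m1.values.equals(m2.values) and mi1.values.equals(mi2.values)

    def test_absent_edge_feature_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            simulate_dual_transcriptome(
                repression_spec=[("nonexistent-mir", "gene0001", 2.0)],
                se_spec=[],
                seed=0,
            )

    def test_truth_labels_cover_all_cells(self):
        mrna, _, truth = simulate_dual_transcriptome(seed=10)
        assert set(truth.subpop_labels) == set(mrna.cell_ids)
        assert set(truth.subpop_labels.values()) == {"I", "II", "III"}


class TestAntisenseDataset:
    def test_background_free_single_cluster_per_planted(self):
        genes, planted = default_antisense_scenario(n_genes=1, seed=0)
        reads, _ = simulate_antisense_dataset(genes, planted, 100, 0.0, seed=1)
        assert len(reads) == 100
        assert all(r.strand == "-" for r in reads)
        assert all(planted[0].start <= r.interval.start < planted[0].end for r in reads)

    def test_zero_antisense_reads_background_only(self):
        genes, planted = default_antisense_scenario(n_genes=2, seed=0)
        reads, truth = simulate_antisense_dataset(genes, planted, 0, 0.001, seed=2)
        assert all(lbl == "background" for lbl in truth.read_labels.values())

    def test_same_strand_overlap_rejected(self):
        genes, _ = default_antisense_scenario(n_genes=1, seed=0)
        bad = [GenomicInterval("chr1", 10_500, 11_500, "+")]  # same strand as gene
        with pytest.raises(ValueError, match="same-strand"):
            simulate_antisense_dataset(genes, bad, 10, 0.0, seed=0)

    def test_determinism(self):
        genes, planted = default_antisense_scenario(seed=0)
        a = simulate_antisense_dataset(genes, planted, 50, 0.001, seed=5)[0]
        b = simulate_antisense_dataset(genes, planted, 50, 0.001, seed=5)[0]
        assert a == b
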