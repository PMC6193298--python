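import numpy as np
import pandas as pd
import pytest

from holoseq.io import AlignmentRecord, GenomicInterval
from holoseq.quant import (
    BarcodeModel,
    barcode_collision_probability,
    barcoded_gene_counts,
    count_reads,
    count_restriction_sites,
    dedup_barcoded,
    max_distinct_barcoded_reads,
    normalize,
    partition_carrier,
    select_expressed_avg,
    select_expressed_reads_and_rpkm,
)
from holoseq.synthetic import simulate_alignment_library, simulate_barcoded_library


def _read(start, end, strand="+", chrom="chr1", **kw):
    return AlignmentRecord(
        f"r{start}", GenomicInterval(chrom, start, end, strand), **kw
    )


class TestCountReads:
    def test_read_inside_exon_sense(self, two_exon_gene):
        assert count_reads([_read(120, 170)], two_exon_gene, "exon", "sense") == 1

    def test_opposite_strand_modes(self, two_exon_gene):
        reads = [_read(120, 170, strand="-")]
        assert count_reads(reads, two_exon_gene, "exon", "sense") == 0
        assert count_reads(reads, two_exon_gene, "exon", "both") == 1

    def test_boundary_reads_count_to_exon_only(self, two_exon_gene):
        # five reads straddling the exon/intron boundary at 200
        reads = [_read(180 + i, 230 + i) for i in range(5)]
        assert count_reads(reads, two_exon_gene, "exon") == 5
        assert count_reads(reads, two_exon_gene, "intron") == 0

    def test_intron_only_read(self, two_exon_gene):
        reads = [_read(210, 260)]
        assert count_reads(reads, two_exon_gene, "exon") == 0
        assert count_reads(reads, two_exon_gene, "intron") == 1

    def test_non_unique_reads_ignored(self, two_exon_gene):
        reads = [_read(120, 170, is_unique=False)]
        assert count_reads(reads, two_exon_gene) == 0

    def test_spliced_read_counts_once(self, two_exon_gene):
        rec = AlignmentRecord(
            "r",
            GenomicInterval("chr1", 150, 350, "+"),
            blocks=(
                GenomicInterval("chr1", 150, 200, "+"),
                GenomicInterval("chr1", 300, 350, "+"),
            ),
        )
        assert count_reads([rec], two_exon_gene, "exon") == 1

    def test_empty_input(self, two_exon_gene):
        assert count_reads([], two_exon_gene) == 0


class TestNormalize:
    def test_rpkm_unit_case(self):
        assert normalize(10, 1000, 10**6, "RPKM") == 10.0

    def test_zero_count(self):
        assert normalize(0, 1000, 10**6, "RPKM") == 0.0

    def test_rpkm_arithmetic(self):
        # 37 reads, 2.5 kb feature, 6.8M mapped
        assert normalize(37, 2500, 6_800_000, "RPKM") == pytest.approx(
            37 / (2.5 * 6.8), rel=1e-12
        )

    def test_rpm(self):
        assert normalize(100, 0, 10**6, "RPM") == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize(1, 1000, 0, "RPKM")

    def test_rpkm_equals_rpm_over_kb(self, rng):
        for _ in range(10):
            c = int(rng.integers(0, 1000))
            L = int(rng.integers(100, 10_000))
            T = int(rng.integers(10**5, 10**7))
            assert normalize(c, L, T, "RPKM") == pytest.approx(
                normalize(c, L, T, "RPM") / (L / 1e3), rel=1e-12
            )


class TestSelectExpressed:
    def test_threshold_is_strict(self):
        rpkm = pd.DataFrame({"lib1": [0.1, 0.11]}, index=["a", "b"])
        assert select_expressed_avg(rpkm, 0.1) == ["b"]

    def test_reads_threshold_is_inclusive(self):
        counts = pd.DataFrame({"lib1": [10, 9]}, index=["a", "b"])
        rpkm = pd.DataFrame({"lib1": [0.2, 0.2]}, index=["a", "b"])
        assert select_expressed_reads_and_rpkm(counts, rpkm) == ["a"]

    def test_empty_matrix(self):
        empty = pd.DataFrame(index=pd.Index([], dtype=str))
        assert select_expressed_avg(empty) == []


class TestPartitionCarrier:
    def test_no_carrier_reads_vacuous_efficiency(self):
        cellular, carrier, eff = partition_carrier([_read(0, 50)])
        assert eff == 1.0 and len(carrier) == 0 and len(cellular) == 1

    def test_all_carrier_matched(self):
        reads = [_read(i, i + 50, source_ref="carrier") for i in range(100)]
        cellular, carrier, eff = partition_carrier(reads)
        assert eff == 1.0 and len(carrier) == 100

    def test_simulated_carrier_fraction(self, single_exon_gene):
        reads, truth = simulate_alignment_library(
            [single_exon_gene], depth=2000, carrier_fraction=0.3, seed=5
        )
        cellular, carrier, eff = partition_carrier(reads)
        assert eff == 1.0
        # cellular fraction ~ 0.7 within 5 sigma
        sigma = np.sqrt(2000 * 0.3 * 0.7)
        assert abs(len(carrier) - 600) < 5 * sigma
        assert len(cellular) + len(carrier) == 2000


class TestRestrictionSites:
    def test_motif_itself(self):
        assert count_restriction_sites("GCGGCCGC") == [0]

    def test_absent_motif(self):
        assert count_restriction_sites("ATATATATAT") == []

    def test_overlapping_occurrences(self):
        assert count_restriction_sites("GCGGCCGCGGCCGC") == [0, 6]

    def test_sliding_window_oracle(self, rng):
        motif = "GCGGCCGC"
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500)) + motif * 3
        expected = [
            i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
        ]
        assert count_restriction_sites(seq, motif) == expected


class TestDedupBarcoded:
    def test_distinct_barcodes_counted(self):
        reads = [
            _read(100, 150, barcode="AAAAAAAA"),
            _read(100, 150, barcode="AAAAAAAA"),
            _read(100, 150, barcode="CCCCCCCC"),
        ]
        counts, missing = dedup_barcoded(reads)
        assert counts[("chr1", 100, "+")] == 2 and missing == 0

    def test_pcr_duplicates_collapse_to_one(self):
        reads = [_read(100, 150, barcode="ACGTACGT") for _ in range(1000)]
        counts, _ = dedup_barcoded(reads)
        assert counts[("chr1", 100, "+")] == 1

    def test_missing_barcodes_tallied(self):
        counts, missing = dedup_barcoded([_read(0, 50)])
        assert missing == 1 and counts == {}

    def test_five_prime_position_on_minus_strand(self):
        reads = [
            _read(100, 150, strand="-", barcode="AAAAAAAA"),
            _read(120, 150, strand="-", barcode="CCCCCCCC"),
        ]
        counts, _ = dedup_barcoded(reads)
        # both reads share the 5' coordinate 149 on the minus strand
        assert counts == {("chr1", 149, "-"): 2}

    def test_collision_free_simulation_recovers_molecule_counts(self):
        reads, truth = simulate_barcoded_library(
            n_positions=50,
            templates_per_position=5,
            cycles=4,
            reads_sampled=50 * 5 * 16,  # exhaustive sampling
            seed=3,
        )
        counts, _ = dedup_barcoded(reads)
        # ignore positions where two templates drew the same barcode
        from collections import Counter

        per_pos = Counter(key for key, _ in truth.barcode_lineage)
        distinct = {}
        for key, bc in truth.barcode_lineage:
            distinct.setdefault(key, set()).add(bc)
        for key, n_templates in truth.molecules_per_position.items():
            if len(distinct[key]) == n_templates:  # collision-free
                assert counts[key] == n_templates


class TestBarcodeCollision:
    def test_single_read_no_collision(self):
        assert barcode_collision_probability(1, 65536) == 0.0

    def test_two_reads_two_barcodes(self):
        assert barcode_collision_probability(2, 2) == pytest.approx(0.5)

    def test_printed_bound(self):
        p = barcode_collision_probability(10, 65536)
        assert p == pytest.approx(6.864e-4, rel=1e-3)
        assert p < 0.01

    def test_pigeonhole(self):
        assert barcode_collision_probability(5, 4) == 1.0

    def test_monotone_in_reads_and_barcodes(self):
        ps = [barcode_collision_probability(n, 1000) for n in range(1, 50)]
        assert all(a < b for a, b in zip(ps, ps[1:]))
        qs = [barcode_collision_probability(10, b) for b in (100, 1000, 10_000)]
        assert qs[0] > qs[1] > qs[2]


class TestAmplificationCeiling:
    def test_single_template_no_cycles(self):
        assert max_distinct_barcoded_reads(BarcodeModel(max_reads_per_position=1, cycles=0)) == 1

    def test_default_model_ceiling(self):
        model = BarcodeModel()
        assert model.n_barcodes == 65536 == 4**8
        assert max_distinct_barcoded_reads(model) == 10_240

    def test_lineage_tree_enumeration(self):
        # 3 templates doubling twice: enumerate the lineage tree by hand
        pool = ["t0", "t1", "t2"]
        for _ in range(2):
            pool = pool + list(pool)
        assert len(pool) == 12
        assert (
            max_distinct_barcoded_reads(BarcodeModel(max_reads_per_position=3, cycles=2))
            == 12
        )


class TestBarcodedGeneCounts:
    def test_counts_sum_over_exonic_positions(self, two_exon_gene):
        reads = [
            _read(120, 170, barcode="AAAAAAAA"),
            _read(120, 170, barcode="CCCCCCCC"),
            _read(350, 390, barcode="AAAAAAAA"),
            _read(250, 290, barcode="GGGGGGGG"),  # intronic 5' end: not counted
        ]
        counts = barcoded_gene_counts(reads, [two_exon_gene])
        assert counts["gA"] == 3
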