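from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holoseq.networks import (
    NetworkEdge,
    TargetCatalog,
    de_test,
    filter_detected,
    filter_detected_min_cells,
    infer_negative_network,
    oncomir_module,
    spearman_edge,
    suppressor_module,
)
from holoseq.synthetic import simulate_dual_transcriptome


def _brute_force_spearman(x, y):
    """Rank (average method) then Pearson on the ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanEdge:
    def test_perfectly_antimonotone(self):
        rho, p, p_exact = spearman_edge([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == pytest.approx(-1.0)

    def test_identical_vectors(self):
        rho, _, _ = spearman_edge([1, 2, 3, 4], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)

    def test_hand_ranked_example(self):
        # d = (-4, -1, -1, 2, 4), sum d^2 = 38: rho = 1 - 6*38/120 = -0.9
        rho, _, _ = spearman_edge([1, 2, 3, 4, 5], [5, 3, 4, 2, 1])
        assert rho == pytest.approx(-0.9)
        assert rho == pytest.approx(_brute_force_spearman([1, 2, 3, 4, 5], [5, 3, 4, 2, 1]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            spearman_edge([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_brute_force_tie_free(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 20))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            rho, _, _ = spearman_edge(x, y)
            assert rho == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)

    def test_average_rank_on_all_four_element_multisets(self):
        values = [0.0, 1.0, 2.0]
        vectors = [v for v in product(values, repeat=4) if len(set(v)) > 1]
        for x in vectors:
            for y in vectors:
                rho, _, _ = spearman_edge(x, y)
                assert rho == pytest.approx(_brute_force_spearman(x, y), abs=1e-12)

    def test_exact_permutation_p_for_antimonotone_n5(self):
        # only the two extreme orderings of 120 reach |rho| = 1
        _, _, p_exact = spearman_edge([1, 2, 3, 4, 5], [9, 7, 5, 3, 1])
        assert p_exact == pytest.approx(2 / 120)

    def test_exact_p_only_for_small_n(self):
        _, _, p_exact = spearman_edge(list(range(12)), list(range(12))[::-1])
        assert p_exact is None


class TestFilterDetected:
    def test_32_cell_arithmetic(self):
        cells = [f"c{i}" for i in range(32)]
        rows = {
            "kept11": [1.0] * 11 + [0.0] * 21,
            "dropped10": [1.0] * 10 + [0.0] * 22,
            "allon": [1.0] * 32,
        }
        m = pd.DataFrame.from_dict(rows, orient="index", columns=cells)
        assert filter_detected(m) == ["kept11", "allon"]

    def test_14_cell_arithmetic(self):
        cells = [f"c{i}" for i in range(14)]
        rows = {"kept5": [1.0] * 5 + [0.0] * 9, "dropped4": [1.0] * 4 + [0.0] * 10}
        m = pd.DataFrame.from_dict(rows, orient="index", columns=cells)
        assert filter_detected(m) == ["kept5"]

    def test_min_cells_rule(self):
        cells = ["a", "b", "c"]
        m = pd.DataFrame([[1, 0, 0], [2, 3, 0]], index=["one", "two"], columns=cells)
        assert filter_detected_min_cells(m, min_reads=1, min_cells=2) == ["two"]


class TestDeTest:
    def test_identical_groups_p_one(self):
        assert de_test([3, 3, 3], [3, 3, 3], "student_two_tailed") == 1.0

    def test_clear_separation_two_tailed(self):
        # pooled t with df=4, t ~ 12.2
        p = de_test([10, 11, 12], [0, 1, 2], "student_two_tailed")
        assert p < 0.001
        t = (11 - 1) / np.sqrt(1.0 * (2 / 3))
        assert p == pytest.approx(2 * stats.t.sf(t, df=4), rel=1e-9)

    def test_one_tailed_direction_of_observed_difference(self):
        p1 = de_test([10, 11, 12], [0, 1, 2], "welch_one_tailed")
        p2 = de_test([0, 1, 2], [10, 11, 12], "welch_one_tailed")
        assert p1 == pytest.approx(p2)
        assert p1 < 0.01

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            de_test([1, 2], [3, 4], "mann_whitney")


class TestCatalog:
    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            TargetCatalog((("m1", "g1", "a"), ("m1", "g1", "b")))

    def test_tsv_reader_deduplicates(self):
        tsv = "miRNA\tTarget Gene\tSupport Type\nm1\tg1\tstrong\nm1\tg1\tweak\nm2\tg2\tstrong\n"
        cat = TargetCatalog.from_tsv(tsv)
        assert len(cat.pairs) == 2


class TestInferNegativeNetwork:
    def _matrices(self, rng, n_cells=32):
        cells = [f"c{i}" for i in range(n_cells)]
        m = pd.DataFrame(
            rng.random((3, n_cells)) + 1.0, index=["m1", "m2", "m3"], columns=cells
        )
        g = pd.DataFrame(
            rng.random((3, n_cells)) + 1.0, index=["g1", "g2", "g3"], columns=cells
        )
        return m, g

    def test_undetected_mirna_pair_absent(self, rng):
        m, g = self._matrices(rng)
        m.loc["m1"] = 0.0
        cat = TargetCatalog((("m1", "g1", ""), ("m2", "g2", "")))
        edges = infer_negative_network(m, g, cat, alpha=1.0)
        assert all(e.mirna_id != "m1" for e in edges)

    def test_empty_catalog_empty_network(self, rng):
        m, g = self._matrices(rng)
        assert infer_negative_network(m, g, TargetCatalog(())) == []

    def test_positive_correlation_never_retained(self, rng):
        m, g = self._matrices(rng)
        g.loc["g1"] = m.loc["m1"] * 2  # perfect positive correlation
        cat = TargetCatalog((("m1", "g1", ""),))
        assert infer_negative_network(m, g, cat) == []

    def test_planted_edges_recovered(self):
        mrna, mirna, truth = simulate_dual_transcriptome(seed=42)
        cat = TargetCatalog(tuple((m, g, "planted") for m, g, _ in truth.mirna_targets))
        edges = infer_negative_network(mirna.values, mrna.values, cat)
        got = {(e.mirna_id, e.gene_id) for e in edges}
        assert got == {(m, g) for m, g, _ in truth.mirna_targets}
        assert all(e.rho < 0 and e.p < 0.05 for e in edges)

    def test_power_monotone_in_effect_size(self):
        from holoseq.synthetic import default_repression_spec

        recovery = []
        for beta in (0.0, 0.75, 2.0):
            hits = 0
            for seed in range(5):
                mrna, mirna, truth = simulate_dual_transcriptome(
                    repression_spec=default_repression_spec(beta=beta), seed=seed
                )
                cat = TargetCatalog(
                    tuple((m, g, "") for m, g, _ in truth.mirna_targets)
                )
                edges = infer_negative_network(mirna.values, mrna.values, cat)
                hits += len(edges)
            recovery.append(hits)
        assert recovery[0] <= recovery[1] <= recovery[2]
        assert recovery[2] > recovery[0]


class TestModules:
    def _planted(self, seed=0):
        mrna, mirna, truth = simulate_dual_transcriptome(seed=seed)
        cat = TargetCatalog(tuple((m, g, "") for m, g, _ in truth.mirna_targets))
        return mrna, mirna, truth, cat

    def test_oncomir_module_keeps_de_edges(self):
        mrna, mirna, truth, cat = self._planted(seed=3)
        # make one planted miRNA and its target differential between I and II+III
        mid, gid, _ = truth.mirna_targets[0]
        cells_i = [c for c, s in truth.subpop_labels.items() if s == "I"]
        mirna.values.loc[mid, cells_i] *= 8
        mrna.values.loc[gid, cells_i] /= 8
        edges = oncomir_module(
            mirna.values, mrna.values, cat, [mid], truth.subpop_labels
        )
        assert {(e.mirna_id, e.gene_id) for e in edges} <= {(mid, gid)}
        if edges:
            assert "differential_expression" in edges[0].passed_filters

    def test_oncomir_module_drops_non_de_target(self, rng):
        cells = [f"c{i}" for i in range(32)]
        labels = {c: ("I" if i < 11 else "II" if i < 22 else "III") for i, c in enumerate(cells)}
        x = np.linspace(1, 5, 32)
        m = pd.DataFrame([x], index=["m1"], columns=cells)
        g = pd.DataFrame([x[::-1]], index=["g1"], columns=cells)
        # m1/g1 perfectly anticorrelated but identically distributed between
        # subpopulations: the DE stage must reject
        m.loc["m1"] = np.tile([1, 2, 3, 4], 8)
        g.loc["g1"] = 5 - m.loc["m1"]
        cat = TargetCatalog((("m1", "g1", ""),))
        assert oncomir_module(m, g, cat, ["m1"], labels) == []

    def test_empty_oncomir_list(self, rng):
        cells = [f"c{i}" for i in range(32)]
        m = pd.DataFrame(rng.random((2, 32)), index=["m1", "m2"], columns=cells)
        g = pd.DataFrame(rng.random((2, 32)), index=["g1", "g2"], columns=cells)
        labels = {c: "I" for c in cells}
        cat = TargetCatalog((("m1", "g1", ""),))
        assert oncomir_module(m, g, cat, [], labels) == []

    def test_suppressor_module_excludes_oncomirs(self):
        mrna, mirna, truth, cat = self._planted(seed=4)
        subset = [c for c, s in truth.subpop_labels.items() if s in ("II", "III")]
        oncomir = truth.mirna_targets[0][0]
        edges = suppressor_module(mirna.values, mrna.values, cat, [oncomir], subset)
        assert all(e.mirna_id != oncomir for e in edges)
        # the remaining planted edges are retained within the subset
        expected = {(m, g) for m, g, _ in truth.mirna_targets if m != oncomir}
        assert {(e.mirna_id, e.gene_id) for e in edges} == expected

    def test_suppressor_detection_uses_subset(self):
        cells = [f"c{i}" for i in range(14)]
        m = pd.DataFrame([[0.0] * 9 + [1, 2, 3, 4, 5]], index=["m1"], columns=cells)
        g = pd.DataFrame([[5, 4, 3, 2, 1] + [1.0] * 9], index=["g1"], columns=cells)
        cat = TargetCatalog((("m1", "g1", ""),))
        # m1 nonzero in 5 of 14 cells: kept; zero in 10 would be dropped
        edges = suppressor_module(m, g, cat, [], cells, alpha=1.0)
        assert len(edges) == 1
        m.loc["m1", cells[9]] = 0.0  # now nonzero in only 4
        assert suppressor_module(m, g, cat, [], cells, alpha=1.0) == []

    def test_empty_subset_rejected(self, rng):
        m = pd.DataFrame(rng.random((1, 4)), index=["m1"], columns=list("abcd"))
        with pytest.raises(ValueError, match="nonempty"):
            suppressor_module(m, m, TargetCatalog(()), [], [])
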