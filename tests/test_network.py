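import itertools

import numpy as np
import pandas as pd
import pytest

from mirmaster.de import size_factors, vst_like_transform
from mirmaster.network import (bootstrap_consensus, dpi_prune, mi_threshold,
                               mutual_information, node_degree)
from mirmaster.synthetic import CohortConfig, generate_cohort


def dpi_oracle(edge_weights, tolerance=0.0):
    """Brute force: enumerate node triples, mark min edges, remove at end."""
    w = {}
    for (u, v), mi in edge_weights.items():
        w[frozenset((u, v))] = mi
    nodes = sorted({n for e in w for n in e})
    doomed = set()
    for a, b, c in itertools.combinations(nodes, 3):
        tri = [frozenset(p) for p in ((a, b), (a, c), (b, c))]
        if not all(e in w for e in tri):
            continue
        vals = sorted(tri, key=lambda e: w[e])
        lo, mid, hi = vals
        if w[lo] < (1 - tolerance) * w[mid] and w[lo] < (1 - tolerance) * w[hi]:
            doomed.add(lo)
    return {tuple(sorted(e)) for e in set(w) - doomed}


class TestMutualInformation:
    def test_symmetry_exact(self, rng):
        x, y = rng.random(200), rng.random(200)
        assert mutual_information(x, y) == mutual_information(y, x)

    def test_constant_vector_is_zero(self, rng):
        assert mutual_information(np.ones(50), rng.random(50)) == 0.0

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            mutual_information(rng.random(10), rng.random(11))

    def test_too_short(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2, 3], [3, 2, 1])

    def test_monotone_transform_invariance(self, rng):
        x, y = rng.random(300), rng.random(300)
        base = mutual_information(x, y)
        assert mutual_information(np.exp(x), y) == base
        assert mutual_information(x, y**3) == base
        assert mutual_information(5 * x + 2, -np.exp(-y)) == base

    def test_gaussian_closed_form(self):
        rho = 0.8
        expected = -0.5 * np.log(1 - rho**2)
        r = np.random.default_rng(42)
        z = r.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=2000)
        assert mutual_information(z[:, 0], z[:, 1]) == pytest.approx(expected, abs=0.08)

    def test_independent_shuffle_below_threshold(self):
        thr = mi_threshold(1000, p_value=0.01, n_null=500, seed=0)
        below = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            x = r.random(1000)
            y = r.permutation(x)
            below += mutual_information(x, y) < thr
        assert below >= 38  # >= 95% of seeds


class TestMiThreshold:
    def test_deterministic(self):
        assert mi_threshold(100, 0.05, 200, seed=3) == mi_threshold(100, 0.05, 200, seed=3)

    def test_decreases_with_n(self):
        assert mi_threshold(500, 0.05, 300, seed=1) < mi_threshold(50, 0.05, 300, seed=1)

    def test_matches_direct_permutation_null(self):
        # independent oracle: quantile of MI between explicitly permuted
        # copies of a fixed vector
        n, p = 200, 0.05
        thr = mi_threshold(n, p, 1000, seed=0)
        r = np.random.default_rng(123)
        x = r.random(n)
        null = np.array(
            [mutual_information(r.permutation(x), r.permutation(x)) for _ in range(1000)]
        )
        oracle = np.quantile(null, 1 - p)
        assert thr == pytest.approx(oracle, abs=0.01)

    def test_bad_p_value(self):
        with pytest.raises(ValueError):
            mi_threshold(100, 0.0, 200, seed=0)

    def test_small_n_null(self):
        with pytest.raises(ValueError):
            mi_threshold(100, 0.05, 50, seed=0)


class TestDpiPrune:
    def test_triangle_removes_weakest(self):
        kept = dpi_prune({("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.1})
        assert kept == {("a", "b"), ("b", "c")}

    def test_tolerance_one_removes_nothing(self):
        edges = {("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.1}
        assert dpi_prune(edges, tolerance=1.0) == {("a", "b"), ("b", "c"), ("a", "c")}

    def test_negative_tolerance(self):
        with pytest.raises(ValueError):
            dpi_prune({("a", "b"): 0.5}, tolerance=-0.1)

    def test_matches_oracle_on_small_graphs(self):
        r = np.random.default_rng(7)
        for _ in range(200):
            n = int(r.integers(3, 7))
            tol = float(r.choice([0.0, 0.1, 0.3]))
            edges = {}
            for a, b in itertools.combinations(range(n), 2):
                if r.random() < 0.7:
                    edges[(a, b)] = float(r.random())
            assert dpi_prune(edges, tol) == dpi_oracle(edges, tol)

    def test_raising_tolerance_never_removes_edges(self):
        r = np.random.default_rng(9)
        edges = {
            (a, b): float(r.random())
            for a, b in itertools.combinations(range(6), 2)
            if r.random() < 0.8
        }
        assert dpi_prune(edges, 0.0) <= dpi_prune(edges, 0.2) <= dpi_prune(edges, 0.5)


def _mini_cohort(seed):
    """3 miRNAs, one planted with 5 edges; 25 genes (20 decoys)."""
    edges = tuple(("mir-001", f"gene-{j:04d}", -1, 1.5) for j in range(1, 6))
    cfg = CohortConfig(n_tumor=300, n_normal=50, n_mirna=3, n_mrna=25,
                       planted_mmr_ids=("mir-001",), planted_edges=edges,
                       stage_trend=0.25, tumor_lfc=2.0, seed=seed)
    mirna, mrna, meta, truth = generate_cohort(cfg)
    is_tumor = (meta.set_index("sample_id").loc[mirna.columns, "condition"]
                == "tumor").to_numpy()
    tum = mirna.columns[is_tumor]
    mv = vst_like_transform(mirna, size_factors(mirna))[tum]
    gv = vst_like_transform(mrna, size_factors(mrna))[tum]
    return mv, gv, truth


class TestBootstrapConsensus:
    def test_single_bootstrap_identity(self):
        mv, gv, _ = _mini_cohort(seed=3)
        net = bootstrap_consensus(mv, gv, n_boot=1, seed=5)
        assert (net["support"] == 1).all()

    def test_support_bounded_by_bootstraps(self):
        mv, gv, _ = _mini_cohort(seed=4)
        net = bootstrap_consensus(mv, gv, n_boot=5, seed=9)
        assert len(net) > 0
        assert (net["support"] <= 5).all()
        assert (net["mi"] >= 0).all()
        assert not net.duplicated(subset=["mirna", "gene"]).any()

    def test_planted_edge_recovery(self):
        # 5 planted edges, 20 decoy genes, n=300, 20 bootstraps, 3 seeds:
        # all 5 recovered, at most 2 false edges
        for seed in (1, 2, 3):
            mv, gv, truth = _mini_cohort(seed)
            net = bootstrap_consensus(mv, gv, n_boot=20, seed=100 + seed)
            got = set(zip(net["mirna"], net["gene"]))
            true = {(m, g) for m, g, _, _ in truth.planted_edges}
            assert true <= got
            assert len(got - true) <= 2

    def test_determinism(self):
        mv, gv, _ = _mini_cohort(seed=6)
        a = bootstrap_consensus(mv, gv, n_boot=3, seed=1)
        b = bootstrap_consensus(mv, gv, n_boot=3, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_columns(self):
        mv, gv, _ = _mini_cohort(seed=6)
        with pytest.raises(ValueError, match="share sample columns"):
            bootstrap_consensus(mv, gv.iloc[:, ::-1], n_boot=2)

    def test_repressive_direction_signs(self):
        mv, gv, truth = _mini_cohort(seed=2)
        net = bootstrap_consensus(mv, gv, n_boot=10, seed=0)
        true = {(m, g) for m, g, _, _ in truth.planted_edges}
        planted_rows = net[[(m, g) in true for m, g in zip(net.mirna, net.gene)]]
        assert (planted_rows["direction_sign"] == -1).all()


class TestNodeDegree:
    def test_star(self):
        net = pd.DataFrame(
            {"mirna": ["m1"] * 3, "gene": ["g1", "g2", "g3"],
             "mi": [0.1] * 3, "support": [1] * 3, "direction_sign": [1] * 3}
        )
        mir, gene = node_degree(net)
        assert mir["m1"] == 3
        assert (gene == 1).all()

    def test_empty(self):
        mir, gene = node_degree(pd.DataFrame(columns=["mirna", "gene"]))
        assert mir.empty and gene.empty

    def test_degree_sums_equal_edge_count(self, rng):
        rows = [
            (f"m{rng.integers(5)}", f"g{rng.integers(20)}")
            for _ in range(60)
        ]
        net = pd.DataFrame(sorted(set(rows)), columns=["mirna", "gene"])
        mir, gene = node_degree(net)
        assert mir.sum() == gene.sum() == len(net)
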