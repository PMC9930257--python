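import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regulonscape as rs
from regulonscape.csn import CellSpecificNetwork, ndm


def naive_csn(norm: pd.DataFrame, box_frac: float, alpha: float, tie_seed: int = 0):
    """Triple-loop reference: per gene pair, per cell, explicit boxes,
    counts, leave-one-out statistic, exact hypergeometric test."""
    genes = list(norm.columns)
    n = norm.shape[0]
    X = norm.to_numpy(dtype=float)
    rng = np.random.default_rng(tie_seed)
    boxes = {}
    for j, g in enumerate(genes):
        order = np.lexsort((rng.random(n), X[:, j]))
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        m = min(math.ceil(box_frac * n), n)
        per_cell = []
        for k in range(n):
            d = np.sort(np.abs(ranks - ranks[k]))
            h = d[m - 1]
            per_cell.append(set(np.flatnonzero(np.abs(ranks - ranks[k]) <= h)))
        boxes[g] = per_cell
    sig = {}
    rho = {}
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            for k in range(n):
                bx, by = boxes[a][k], boxes[b][k]
                nx, ny, nxy = len(bx), len(by), len(bx & by)
                assert k in bx and k in by
                r = rs.csn_statistic(n - 1, nx - 1, ny - 1, nxy - 1)
                rho[(a, b, k)] = r
                if nx <= 1 or nx >= n or ny <= 1 or ny >= n:
                    sig[(a, b, k)] = False
                else:
                    p = stats.hypergeom.sf(nxy - 2, n - 1, nx - 1, ny - 1)
                    sig[(a, b, k)] = p <= alpha
    return boxes, rho, sig


class TestCsnStatistic:
    def test_exact_independence_is_zero(self):
        assert rs.csn_statistic(100, 10, 10, 1) == 0.0

    def test_full_overlap(self):
        assert rs.csn_statistic(100, 10, 10, 10) == pytest.approx(math.sqrt(99))

    def test_empty_overlap(self):
        assert rs.csn_statistic(100, 10, 10, 0) == pytest.approx(
            math.sqrt(99) * (-100) / 900
        )

    def test_degenerate_boxes_nan(self):
        assert np.isnan(rs.csn_statistic(100, 0, 10, 0))
        assert np.isnan(rs.csn_statistic(100, 100, 10, 10))

    def test_symmetry_in_gene_order(self, rng):
        for _ in range(20):
            n = 50
            nx, ny = rng.integers(1, n), rng.integers(1, n)
            nxy = rng.integers(0, min(nx, ny) + 1)
            assert rs.csn_statistic(n, nx, ny, nxy) == rs.csn_statistic(n, ny, nx, nxy)


class TestBoxMembership:
    def test_distinct_values_rank_window(self):
        vals = np.arange(1, 11)
        got = rs.box_membership(vals, k=4, box_frac=0.3)
        assert set(got) == {3, 4, 5}  # values 4, 5, 6

    def test_full_window(self):
        vals = np.arange(12.0)
        assert len(rs.box_membership(vals, 0, box_frac=1.0)) == 12

    def test_box_has_nominal_size_and_contains_k(self, rng):
        vals = rng.uniform(size=40)
        for k in (0, 7, 39):
            box = rs.box_membership(vals, k, box_frac=0.2)
            assert k in box
            assert 8 <= len(box) <= 9  # ceil(0.2*40)=8, parity may add one

    def test_tie_block_subsampled_to_nominal_size(self):
        vals = np.zeros(30)
        box = rs.box_membership(vals, 3, box_frac=0.1)
        assert 3 in box and len(box) <= 5


class TestBuildCsn:
    def test_matches_naive_reference(self, rng):
        """Vectorized construction equals the triple-loop reference on a
        30-cell x 6-gene instance (boxes, statistics, calls)."""
        norm = pd.DataFrame(
            rng.uniform(size=(30, 6)), columns=[f"g{i}" for i in range(6)]
        )
        params = rs.CsnParams(box_frac=0.2, alpha=0.05, tie_seed=9)
        res = rs.build_csn(norm, params)
        _, rho_ref, sig_ref = naive_csn(norm, 0.2, 0.05, tie_seed=9)
        called = set(zip(res.edges["gene_a"], res.edges["gene_b"],
                         [int(c) for c in res.edges["cell_id"]]))
        expected = {key for key, s in sig_ref.items() if s}
        assert called == expected
        for _, row in res.edges.iterrows():
            k = int(row["cell_id"])
            assert row["rho"] == pytest.approx(
                rho_ref[(row["gene_a"], row["gene_b"], k)], abs=1e-12
            )

    def test_integer_count_matrix_with_ties_matches_naive(self, rng):
        """Reference equivalence holds with heavy ties (sparse counts)."""
        norm = pd.DataFrame(
            rng.poisson(0.8, size=(25, 5)).astype(float),
            columns=[f"g{i}" for i in range(5)],
        )
        res = rs.build_csn(norm, rs.CsnParams(box_frac=0.2, alpha=0.05, tie_seed=4))
        _, _, sig_ref = naive_csn(norm, 0.2, 0.05, tie_seed=4)
        called = set(zip(res.edges["gene_a"], res.edges["gene_b"],
                         [int(c) for c in res.edges["cell_id"]]))
        assert called == {key for key, s in sig_ref.items() if s}

    def test_null_calibration(self):
        """Edge-call rate on independent uniform data stays within half a
        percentage point of the nominal level (alpha = 0.01, n = 500)."""
        rates = []
        for seed in range(10):
            gen = np.random.default_rng(seed)
            X = pd.DataFrame(gen.uniform(size=(500, 10)),
                             columns=[f"g{i}" for i in range(10)])
            res = rs.build_csn(X, rs.CsnParams(box_frac=0.1, alpha=0.01))
            rates.append(len(res.edges) / (45 * 500))
        assert abs(np.mean(rates) - 0.01) <= 0.005

    def test_coexpressed_pair_nearly_always_called(self):
        gen = np.random.default_rng(1)
        x = gen.normal(size=300)
        norm = pd.DataFrame({"a": x, "b": x})
        res = rs.build_csn(norm, rs.CsnParams(box_frac=0.1, alpha=0.01))
        order = np.argsort(np.argsort(x))
        interior = set(np.flatnonzero((order >= 30) & (order < 270)))
        called = {int(c) for c in res.edges["cell_id"]}
        assert len(interior & called) / len(interior) >= 0.95

    def test_default_box_frac(self):
        assert rs.CsnParams().box_frac == 0.1

    def test_subset_missing_gene_raises(self, uniform_matrix):
        with pytest.raises(ValueError, match="missing"):
            rs.build_csn(uniform_matrix, rs.CsnParams(gene_subset=["g0", "zz"]))

    def test_transformer_returns_cells_by_genes(self, uniform_matrix):
        est = CellSpecificNetwork(box_frac=0.2, alpha=0.05)
        out = est.fit_transform(uniform_matrix)
        assert out.shape == uniform_matrix.shape
        assert list(out.index) == list(uniform_matrix.index)


class TestNdm:
    def test_degree_counting(self):
        edges = pd.DataFrame(
            {"cell_id": ["c0", "c0"], "gene_a": ["a", "a"], "gene_b": ["b", "c"],
             "rho": [3.0, 3.0]}
        )
        res = rs.CsnResult(edges=edges, ndm=None, params=rs.CsnParams(),
                           gene_ids=["a", "b", "c"], cell_ids=["c0", "c1"])
        out = ndm(res)
        assert out.loc["a", "c0"] == 2
        assert out.loc["b", "c0"] == 1 and out.loc["c", "c0"] == 1
        assert (out["c1"] == 0).all()

    def test_handshake_identity(self, uniform_matrix):
        res = rs.build_csn(uniform_matrix, rs.CsnParams(box_frac=0.2, alpha=0.1))
        recomputed = ndm(res)
        pd.testing.assert_frame_equal(recomputed, res.ndm, check_dtype=False)
        per_cell_edges = res.edges.groupby("cell_id").size()
        for cell, n_edges in per_cell_edges.items():
            assert res.ndm[cell].sum() == 2 * n_edges


class TestDifferentialNdm:
    def test_exact_small_sample_p(self):
        """[1,2,3] vs [4,5,6]: two-sided exact rank-sum p = 2/20 = 0.1."""
        mat = pd.DataFrame([[1, 2, 3, 4, 5, 6]], index=["g"],
                           columns=[f"c{i}" for i in range(6)])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        res = rs.differential_ndm(mat, labels, "A")
        assert res.loc["g", "pvalue"] == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        mat = pd.DataFrame([[2, 2, 2, 2, 2, 2]], index=["g"],
                           columns=[f"c{i}" for i in range(6)])
        res = rs.differential_ndm(mat, np.repeat(["A", "B"], 3), "A")
        assert res.loc["g", "pvalue"] == 1.0

    def test_single_cluster_raises(self):
        mat = pd.DataFrame([[1, 2, 3]], index=["g"], columns=["c0", "c1", "c2"])
        with pytest.raises(ValueError, match=">= 2"):
            rs.differential_ndm(mat, np.array(["A", "A", "A"]), "A")

    def test_planted_tf_connectivity_recovered(self, default_dataset, default_norm, default_labels):
        """The planted TF's mean NDM peaks in its active cluster and the
        rank-sum test flags it (BH-adjusted p < 0.05)."""
        truth = default_dataset.regulon_truth
        reg_genes = sorted({g for n, l in truth.items() for g in [n] + l})
        background = [g for g in default_norm.columns if g not in set(reg_genes)][:20]
        res = rs.build_csn(default_norm, rs.CsnParams(0.1, 0.01, gene_subset=reg_genes + background))
        for tf in truth:
            active = int(default_dataset.activity_design.loc[tf].idxmax())
            by_cluster = res.ndm.loc[tf].groupby(default_labels).mean()
            assert by_cluster.idxmax() == active
            dn = rs.differential_ndm(res.ndm, default_labels, active)
            assert dn.loc[tf, "padj"] < 0.05


class TestConnectivityByCluster:
    def test_extremes_and_bounds(self):
        edges = pd.DataFrame(
            {"cell_id": ["c0", "c1"], "gene_a": ["a", "a"], "gene_b": ["b", "b"],
             "rho": [3.0, 3.0]}
        )
        res = rs.CsnResult(edges=edges, ndm=None, params=rs.CsnParams(),
                           gene_ids=["a", "b"], cell_ids=["c0", "c1", "c2", "c3"])
        labels = np.array(["A", "A", "B", "B"])
        conn = rs.connectivity_by_cluster(res, labels)
        assert conn["A"][("a", "b")] == 1.0
        assert conn["B"][("a", "b")] == 0.0

    def test_planted_pair_frequency_maximal_in_active_cluster(
        self, default_dataset, default_norm, default_labels
    ):
        import itertools as it

        truth = default_dataset.regulon_truth
        reg_genes = sorted({g for n, l in truth.items() for g in [n] + l})
        res = rs.build_csn(default_norm, rs.CsnParams(0.1, 0.01, gene_subset=reg_genes))
        conn = rs.connectivity_by_cluster(res, default_labels)
        for tf, targets in truth.items():
            active = int(default_dataset.activity_design.loc[tf].idxmax())
            pairs = [tuple(sorted(p)) for p in it.combinations(targets, 2)]
            means = {c: np.mean([conn[c].get(p, 0.0) for p in pairs]) for c in conn}
            assert max(means, key=means.get) == active
        for c in conn:
            assert all(0.0 <= v <= 1.0 for v in conn[c].values())
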