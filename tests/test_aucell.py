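import itertools
import math

import numpy as np
import pandas as pd
import pytest

import regulonscape as rs
from regulonscape.aucell import AUCellScorer


def _rank_frame(ranks_row):
    cols = [f"g{i}" for i in range(len(ranks_row))]
    return pd.DataFrame([ranks_row], index=["c0"], columns=cols)


def _set_at_ranks(ranks_row, wanted):
    return [f"g{i}" for i, r in enumerate(ranks_row) if r in wanted]


class TestRankGenes:
    def test_strictly_decreasing_no_ties(self):
        norm = pd.DataFrame([[5.0, 4.0, 3.0, 2.0, 1.0]], columns=list("abcde"))
        ranks = rs.rank_genes_per_cell(norm, tie_seed=0)
        assert ranks.iloc[0].tolist() == [1, 2, 3, 4, 5]

    def test_all_zero_cell_deterministic_permutation(self):
        norm = pd.DataFrame(np.zeros((1, 8)), columns=[f"g{i}" for i in range(8)])
        a = rs.rank_genes_per_cell(norm, tie_seed=3)
        b = rs.rank_genes_per_cell(norm, tie_seed=3)
        assert sorted(a.iloc[0]) == list(range(1, 9))
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_transform_invariance(self, uniform_matrix):
        ranks = rs.rank_genes_per_cell(uniform_matrix, tie_seed=1)
        squared = rs.rank_genes_per_cell(uniform_matrix**2, tie_seed=1)
        pd.testing.assert_frame_equal(ranks, squared)


class TestAucellScore:
    def test_maximal_packing(self):
        ranks = _rank_frame([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        auc = rs.aucell_score(ranks, ["g0", "g1"], top_frac=0.5)
        assert auc[0] == pytest.approx(1.0)

    def test_set_outside_top_block(self):
        ranks = _rank_frame([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        auc = rs.aucell_score(ranks, ["g8", "g9"], top_frac=0.5)
        assert auc[0] == 0.0

    def test_step_curve_enumeration(self):
        """Set at ranks {1, 3} of 10 with T=5: raw 1+1+2+2=6, max 7."""
        ranks = _rank_frame([1, 2, 3, 4, 5, 6, 7, 8, 9, 10])
        auc = rs.aucell_score(ranks, ["g0", "g2"], top_frac=0.5)
        assert auc[0] == pytest.approx(6 / 7)

    def test_bounds_and_missing_genes(self, uniform_matrix):
        ranks = rs.rank_genes_per_cell(uniform_matrix, tie_seed=0)
        with pytest.warns(UserWarning, match="absent"):
            auc = rs.aucell_score(ranks, ["g0", "g1", "NOT_A_GENE"], top_frac=0.5)
        assert np.all((auc >= 0) & (auc <= 1))
        with pytest.raises(ValueError, match="no overlap"):
            rs.aucell_score(ranks, ["NOPE"], top_frac=0.5)

    def test_null_mean_matches_enumeration_oracle(self, rng):
        """Mean AUC of random gene sets on uniform ranks matches the exact
        expectation enumerated over all rank placements (G=10, m=3)."""
        G, m, top = 10, 3, 0.5
        T = math.ceil(top * G)
        max_raw = sum(min(t, m) for t in range(1, T))
        placements = [
            sum(T - r for r in combo if r <= T - 1) / max_raw
            for combo in itertools.combinations(range(1, G + 1), m)
        ]
        exact = float(np.mean(placements))
        norm = pd.DataFrame(rng.uniform(size=(3000, G)), columns=[f"g{i}" for i in range(G)])
        ranks = rs.rank_genes_per_cell(norm, tie_seed=0)
        sim = rs.aucell_score(ranks, ["g0", "g1", "g2"], top_frac=top)
        assert abs(sim.mean() - exact) < 0.01


class TestScoreAll:
    def test_matches_single_scores_and_duplicates(self, uniform_matrix):
        ranks = rs.rank_genes_per_cell(uniform_matrix, tie_seed=0)
        regs = {"r1": ["g0", "g1"], "r1_copy": ["g0", "g1"]}
        act = rs.score_all(ranks, regs, top_frac=0.5)
        np.testing.assert_array_equal(act["r1"], act["r1_copy"])
        np.testing.assert_array_equal(
            act["r1"], rs.aucell_score(ranks, ["g0", "g1"], top_frac=0.5)
        )

    def test_planted_regulon_highest_in_active_cluster(
        self, default_dataset, default_norm, default_labels
    ):
        ranks = rs.rank_genes_per_cell(default_norm, tie_seed=0)
        act = rs.score_all(ranks, default_dataset.regulon_truth, top_frac=0.2)
        for name in act.columns:
            med = act[name].groupby(default_labels).median()
            active = int(default_dataset.activity_design.loc[name].idxmax())
            assert med.idxmax() == active
            assert (med.drop(active) < med[active]).all()

    def test_transformer_api(self, uniform_matrix):
        scorer = AUCellScorer({"r": ["g0", "g1"]}, top_frac=0.5, tie_seed=2)
        act = scorer.fit_transform(uniform_matrix)
        assert act.shape == (len(uniform_matrix), 1)
        assert scorer.get_params()["top_frac"] == 0.5
        again = AUCellScorer(**scorer.get_params()).fit_transform(uniform_matrix)
        pd.testing.assert_frame_equal(act, again)


class TestDifferentialActivity:
    def test_kruskal_wallis_hand_value(self):
        """Three groups [1,2,3],[4,5,6],[7,8,9]: H = 7.2 by the rank-sum
        formula at N=9."""
        vals = pd.DataFrame({"f": [1, 2, 3, 4, 5, 6, 7, 8, 9]}, dtype=float)
        res = rs.differential_activity(vals, np.repeat([0, 1, 2], 3))
        assert res.loc["f", "statistic"] == pytest.approx(7.2)

    def test_null_not_significant(self, rng):
        base = rng.normal(size=60)
        vals = pd.DataFrame({"f": base, "g": base[::-1]})
        res = rs.differential_activity(vals, np.repeat([0, 1, 2], 20))
        assert (res["padj"] > 0.05).all()

    def test_constant_feature_untestable(self):
        vals = pd.DataFrame({"f": np.ones(8), "g": np.arange(8.0)})
        res = rs.differential_activity(vals, np.repeat([0, 1], 4))
        assert np.isnan(res.loc["f", "pvalue"])
        assert np.isfinite(res.loc["g", "pvalue"])

    def test_recovery_and_type_I_on_synthetic(
        self, default_dataset, default_norm, default_labels, rng
    ):
        """Planted regulons all flagged; decoy gene-set 'regulons' flagged in
        at most 5% of features."""
        ranks = rs.rank_genes_per_cell(default_norm, tie_seed=0)
        decoys = {}
        pool = [g for g in default_norm.columns if g.startswith("G00")]
        pool = [g for g in pool
                if g not in {x for n, l in default_dataset.regulon_truth.items() for x in [n] + l}]
        for j in range(40):
            decoys[f"decoy{j}"] = list(rng.choice(pool, size=10, replace=False))
        act = rs.score_all(ranks, {**default_dataset.regulon_truth, **decoys}, top_frac=0.2)
        shuffled = np.array(default_labels)
        rng.shuffle(shuffled)
        res_true = rs.differential_activity(act[list(default_dataset.regulon_truth)], default_labels)
        assert (res_true["padj"] < 0.05).all()
        res_decoy = rs.differential_activity(act[list(decoys)], shuffled)
        assert (res_decoy["padj"] < 0.05).mean() <= 0.05

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            rs.differential_activity(pd.DataFrame({"f": [1.0, 2.0]}), [0, 0])


class TestSummarizeByCluster:
    def test_constant_feature_zscales_to_zero(self):
        vals = pd.DataFrame({"f": [3.0, 3.0, 3.0, 3.0]})
        out = rs.summarize_by_cluster(vals, [0, 0, 1, 1], row_scale="z")
        assert (out["f"] == 0).all()

    def test_one_cell_per_cluster_is_identity(self):
        vals = pd.DataFrame({"f": [1.0, 5.0], "g": [2.0, 0.0]})
        out = rs.summarize_by_cluster(vals, [0, 1], row_scale=None)
        np.testing.assert_array_equal(out.to_numpy(), vals.to_numpy())

    def test_planted_regulon_argmax_is_active_cluster(
        self, default_dataset, default_norm, default_labels
    ):
        ranks = rs.rank_genes_per_cell(default_norm, tie_seed=0)
        act = rs.score_all(ranks, default_dataset.regulon_truth, top_frac=0.2)
        summ = rs.summarize_by_cluster(act, default_labels, row_scale=None)
        for name in act.columns:
            assert summ[name].idxmax() == int(default_dataset.activity_design.loc[name].idxmax())
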