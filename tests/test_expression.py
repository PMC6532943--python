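"""Expression- and growth-based scoring, correction, clustering, enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from epinet import expression as xp
from epinet.patterns import GIPattern


def make_profile(m, p=None, pair="x-y") -> xp.PairProfile:
    m = np.asarray(m, dtype=float)
    if p is None:
        p = np.where(np.abs(m) > 0.5, 1e-6, 1.0)
    genes = pd.Index([f"g{i}" for i in range(len(m))], name="gene")
    return xp.PairProfile(
        pair,
        pd.DataFrame(
            {
                "m_x": m[:, 0], "p_x": p[:, 0],
                "m_y": m[:, 1], "p_y": p[:, 1],
                "m_xy": m[:, 2], "p_xy": p[:, 2],
            },
            index=genes,
        ),
    )


class TestGrowthScores:
    @pytest.mark.parametrize(
        "wx, wy, wxy, expected",
        [(1, 1, 1, 0.0), (0.9, 0.8, 0.5, -0.22), (0.9, 0.8, 0.72, 0.0)],
    )
    def test_epsilon(self, wx, wy, wxy, expected):
        assert xp.growth_epsilon(wx, wy, wxy) == pytest.approx(expected)

    def test_non_positive_fitness_rejected(self):
        with pytest.raises(ValueError):
            xp.growth_epsilon(0.0, 0.8, 0.5)

    def test_z_scores_and_tail(self):
        out = xp.growth_significance([0.0, -0.3], null_mean=0.0, null_sd=0.1)
        assert out["z"].tolist() == pytest.approx([0.0, -3.0])
        assert out["p"].iloc[0] == pytest.approx(0.5)
        assert out["p"].iloc[1] == pytest.approx(0.00135, rel=0.01)

    def test_benjamini_hochberg_ladder(self):
        # hand-computed BH: p (0.01, 0.02, 0.9) -> (0.03, 0.03, 0.9)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.9], method="fdr_bh")[1]
        assert adj == pytest.approx([0.03, 0.03, 0.9])

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            xp.growth_significance([0.1], 0.0, 0.0)


class TestWtSimilarity:
    def test_threshold_boundary(self):
        m = np.r_[np.full(7, 2.0), np.zeros(10)]
        p = np.r_[np.full(7, 0.001), np.ones(10)]
        assert xp.wt_similarity(m, p)
        m8 = np.r_[np.full(8, 2.0), np.zeros(10)]
        p8 = np.r_[np.full(8, 0.001), np.ones(10)]
        assert not xp.wt_similarity(m8, p8)

    def test_empty_profile_is_wt_like(self):
        assert xp.wt_similarity(np.array([]), np.array([]))


class TestSlowGrowthCorrection:
    def test_pure_signature_removed(self):
        v = np.array([0.6, 0.8, 0.0])
        assert xp.slow_growth_correct(2 * v, v) == pytest.approx(np.zeros(3))

    def test_orthogonal_profile_unchanged(self):
        v = np.array([1.0, 0.0, 0.0])
        m = np.array([0.0, 2.0, -1.0])
        assert xp.slow_growth_correct(m, v) == pytest.approx(m)

    def test_idempotent_and_norm_non_increasing(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(50)
        m = rng.standard_normal(50)
        once = xp.slow_growth_correct(m, v)
        twice = xp.slow_growth_correct(once, v)
        assert once == pytest.approx(twice)
        assert np.linalg.norm(once) <= np.linalg.norm(m) + 1e-12
        assert abs(once @ (v / np.linalg.norm(v))) < 1e-10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            xp.slow_growth_correct(np.ones(3), np.ones(4))


class TestPairProfileScoring:
    def test_planted_buffering_recovered(self):
        rng = np.random.default_rng(1)
        m = np.zeros((200, 3))
        m[:40, 2] = 1.5  # buffering: singles silent, double up
        m += rng.normal(0, 0.1, size=m.shape)
        p = 2 * np.exp(-0.5 * (m / 0.1) ** 2)  # monotone proxy for significance
        result = xp.pair_gi_profile(make_profile(m, np.clip(p, 0, 1)))
        buffering = result.calls["pattern"][:40]
        assert (buffering == "buffering").sum() >= 38

    def test_planted_inversion_triple(self):
        m = np.array([[1.5, 0.0, -1.5]])
        result = xp.pair_gi_profile(make_profile(m))
        assert result.calls["pattern"].iloc[0] == "inversion"

    def test_silent_profile_is_excluded(self):
        m = np.zeros((50, 3))
        result = xp.pair_gi_profile(make_profile(m, np.ones((50, 3))))
        assert result.interaction_score == 0
        assert result.excluded

    def test_counts_invariant_to_gene_order(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1.2, size=(100, 3))
        prof = make_profile(m)
        shuffled = xp.PairProfile("x-y", prof.data.sample(frac=1, random_state=0))
        a = xp.pair_gi_profile(prof).pattern_counts
        b = xp.pair_gi_profile(shuffled).pattern_counts
        pd.testing.assert_series_equal(a, b)


class TestSelection:
    def test_selects_negative_significant_with_wt_like_single(self):
        growth = pd.DataFrame(
            {
                "epsilon": [-0.3, -0.3, 0.2, -0.3],
                "significant": [True, True, True, False],
            },
            index=["a", "b", "c", "d"],
        )
        wt = {"a": (True, False), "b": (False, False),
              "c": (True, True), "d": (True, True)}
        sel = xp.select_pairs(growth, wt)
        assert sel.tolist() == [True, False, False, False]


class TestClustering:
    def test_identical_vectors_merge_at_zero(self):
        counts = pd.DataFrame([[5, 1, 0], [5, 1, 0], [0, 0, 9]],
                              index=["a", "b", "c"])
        tree = xp.cluster_pairs(counts)
        assert tree["linkage"][0, 2] == pytest.approx(0.0)

    def test_orthogonal_vectors_at_distance_one(self):
        counts = pd.DataFrame([[5, 0], [0, 3]], index=["a", "b"])
        tree = xp.cluster_pairs(counts)
        assert tree["linkage"][0, 2] == pytest.approx(1.0)

    def test_all_zero_vector_rejected(self):
        counts = pd.DataFrame([[0, 0], [1, 2]], index=["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            xp.cluster_pairs(counts)

    def test_newick_contains_all_labels(self):
        counts = pd.DataFrame([[5, 1], [4, 2], [0, 9]], index=["a", "b", "c"])
        tree = xp.cluster_pairs(counts)
        for label in "abc":
            assert label in tree["newick"]
        assert tree["newick"].endswith(";")


class TestGroupComparison:
    def test_separated_groups_exact_p(self):
        # n = m = 3, complete separation: U = 0, two-sided exact p = 0.1
        out = xp.compare_inversion_fraction(
            {"lo": [1, 2, 3], "hi": [10, 11, 12]}
        )
        assert out["u"].iloc[0] in (0.0, 9.0)
        assert out["p"].iloc[0] == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        out = xp.compare_inversion_fraction({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert out["p"].iloc[0] > 0.9

    def test_label_permutation_symmetric(self):
        p1 = xp.compare_inversion_fraction({"a": [1, 5, 3], "b": [2, 8, 9]})
        p2 = xp.compare_inversion_fraction({"b": [2, 8, 9], "a": [1, 5, 3]})
        assert p1["p"].iloc[0] == pytest.approx(p2["p"].iloc[0])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            xp.compare_inversion_fraction({"a": [1.0], "b": [1, 2]})


class TestEnrichment:
    def test_exact_urn_probability(self):
        # drawing all 5 annotated genes in 5 draws from 10: 1 / C(10,5)
        out = xp.hypergeom_enrich({"g1", "g2", "g3", "g4", "g5"},
                                  {"A": {"g1", "g2", "g3", "g4", "g5"}},
                                  background=10)
        assert out["p"].iloc[0] == pytest.approx(1 / 252)

    def test_empty_hit_set_gives_p_one(self):
        out = xp.hypergeom_enrich(set(), {"A": {"g1"}}, background=100)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_bonferroni_scales_with_annotations(self):
        hits = {f"g{i}" for i in range(5)}
        anns = {f"A{k}": {f"g{i}" for i in range(5)} for k in range(4)}
        out = xp.hypergeom_enrich(hits, anns, background=50)
        assert out["p_bonferroni"].iloc[0] == pytest.approx(
            min(1.0, out["p"].iloc[0] * 4)
        )

    def test_oversized_hit_set_rejected(self):
        with pytest.raises(ValueError):
            xp.hypergeom_enrich({"a", "b"}, {"A": {"a"}}, background=1)
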