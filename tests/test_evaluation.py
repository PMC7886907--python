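"""Ranking metrics, matched sampling, E-P constraints and cell-type overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopcomp.evaluation import (
    auprc,
    auroc,
    celltype_compare,
    ep_constraint,
    evaluate_pairs,
    matched_negatives,
    subsample_ci,
)
from loopcomp.model import score_pairs


class TestMetrics:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert auprc(scores, labels) == 1.0
        assert auroc(scores, labels) == 1.0

    def test_single_positive_at_rank_two(self):
        # positive retrieved second: AP = 1/2
        assert auprc([0.8, 0.9, 0.1, 0.05], [1, 0, 0, 0]) == pytest.approx(0.5)

    def test_random_scores_approach_class_fraction(self):
        rng = np.random.default_rng(0)
        n = 40_000
        labels = (rng.random(n) < 0.1).astype(int)
        scores = rng.random(n)
        assert auprc(scores, labels) == pytest.approx(0.1, abs=0.015)
        assert auroc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auprc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [0, 0])

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_auroc_equals_mann_whitney(self, seed):
        # brute-force pairwise-comparison oracle on small instances
        rng = np.random.default_rng(seed)
        n = 30
        labels = np.zeros(n, int)
        labels[: rng.integers(1, n - 1)] = 1
        rng.shuffle(labels)
        scores = rng.integers(0, 10, n).astype(float)  # ties on purpose
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n_).sum() + 0.5 * (p == n_).sum() for p, n_ in [(pos[:, None], neg[None, :])])
        oracle = float(wins) / (len(pos) * len(neg))
        assert auroc(scores, labels) == pytest.approx(oracle)

    def test_evaluate_pairs_curves_and_correlation(self, default_landscape):
        cfg, sites, pairs = default_landscape
        scored = score_pairs(sites, pairs, cfg.params)
        res = evaluate_pairs(scored)
        assert 0 < res.auprc <= 1 and 0.5 < res.auroc <= 1
        assert res.pr_curve["recall"].min() == 0.0 and res.pr_curve["recall"].max() == 1.0
        assert res.pet_correlation > 0.3  # probabilities track PET counts

    def test_subsample_ci_brackets_point_estimate(self, default_landscape):
        cfg, sites, pairs = default_landscape
        scored = score_pairs(sites, pairs, cfg.params)
        point = auprc(scored["p_ij"], scored["label"])
        mean, lo, hi = subsample_ci(scored["p_ij"], scored["label"], seed=1)
        assert lo <= mean <= hi
        assert abs(mean - point) < 0.15


@pytest.fixture(scope="module")
def scored_landscape(default_landscape):
    cfg, sites, pairs = default_landscape
    scoring = cfg.params.replace(lam=300_000.0, decay_kind="exponential")
    return score_pairs(sites, pairs, scoring)


class TestMatchedNegatives:
    def test_exact_twin_selected(self):
        df = pd.DataFrame(
            {
                "label": [1, 0, 0],
                "ori_class": ["convergent"] * 3,
                "p_i": [0.5, 0.5, 0.01],
                "p_j": [0.5, 0.5, 0.9],
                "D_ij": [0.8, 0.8, 0.1],
                "LC_ij": [0.9, 0.2, 0.9],
            }
        )
        matched, dropped = matched_negatives(df, "distance", seed=0)
        assert dropped == 0
        neg = matched[matched["label"] == 0]
        assert len(neg) == 1 and neg["LC_ij"].iloc[0] == 0.2

    def test_unmatchable_positive_dropped_and_counted(self):
        df = pd.DataFrame(
            {
                "label": [1, 0],
                "ori_class": ["convergent", "divergent"],
                "p_i": [0.5, 0.5],
                "p_j": [0.5, 0.5],
                "D_ij": [0.8, 0.8],
                "LC_ij": [0.9, 0.9],
            }
        )
        matched, dropped = matched_negatives(df, "distance", seed=0)
        assert dropped == 1 and len(matched) == 0

    def test_invalid_factor_rejected(self, scored_landscape):
        with pytest.raises(ValueError):
            matched_negatives(scored_landscape, "distance", factor=1.0)

    def test_constraints_hold_on_landscape(self, scored_landscape):
        for mode, free in [("distance", "LC_ij"), ("loop_competition", "D_ij")]:
            matched, dropped = matched_negatives(scored_landscape, mode, seed=3)
            assert len(matched) > 100
            pos = matched[matched["label"] == 1].set_index("match_group")
            neg = matched[matched["label"] == 0].set_index("match_group")
            bi_ratio = (pos["p_i"] * pos["p_j"]) / (neg["p_i"] * neg["p_j"]).to_numpy()
            assert (np.maximum(bi_ratio, 1 / bi_ratio) <= 2.0 + 1e-9).all()

    def test_competition_informative_when_distance_matched(self, scored_landscape):
        # labels were drawn with LC in the generator: after matching away
        # intensity and distance, the full model still separates classes...
        dm, _ = matched_negatives(scored_landscape, "distance", seed=1)
        assert auroc(dm["p_ij"], dm["label"]) > 0.6
        # ...while distance alone is uninformative once LC is matched
        lm, _ = matched_negatives(scored_landscape, "loop_competition", seed=1)
        assert abs(auroc(lm["D_ij"], lm["label"]) - 0.5) < 0.1


def _loops(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "anchor1_start", "anchor1_end", "anchor2_start", "anchor2_end", "pet_count"]
    )


def _links(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "enh_start", "enh_end", "prom_start", "prom_end", "label"]
    )


class TestEPConstraint:
    def test_nested_link_contained_not_crossing(self):
        loops = _loops([("chr1", 1_000, 1_200, 9_000, 9_200, 5)])
        links = _links([("chr1", 3_000, 3_100, 6_000, 6_100, 1)])
        res = ep_constraint(links, loops)
        assert res.links["cross_n"].iloc[0] == 0
        assert res.links["contain_n"].iloc[0] == 1

    def test_straddling_link_crosses(self):
        loops = _loops([("chr1", 1_000, 1_200, 9_000, 9_200, 5)])
        links = _links([("chr1", 5_000, 5_100, 12_000, 12_100, 1)])
        res = ep_constraint(links, loops)
        assert res.links["cross_n"].iloc[0] == 1
        assert res.links["contain_n"].iloc[0] == 0

    def test_toy_enrichment_with_pseudocount(self):
        loops = _loops([("chr1", 1_000, 1_200, 9_000, 9_200, 5)])
        links = _links(
            [
                ("chr1", 3_000, 3_100, 6_000, 6_100, 1),  # true, inside
                ("chr1", 2_000, 2_100, 7_000, 7_100, 1),  # true, inside
                ("chr1", 5_000, 5_100, 12_000, 12_100, 0),  # false, crossing
                ("chr1", 500, 600, 4_000, 4_100, 0),  # false, crossing
            ]
        )
        res = ep_constraint(links, loops)
        # no-cross group: 2 true / 0 false -> pseudo-counted ratio (2.5 / 0.5)
        assert res.pseudocount_used
        assert res.ratio_no_cross == pytest.approx(5.0)
        assert res.enrichment_no_cross > 1
        assert res.enrichment_contain > 1

    def test_translation_invariance(self):
        loops = _loops([("chr1", 1_000, 1_200, 9_000, 9_200, 5)])
        links = _links(
            [("chr1", 3_000, 3_100, 6_000, 6_100, 1), ("chr1", 5_000, 5_100, 12_000, 12_100, 0)]
        )
        res1 = ep_constraint(links, loops)
        shift = 1_000_000
        loops2 = loops.copy()
        for c in loops2.columns[1:5]:
            loops2[c] += shift
        links2 = links.copy()
        for c in ["enh_start", "enh_end", "prom_start", "prom_end"]:
            links2[c] += shift
        res2 = ep_constraint(links2, loops2)
        assert res1.links["cross_n"].tolist() == res2.links["cross_n"].tolist()
        assert res1.links["contain_n"].tolist() == res2.links["contain_n"].tolist()

    def test_empty_loop_set_flagged(self):
        links = _links([("chr1", 3_000, 3_100, 6_000, 6_100, 1), ("chr1", 1, 2, 10, 20, 0)])
        res = ep_constraint(links, _loops([]))
        assert (res.links["cross_n"] == 0).all()
        assert res.pseudocount_used


class TestCelltypeCompare:
    def test_identical_sets_fully_shared(self):
        loops = _loops(
            [("chr1", 100, 200, 900, 1_000, 9), ("chr2", 100, 200, 900, 1_000, 4)]
        )
        with pytest.warns(UserWarning):
            res = celltype_compare(loops, loops.copy(), top_n=10)
        assert res.frac_shared_a == 1.0 and res.frac_shared_b == 1.0

    def test_disjoint_chromosomes_nothing_shared(self):
        a = _loops([("chr1", 100, 200, 900, 1_000, 9)])
        b = _loops([("chr2", 100, 200, 900, 1_000, 9)])
        with pytest.warns(UserWarning):
            res = celltype_compare(a, b, top_n=10)
        assert res.frac_shared_a == 0.0 and res.frac_shared_b == 0.0

    def test_partial_overlap_partition(self):
        a = _loops(
            [
                ("chr1", 100, 200, 900, 1_000, 9),
                ("chr1", 5_000, 5_200, 9_000, 9_200, 8),
                ("chr1", 20_000, 20_200, 29_000, 29_200, 7),
            ]
        )
        b = _loops(
            [
                ("chr1", 150, 250, 950, 1_050, 9),  # anchors overlap a[0]
                ("chr1", 5_100, 5_300, 9_100, 9_300, 2),  # overlaps a[1]
                ("chr1", 40_000, 40_200, 49_000, 49_200, 7),
            ]
        )
        with pytest.warns(UserWarning):
            res = celltype_compare(a, b, top_n=10)
        assert len(res.shared_a) == 2 and len(res.specific_a) == 1
        assert len(res.shared_b) == 2 and len(res.specific_b) == 1

    def test_top_n_selection_by_pet(self):
        a = _loops(
            [("chr1", 100, 200, 900, 1_000, 100), ("chr1", 5_000, 5_200, 9_000, 9_200, 1)]
        )
        b = _loops([("chr1", 100, 200, 900, 1_000, 50)])
        res = celltype_compare(a, b, top_n=1)
        # only the strongest loop of A is considered and it is shared
        assert res.frac_shared_a == 1.0
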