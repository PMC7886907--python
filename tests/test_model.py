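"""Closed-form model terms: occupancy, orientation, decay, competition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopcomp.model import (
    CONVERGENT,
    DIVERGENT,
    TANDEM,
    ModelParams,
    binding_probability,
    distance_decay,
    lc_approx,
    loop_probability,
    occupancy_scale_from_affinity,
    orientation_class,
    orientation_weight,
    score_pairs,
)
from .conftest import make_sites


class TestBindingProbability:
    @pytest.mark.parametrize(
        "x,a,expected",
        [(0.0, 8.5, 0.0), (8.5, 8.5, 0.5), (25.5, 8.5, 0.75), (1.0, 1.0, 0.5)],
    )
    def test_hill_closed_form(self, x, a, expected):
        assert binding_probability(x, ModelParams(a=a)) == pytest.approx(expected)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            binding_probability(-0.1, ModelParams())

    @given(st.floats(0, 1e6), st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_hill_in_unit_interval(self, x, a):
        p = binding_probability(x, ModelParams(a=a))
        assert 0.0 <= p < 1.0

    @pytest.mark.parametrize("kind", ["hill", "tanh"])
    def test_strictly_increasing(self, kind):
        params = ModelParams(binding_kind=kind)
        xs = np.linspace(0, 50, 200)
        p = binding_probability(xs, params)
        assert np.all(np.diff(p) > 0)
        assert p[0] == 0.0

    def test_tanh_variant_saturates(self):
        params = ModelParams(binding_kind="tanh", a_tanh=0.5)
        assert binding_probability(1.0, params) == pytest.approx(np.tanh(0.5))
        assert binding_probability(1e6, params) < 1.0

    def test_affinity_ratio_magnitude(self):
        # in-vitro Kd 370 nM over nuclear [CTCF] 144 nM: same order as fitted a
        assert occupancy_scale_from_affinity(370, 144) == pytest.approx(2.6, abs=0.05)


class TestOrientation:
    @pytest.mark.parametrize(
        "oi,oj,cls,weight",
        [
            ("forward", "reverse", CONVERGENT, 1.0),
            ("forward", "forward", TANDEM, 1 / 3),
            ("reverse", "reverse", TANDEM, 1 / 3),
            ("reverse", "forward", DIVERGENT, 1 / 9),
        ],
    )
    def test_classes_and_weights(self, oi, oj, cls, weight):
        params = ModelParams(w=3.0)
        assert orientation_class(oi, oj) == cls
        assert orientation_weight(oi, oj, params) == pytest.approx(weight)

    def test_general_two_parameter_weights(self):
        params = ModelParams(w=3.0, w1=2.0, w2=10.0)
        assert orientation_weight("forward", "forward", params) == pytest.approx(0.5)
        assert orientation_weight("reverse", "forward", params) == pytest.approx(0.1)

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError):
            orientation_class("ambiguous", "forward")

    def test_ratio_law(self):
        # convergent : tandem : divergent = 1 : 1/w : 1/w^2 exactly
        for w in (1.5, 3.0, 4.0):
            params = ModelParams(w=w)
            c = orientation_weight("forward", "reverse", params)
            t = orientation_weight("forward", "forward", params)
            d = orientation_weight("reverse", "forward", params)
            assert c / t == pytest.approx(w)
            assert c / d == pytest.approx(w**2)


class TestDistanceDecay:
    def test_disabled_term_is_one(self):
        params = ModelParams(lam=None)
        assert distance_decay(123_456, params) == 1.0

    def test_exponential_closed_form(self):
        params = ModelParams(lam=300_000.0)
        assert distance_decay(300_000, params) == pytest.approx(np.exp(-1))
        assert distance_decay(1, params) == pytest.approx(1.0, abs=1e-5)

    def test_powerlaw_uses_kb_units(self):
        params = ModelParams(decay_kind="powerlaw", k=1.0)
        assert distance_decay(1000, params) == pytest.approx(1.0)
        assert distance_decay(10_000, params) == pytest.approx(0.1)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            distance_decay(0, ModelParams())

    def test_monotone_nonincreasing(self):
        params = ModelParams(lam=300_000.0)
        d = np.linspace(1, 1e6, 100)
        assert np.all(np.diff(distance_decay(d, params)) < 0)


class TestLoopCompetitionApprox:
    def test_empty_product_is_one(self):
        assert lc_approx([]) == 1.0

    @pytest.mark.parametrize(
        "ps,expected",
        [([0.5, 0.5], 0.25), ([0.5, 0.75], 0.125), ([0.0], 1.0)],
    )
    def test_internal_product(self, ps, expected):
        assert lc_approx(ps) == pytest.approx(expected)

    def test_from_intensities(self):
        # occupancy of x in {8.5, 25.5} at a=8.5 is {0.5, 0.75}
        params = ModelParams(a=8.5)
        ps = binding_probability(np.array([8.5, 25.5]), params)
        assert lc_approx(ps) == pytest.approx(0.125)

    def test_monotone_in_site_count(self):
        vals = [lc_approx([0.3] * k) for k in range(6)]
        assert np.all(np.diff(vals) < 0)

    def test_pass_through_attenuation(self):
        # a single competing occupancy 0.5 at s=0.4 contributes 1 - 0.6*0.5
        assert lc_approx([0.5], ModelParams(s=0.4)) == pytest.approx(0.7)
        assert lc_approx([0.5, 0.9], ModelParams(s=1.0)) == pytest.approx(1.0)


def _three_site_frame(ori=("forward", "reverse", "reverse"), xs=(1.0, 1.0, 1.0)):
    return make_sites([1000, 5000, 9000], ori, xs)


class TestLoopProbability:
    def test_decomposition_convergent(self, no_decay_params):
        # p_i = p_j = 0.5 at x = a; convergent, no internal sites
        sites = make_sites([0, 1000], ["forward", "reverse"], [8.5, 8.5])
        row = loop_probability(sites, "s0", "s1", no_decay_params)
        assert row["p_ij"] == pytest.approx(0.25)
        assert row["p_ij"] == pytest.approx(
            row["w_ij"] * row["p_i"] * row["p_j"] * row["D_ij"] * row["LC_ij"]
        )

    def test_tandem_three_fold_lower(self, no_decay_params):
        sites = make_sites([0, 1000], ["forward", "forward"], [8.5, 8.5])
        row = loop_probability(sites, "s0", "s1", no_decay_params)
        assert row["p_ij"] == pytest.approx(0.25 / 3)

    def test_internal_site_competes(self, no_decay_params):
        sites = make_sites([0, 500, 1000], ["forward", "forward", "reverse"], [8.5, 8.5, 8.5])
        row = loop_probability(sites, "s0", "s2", no_decay_params)
        assert row["p_ij"] == pytest.approx(0.25 * 0.5)

    def test_reduction_limit(self):
        # w = 1, no decay, no internal sites: p_ij = p_i * p_j exactly
        params = ModelParams(a=2.0, w=1.0, lam=None)
        sites = make_sites([0, 1000], ["reverse", "forward"], [3.0, 5.0])
        row = loop_probability(sites, "s0", "s1", params)
        assert row["p_ij"] == pytest.approx(row["p_i"] * row["p_j"])

    def test_bounded_by_anchor_occupancy(self, no_decay_params):
        sites = _three_site_frame(xs=(40.0, 10.0, 3.0))
        row = loop_probability(sites, "s0", "s2", no_decay_params)
        assert row["p_ij"] <= min(row["p_i"], row["p_j"])

    def test_different_chromosomes_rejected(self, no_decay_params):
        a = make_sites([0, 1000], ["forward", "reverse"], [1, 1], chrom="chr1")
        b = make_sites([0, 1000], ["forward", "reverse"], [1, 1], chrom="chr2")
        b["site_id"] = ["t0", "t1"]
        sites = pd.concat([a, b], ignore_index=True)
        with pytest.raises(ValueError):
            loop_probability(sites, "s0", "t1", no_decay_params)

    def test_pass_through_limits(self, no_decay_params):
        # s = 0 reduces to complete blocking; s = 1 removes competition
        sites = _three_site_frame(xs=(8.5, 8.5, 8.5))
        blocked = loop_probability(sites, "s0", "s2", no_decay_params.replace(s=0.0))
        free = loop_probability(sites, "s0", "s2", no_decay_params.replace(s=1.0))
        assert blocked["LC_ij"] == pytest.approx(0.5)
        assert free["LC_ij"] == pytest.approx(1.0)
        ss = np.linspace(0, 1, 11)
        ps = [
            loop_probability(sites, "s0", "s2", no_decay_params.replace(s=float(s)))["p_ij"]
            for s in ss
        ]
        assert np.all(np.diff(ps) >= 0)

    @given(st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_anchor_intensity(self, x_lo, x_hi):
        params = ModelParams(a=8.5, w=3.0, lam=None)
        lo, hi = sorted([x_lo, x_hi])
        sites_lo = make_sites([0, 1000], ["forward", "reverse"], [lo, 1.0])
        sites_hi = make_sites([0, 1000], ["forward", "reverse"], [hi, 1.0])
        p_lo = loop_probability(sites_lo, "s0", "s1", params)["p_ij"]
        p_hi = loop_probability(sites_hi, "s0", "s1", params)["p_ij"]
        assert p_hi >= p_lo


class TestScorePairs:
    def test_vectorized_matches_single_pair(self, no_decay_params):
        sites = make_sites(
            [0, 2000, 5000, 9000],
            ["forward", "reverse", "forward", "reverse"],
            [8.5, 3.0, 20.0, 8.5],
        )
        from loopcomp.io import enumerate_pairs

        pairs = score_pairs(sites, enumerate_pairs(sites), no_decay_params)
        for row in pairs.itertuples(index=False):
            single = loop_probability(sites, row.i, row.j, no_decay_params)
            assert row.p_ij == pytest.approx(single["p_ij"], rel=1e-12)

    def test_probabilities_normalized(self, default_landscape, no_decay_params):
        _, sites, pairs = default_landscape
        scored = score_pairs(sites, pairs, no_decay_params)
        assert ((scored["p_ij"] >= 0) & (scored["p_ij"] < 1)).all()
        assert (scored["p_ij"] <= np.minimum(scored["p_i"], scored["p_j"]) + 1e-12).all()


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"a": 0.0},
            {"w": 0.5},
            {"lam": -1.0},
            {"s": 1.5},
            {"decay_kind": "powerlaw", "k": 0.0},
            {"binding_kind": "sigmoid"},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_null_lambda_disables_decay(self):
        assert ModelParams(lam=None).decay_kind == "none"
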