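"""Exact arc geometry of the binary visual field and its functionals."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from viswarm import (
    AgentState2D,
    ArcSet,
    DegenerateGeometryError,
    field_edges,
    occlusion_union,
    subtended_arc,
    visual_field,
    weighted_area_integral,
    weighted_edge_sum,
    wrap_angle,
)


def agent(x, y, psi=0.0, v=1.0):
    return AgentState2D(x, y, v, psi)


class TestSubtendedArc:
    @pytest.mark.parametrize(
        "neighbor, expect_center, expect_half",
        [
            ((1.0, 0.0), 0.0, math.pi / 6),          # ahead at d = BL
            ((-2.0, 0.0), math.pi, math.asin(0.25)),  # behind at d = 2 BL
            ((0.0, 0.5), math.pi / 2, math.pi / 2),   # overlapping bodies, clamped
        ],
    )
    def test_closed_form_geometry(self, neighbor, expect_center, expect_half):
        c, w = subtended_arc(agent(0, 0), agent(*neighbor))
        assert c == pytest.approx(expect_center)
        assert w == pytest.approx(expect_half)

    def test_center_is_relative_to_heading(self):
        # neighbor due north, focal heading north -> bearing zero
        c, _ = subtended_arc(agent(0, 0, psi=math.pi / 2), agent(0, 5))
        assert c == pytest.approx(0.0)

    def test_coincident_positions_raise(self):
        with pytest.raises(DegenerateGeometryError):
            subtended_arc(agent(1, 2), agent(1, 2))

    def test_half_width_shrinks_with_distance(self):
        widths = [subtended_arc(agent(0, 0), agent(d, 0))[1] for d in (1, 2, 5, 50)]
        assert widths == sorted(widths, reverse=True)


class TestOcclusionUnion:
    def test_idempotent_union(self):
        arc = (0.3, 0.2)
        once = occlusion_union([arc])
        twice = occlusion_union([arc, arc])
        assert once == twice
        assert once.measure == pytest.approx(0.4)

    def test_hidden_neighbor_adds_nothing(self):
        near = (0.0, 0.4)
        far = (0.1, 0.1)  # arc strictly inside near's arc
        assert occlusion_union([near, far]) == occlusion_union([near])

    def test_disjoint_arcs_sorted(self):
        out = occlusion_union([(1.1, 0.1), (0.0, 0.1)])
        assert len(out) == 2
        assert out.arcs[0][0] == pytest.approx(-0.1)
        assert out.measure == pytest.approx(0.4)

    def test_wrapping_arc_is_split(self):
        out = occlusion_union([(math.pi, 0.2)])
        assert len(out) == 2
        assert out.measure == pytest.approx(0.4)
        assert out.contains(math.pi)
        assert out.contains(-math.pi + 0.1)

    def test_empty_input(self):
        assert occlusion_union([]) == ArcSet.empty()
        assert occlusion_union([]).measure == 0.0

    def test_saturating_arcs_give_full_circle(self):
        arcs = [(c, math.pi / 2) for c in np.linspace(-math.pi, math.pi, 9)]
        assert occlusion_union(arcs).is_full


class TestFieldEdges:
    def test_single_arc_two_edges(self):
        f = occlusion_union([(0.0, math.pi / 6)])
        assert field_edges(f) == pytest.approx([-math.pi / 6, math.pi / 6])

    def test_full_circle_no_edges(self):
        assert field_edges(ArcSet.full()) == []

    def test_two_arcs_four_edges(self):
        f = occlusion_union([(0.0, 0.1), (2.0, 0.2)])
        assert len(field_edges(f)) == 4

    def test_wrap_split_boundaries_not_counted(self):
        f = occlusion_union([(math.pi, 0.25)])
        edges = field_edges(f)
        assert len(edges) == 2
        assert set(np.round(np.abs(edges), 10)) == {round(math.pi - 0.25, 10)}


class TestWeightedFunctionals:
    def test_cos_area_symmetric_arc(self):
        f = occlusion_union([(0.0, math.pi / 6)])
        assert weighted_area_integral(f, "cos") == pytest.approx(1.0)
        assert weighted_area_integral(f, "sin") == pytest.approx(0.0, abs=1e-12)

    def test_full_circle_integrates_to_zero(self):
        assert weighted_area_integral(ArcSet.full(), "cos") == 0.0
        assert weighted_area_integral(ArcSet.full(), "sin") == 0.0

    def test_edge_sums_closed_forms(self):
        edges = [-math.pi / 6, math.pi / 6]
        assert weighted_edge_sum(edges, "cos") == pytest.approx(math.sqrt(3))
        assert weighted_edge_sum(edges, "sin") == pytest.approx(0.0, abs=1e-12)
        side = [math.pi / 2 - 0.02, math.pi / 2 + 0.02]
        assert weighted_edge_sum(side, "sin") == pytest.approx(2 * math.cos(0.02))

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            weighted_area_integral(ArcSet.full(), "tan")


def random_config(rng, n):
    """Focal at origin with random heading; n neighbors at distinct positions."""
    focal = AgentState2D(0.0, 0.0, 1.0, rng.uniform(-math.pi, math.pi))
    others = []
    while len(others) < n:
        x, y = rng.uniform(-8, 8, size=2)
        if math.hypot(x, y) > 1e-6:
            others.append(AgentState2D(x, y, 1.0, 0.0))
    return focal, others


class TestFieldInvariances:
    @given(st.floats(-math.pi, math.pi), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_rotational_equivariance(self, rot, seed):
        rng = np.random.default_rng(seed)
        focal, others = random_config(rng, 4)
        arcs = [subtended_arc(focal, o) for o in others]
        c, s = math.cos(rot), math.sin(rot)
        focal_r = AgentState2D(0.0, 0.0, 1.0, wrap_angle(focal.psi + rot))
        others_r = [
            AgentState2D(o.x * c - o.y * s, o.x * s + o.y * c, 1.0, 0.0)
            for o in others
        ]
        arcs_r = [subtended_arc(focal_r, o) for o in others_r]
        for (c0, w0), (c1, w1) in zip(arcs, arcs_r):
            assert math.isclose(
                wrap_angle(c0 - c1), 0.0, abs_tol=1e-9
            ) or math.isclose(abs(wrap_angle(c0 - c1)), 2 * math.pi, abs_tol=1e-9)
            assert w0 == pytest.approx(w1)

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.integers(0, 2**31 - 1)
    )
    @settings(max_examples=40, deadline=None)
    def test_translational_invariance(self, ox, oy, seed):
        rng = np.random.default_rng(seed)
        focal, others = random_config(rng, 4)
        f1 = visual_field(focal, others)
        focal_t = AgentState2D(focal.x + ox, focal.y + oy, 1.0, focal.psi)
        others_t = [AgentState2D(o.x + ox, o.y + oy, 1.0, o.psi) for o in others]
        f2 = visual_field(focal_t, others_t)
        assert np.allclose(f1.arcs, f2.arcs, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_mirror_symmetry_flips_sin_preserves_cos(self, seed):
        rng = np.random.default_rng(seed)
        focal, others = random_config(rng, 4)
        f1 = visual_field(focal, others)
        # reflect about the focal heading axis (heading 0 at origin here)
        focal_m = AgentState2D(0.0, 0.0, 1.0, -focal.psi)
        others_m = [AgentState2D(o.x, -o.y, 1.0, o.psi) for o in others]
        # rotate both so focal heads the same way; equivalent: compare functionals
        f1_cos = weighted_area_integral(f1, "cos")
        f1_sin = weighted_area_integral(f1, "sin")
        f2 = visual_field(focal_m, others_m)
        assert weighted_area_integral(f2, "cos") == pytest.approx(f1_cos, abs=1e-9)
        assert weighted_area_integral(f2, "sin") == pytest.approx(-f1_sin, abs=1e-9)
        e1s = weighted_edge_sum(field_edges(f1), "sin")
        e2s = weighted_edge_sum(field_edges(f2), "sin")
        assert e2s == pytest.approx(-e1s, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_occluded_agent_changes_nothing(self, seed):
        rng = np.random.default_rng(seed)
        focal, others = random_config(rng, 3)
        f1 = visual_field(focal, others)
        # add an agent twice as far along the direction of others[0]: its arc
        # is a strict subset of the nearer agent's arc
        far = AgentState2D(others[0].x * 2.0, others[0].y * 2.0, 1.0, 0.0)
        f2 = visual_field(focal, others + [far])
        assert np.allclose(f1.arcs, f2.arcs, atol=1e-12)


def rasterized_functionals(focal, others, n_bins=200_000, BL=1.0):
    """Brute-force retina oracle: rasterize V(phi), then integrate.

    Edges are located by 0/1 transitions between adjacent bins (periodic)
    and weighted once each, mirroring the unit-weight Dirac-comb reading of
    the squared angular derivative.
    """
    phi = -math.pi + (np.arange(n_bins) + 0.5) * (2 * math.pi / n_bins)
    v = np.zeros(n_bins, dtype=bool)
    for o in others:
        c, w = subtended_arc(focal, o, BL)
        delta = np.abs(np.mod(phi - c + math.pi, 2 * math.pi) - math.pi)
        v |= delta <= w
    dphi = 2 * math.pi / n_bins
    a_cos = float(np.sum(np.cos(phi) * v) * dphi)
    a_sin = float(np.sum(np.sin(phi) * v) * dphi)
    trans = v != np.roll(v, -1)
    phi_e = phi + dphi / 2
    e_cos = float(np.sum(np.cos(phi_e[trans])))
    e_sin = float(np.sum(np.sin(phi_e[trans])))
    return a_cos, a_sin, e_cos, e_sin


@pytest.mark.parametrize("seed", [11, 23, 37, 59])
@pytest.mark.parametrize("n", [1, 3, 6])
def test_analytic_matches_rasterized_retina(seed, n):
    """Grid oracle: a 2e5-bin rasterized retina reproduces the exact values."""
    rng = np.random.default_rng(seed)
    focal, others = random_config(rng, n)
    f = visual_field(focal, others)
    edges = field_edges(f)
    a_cos, a_sin, e_cos, e_sin = rasterized_functionals(focal, others)
    assert weighted_area_integral(f, "cos") == pytest.approx(a_cos, abs=1e-3)
    assert weighted_area_integral(f, "sin") == pytest.approx(a_sin, abs=1e-3)
    assert weighted_edge_sum(edges, "cos") == pytest.approx(e_cos, abs=1e-2)
    assert weighted_edge_sum(edges, "sin") == pytest.approx(e_sin, abs=1e-2)


class TestArcSetInvariants:
    def test_rejects_overlapping_arcs(self):
        with pytest.raises(ValueError):
            ArcSet([(0.0, 0.5), (0.4, 0.8)])

    def test_rejects_degenerate_arcs(self):
        with pytest.raises(ValueError):
            ArcSet([(0.5, 0.5)])

    @given(
        st.lists(
            st.tuples(
                st.floats(-math.pi, math.pi), st.floats(1e-3, math.pi / 2)
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_union_is_valid_and_bounded(self, raw):
        out = occlusion_union(raw)
        arcs = out.arcs
        assert np.all(arcs[:, 0] < arcs[:, 1])
        assert np.all(np.diff(arcs[:, 0]) > 0)
        assert out.measure <= 2 * math.pi + 1e-9
        biggest = max(2 * w for _, w in raw)
        assert out.measure >= min(biggest, 2 * math.pi) - 1e-9
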