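"""Compositional algebra: closure, descriptives, pivot ilr, reallocations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hac24 as h
from hac24.composition import PARTS, barycentric_xy

# the cohort compositional mean and the two example profiles printed as
# hours/day in the source material's worked examples
MEAN_HOURS = [10.23, 3.68, 1.24, 8.85]
PROFILE_A = [10.0, 3.0, 2.0, 9.0]     # 41.7 / 12.5 / 8.3 / 37.5 %
PROFILE_B = [7.6, 5.4, 2.0, 9.0]      # 31.7 / 22.5 / 8.3 / 37.5 %


def positive_composition(draw):
    vals = draw(st.lists(st.floats(0.01, 0.96), min_size=4, max_size=4))
    return h.close(np.array(vals) + 0.01)


comp_strategy = st.builds(
    lambda v: h.close(np.asarray(v) + 0.01),
    st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=4, max_size=4),
)


class TestClose:
    def test_simple_hours(self):
        c = h.close([12, 6, 2, 4])
        np.testing.assert_allclose(c.proportions, [0.5, 0.25, 1 / 12, 1 / 6])

    def test_idempotent(self):
        c = h.close([0.5, 0.25, 1 / 12, 1 / 6])
        np.testing.assert_allclose(h.close(c.proportions).proportions,
                                   c.proportions)

    def test_cohort_mean_percentages(self):
        """The printed compositional mean converts to 42.6/15.3/5.2/36.9%."""
        c = h.close(MEAN_HOURS)
        np.testing.assert_allclose(np.round(c.proportions * 100, 1),
                                   [42.6, 15.3, 5.2, 36.9])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            h.close([0, 0, 0, 0])


class TestCompositionalMean:
    def test_identical_sample(self):
        c = h.close(MEAN_HOURS)
        m = h.compositional_mean([c] * 5)
        np.testing.assert_allclose(m.proportions, c.proportions, atol=1e-12)

    def test_two_part_symmetry(self):
        sample = np.array([[0.2, 0.8], [0.8, 0.2]])
        m = h.compositional_mean(sample)
        np.testing.assert_allclose(m.proportions, [0.5, 0.5])

    def test_against_longhand_geometric_mean(self, rng):
        X = rng.dirichlet(np.ones(4), size=50)
        m = h.compositional_mean(X)
        # independent long-hand: per-part product^(1/n), then normalize
        gm = np.array([np.prod(X[:, j]) ** (1.0 / 50) for j in range(4)])
        np.testing.assert_allclose(m.proportions, gm / gm.sum(), rtol=1e-8)

    def test_zero_part_rejected(self):
        with pytest.raises(ValueError, match="impute_zeros"):
            h.compositional_mean(np.array([[0.5, 0.5, 0.0, 0.0]] * 3))


class TestVariationMatrix:
    def test_proportional_parts_have_zero_entry(self, rng):
        a = rng.uniform(0.1, 1.0, size=20)
        X = np.column_stack([a, 2 * a, rng.uniform(0.1, 1, 20)])
        X = X / X.sum(axis=1, keepdims=True)
        T = h.variation_matrix(X)
        assert T[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diag(T) == 0)

    def test_three_observation_hand_case(self):
        X = np.array([[0.5, 0.3, 0.2], [0.4, 0.4, 0.2], [0.6, 0.2, 0.2]])
        T = h.variation_matrix(X)
        lr = np.log(X[:, 0] / X[:, 1])
        hand = sum((v - lr.mean()) ** 2 for v in lr) / 2  # ddof=1, n=3
        assert T[0, 1] == pytest.approx(hand, rel=1e-12)
        np.testing.assert_allclose(T, T.T)

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            h.variation_matrix(np.array([[0.5, 0.5]]))


class TestPivotIlr:
    def test_two_part_balanced_is_zero(self):
        basis = h.PivotBasis(("a", "b"))
        z = h.pivot_ilr(h.close([1, 1], ("a", "b")), basis)
        assert z.values[0] == pytest.approx(0.0)

    def test_step_pivot_printed_profile(self):
        """z1 of the 41.7/12.5/8.3/37.5% profile with step as the pivot,
        frozen from a direct evaluation of sqrt(3/4)*ln(step/gmean(rest))."""
        c = h.close(PROFILE_A)
        z = h.pivot_ilr(c, h.PivotBasis.for_pivot("step"))
        x = c.as_dict()
        direct = math.sqrt(3 / 4) * math.log(
            x["step"] / (x["sit"] * x["stand"] * x["sleep"]) ** (1 / 3))
        assert z.values[0] == pytest.approx(direct, rel=1e-12)
        assert z.values[0] == pytest.approx(-1.02, abs=0.005)

    def test_round_trip(self, rng):
        for pivot in PARTS:
            basis = h.PivotBasis.for_pivot(pivot)
            c = h.close(rng.dirichlet(np.ones(4)))
            back = h.inverse_ilr(h.pivot_ilr(c, basis), basis)
            np.testing.assert_allclose(back.reorder(PARTS).proportions,
                                       c.proportions, atol=1e-10)

    def test_zero_vector_gives_uniform(self):
        basis = h.PivotBasis.for_pivot("sit")
        c = h.inverse_ilr(np.zeros(3), basis)
        np.testing.assert_allclose(c.proportions, 0.25)

    def test_forward_recovers_random_coordinates(self, rng):
        basis = h.PivotBasis.for_pivot("stand")
        z = rng.normal(size=3)
        z2 = h.pivot_ilr(h.inverse_ilr(z, basis), basis)
        np.testing.assert_allclose(z2.values, z, atol=1e-10)

    def test_matches_scikit_bio_with_same_basis(self, rng):
        """Independent oracle: skbio's ilr with our contrast matrix."""
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        basis = h.PivotBasis.for_pivot("step")
        V = basis.contrast_matrix()
        c = h.close(rng.dirichlet(np.ones(4)))
        x = c.reorder(basis.order).proportions
        ours = h.pivot_ilr(c, basis).values
        theirs = skbio_comp.ilr(x, basis=V)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_zero_part_rejected(self):
        with pytest.raises(ValueError):
            h.pivot_ilr(h.Composition(PARTS, np.array([0.5, 0.5, 0.0, 0.0])),
                        h.PivotBasis.for_pivot("sit"))


class TestIlrContrast:
    def test_identical_profiles(self):
        c = h.close(MEAN_HOURS)
        z = h.ilr_contrast(c, c, h.PivotBasis.for_pivot("sit"))
        np.testing.assert_allclose(z.values, 0.0, atol=1e-14)

    def test_printed_profile_pair_first_coordinate(self):
        """The sit-to-stand shifted profile differs from baseline by about
        -0.1 on the step pivot coordinate (one decimal)."""
        a, b = h.close(PROFILE_A), h.close(PROFILE_B)
        dz = h.ilr_contrast(a, b, h.PivotBasis.for_pivot("step"))
        assert round(float(dz.values[0]), 1) == -0.1

    def test_antisymmetry(self, rng):
        basis = h.PivotBasis.for_pivot("sleep")
        a = h.close(rng.dirichlet(np.ones(4)))
        b = h.close(rng.dirichlet(np.ones(4)))
        np.testing.assert_allclose(h.ilr_contrast(a, b, basis).values,
                                   -h.ilr_contrast(b, a, basis).values,
                                   atol=1e-12)


class TestOneVsRemainingRealloc:
    def test_ten_minute_step_increase_worked_example(self):
        """+10 min of stepping from the cohort mean: r about 13%, common
        decrease s about 0.7%, standing down about 1.6 min."""
        base = h.close(MEAN_HOURS)
        spec, new = h.one_vs_remaining_realloc(base, "step", 10.0, 1440.0)
        assert spec.r * 100 == pytest.approx(13.0, abs=0.5)
        assert spec.s * 100 == pytest.approx(0.7, abs=0.05)
        stand_drop = (base.part("stand") - new.part("stand")) * 1440.0
        assert stand_drop == pytest.approx(1.6, abs=0.05)

    def test_zero_delta_is_identity(self):
        base = h.close(MEAN_HOURS)
        spec, new = h.one_vs_remaining_realloc(base, "sit", 0.0)
        assert spec.r == spec.s == 0.0
        np.testing.assert_allclose(new.proportions, base.proportions)

    def test_remaining_ratios_constant_and_s_formula(self, rng):
        base = h.close(rng.dirichlet(np.ones(4)))
        spec, new = h.one_vs_remaining_realloc(base, "step", 12.0)
        others = [p for p in PARTS if p != "step"]
        for i, j in [(0, 1), (1, 2)]:
            assert new.part(others[i]) / new.part(others[j]) == pytest.approx(
                base.part(others[i]) / base.part(others[j]), rel=1e-12)
        assert spec.s == pytest.approx(spec.r * spec.x1 / (1 - spec.x1),
                                       abs=1e-15)
        assert new.proportions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_common_factor_against_root_finding_oracle(self):
        """Brute-force oracle: solve for the common shrink factor that
        restores closure after scaling the target part."""
        from scipy.optimize import brentq

        base = h.close(MEAN_HOURS)
        delta = 25.0
        spec, _ = h.one_vs_remaining_realloc(base, "stand", delta, 1440.0)
        x1 = base.part("stand")
        r = delta / (x1 * 1440.0)

        def closure_gap(s):
            scaled = [x1 * (1 + r) if p == "stand" else base.part(p) * (1 - s)
                      for p in PARTS]
            return sum(scaled) - 1.0

        s_oracle = brentq(closure_gap, -0.9, 0.9, xtol=1e-14)
        assert spec.s == pytest.approx(s_oracle, abs=1e-12)

    def test_out_of_range_delta_rejected(self):
        base = h.close(MEAN_HOURS)
        with pytest.raises(ValueError):
            h.one_vs_remaining_realloc(base, "step", -80.0, 1440.0)


class TestPairwiseRealloc:
    def test_sit_to_stand_worked_example(self):
        """2.4 h from sitting to standing: 31.7% sit, 22.5% stand."""
        new = h.pairwise_realloc(dict(zip(PARTS, PROFILE_A)), "sit", "stand",
                                 2.4)
        assert round(new.part("sit") * 100, 1) == 31.7
        assert round(new.part("stand") * 100, 1) == 22.5

    def test_zero_delta_and_inverse(self):
        base = dict(zip(PARTS, PROFILE_A))
        same = h.pairwise_realloc(base, "sit", "step", 0.0)
        np.testing.assert_allclose(same.proportions,
                                   h.close(PROFILE_A).proportions)
        fwd = h.pairwise_realloc(base, "sit", "step", 1.5)
        back = h.pairwise_realloc(
            {p: fwd.part(p) * sum(PROFILE_A) for p in PARTS},
            "sit", "step", -1.5)
        np.testing.assert_allclose(back.proportions,
                                   h.close(PROFILE_A).proportions, atol=1e-12)

    def test_exhausting_a_part_rejected(self):
        with pytest.raises(ValueError):
            h.pairwise_realloc(dict(zip(PARTS, PROFILE_A)), "step", "sit", 2.0)


class TestJamesTest:
    def test_identical_groups(self, rng):
        g = rng.normal(size=(50, 3))
        stat, p = h.james_test([g, g.copy()])
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_large_shift_detected(self, rng):
        g1 = rng.normal(size=(100, 3))
        g2 = rng.normal(size=(100, 3)) + 2.0
        _, p = h.james_test([g1, g2])
        assert p < 0.001

    def test_permutation_fallback_agrees_in_direction(self, rng):
        g1 = rng.normal(size=(15, 2))
        g2 = rng.normal(size=(15, 2)) + 1.5
        _, p_perm = h.james_test([g1, g2], permutations=199, seed=1)
        assert p_perm < 0.05


class TestTernary:
    def test_vertices_map_to_triangle_corners(self):
        xy = barycentric_xy(np.eye(3))
        np.testing.assert_allclose(
            xy, [[0, 0], [1, 0], [0.5, math.sqrt(3) / 2]], atol=1e-12)

    def test_uniform_maps_to_centroid(self):
        xy = barycentric_xy(np.array([[1 / 3, 1 / 3, 1 / 3]]))
        np.testing.assert_allclose(xy[0], [0.5, math.sqrt(3) / 6], atol=1e-12)

    def test_axis_values_readable_from_point(self):
        """A point at 49/38/13 projects where the three axis readings
        recover those percentages."""
        comp = np.array([[0.49, 0.38, 0.13]])
        x, y = barycentric_xy(comp)[0]
        c = y / (math.sqrt(3) / 2)
        b = x - 0.5 * c
        assert (round(1 - b - c, 2), round(b, 2), round(c, 2)) == \
            (0.49, 0.38, 0.13)

    def test_figure_written(self, tmp_path, rng):
        X = rng.dirichlet(np.ones(4), size=30)
        out = tmp_path / "tern.png"
        h.ternary_plot(X, color=rng.normal(size=30), path=str(out))
        assert out.exists()

    def test_wrong_width_rejected(self):
        with pytest.raises(ValueError):
            barycentric_xy(np.ones((3, 4)))


class TestIlrProperties:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.05, 10.0), min_size=4, max_size=4),
           st.floats(0.1, 100.0))
    def test_scale_invariance(self, amounts, k):
        basis = h.PivotBasis.for_pivot("step")
        z1 = h.pivot_ilr(h.close(amounts), basis)
        z2 = h.pivot_ilr(h.close([k * a for a in amounts]), basis)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.05, 10.0), min_size=4, max_size=4),
           st.lists(st.floats(0.05, 10.0), min_size=4, max_size=4))
    def test_distances_preserved_across_bases(self, a, b):
        """Pivot bases are orthonormal rotations: coordinate distances do
        not depend on the chosen pivot."""
        ca, cb = h.close(a), h.close(b)
        dists = []
        for pivot in PARTS:
            basis = h.PivotBasis.for_pivot(pivot)
            dz = h.pivot_ilr(ca, basis).values - h.pivot_ilr(cb, basis).values
            dists.append(np.linalg.norm(dz))
        np.testing.assert_allclose(dists, dists[0], rtol=1e-9, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-3.0, 3.0), min_size=3, max_size=3))
    def test_inverse_is_right_inverse(self, z):
        basis = h.PivotBasis.for_pivot("sleep")
        z2 = h.pivot_ilr(h.inverse_ilr(np.array(z), basis), basis)
        np.testing.assert_allclose(z2.values, z, atol=1e-10)
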