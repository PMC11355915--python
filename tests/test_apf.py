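"""APF curves and the signed-supremum asymmetry between image pairs."""

import numpy as np
import pytest

from reva.apf import APFCurve, ReVAExtractor, apf_curve, compute_reva_pair, reva, rrpd
from reva.persistence import PersistenceDiagram, compute_persistence
from reva.synthetic import VesselParams, make_pair, make_vessel_image

from conftest import random_small_image


def make_diagram(pairs, dim=0):
    b = np.array([p[0] for p in pairs], dtype=float)
    d = np.array([p[1] for p in pairs], dtype=float)
    return PersistenceDiagram(b, d, np.zeros(len(pairs), dtype=bool), dim=dim)


class TestRRPD:
    def test_mean_age_and_lifetime(self):
        r = rrpd(make_diagram([(0, 2), (1, 2)]))
        assert sorted(zip(r.mean_ages, r.lifetimes)) == [(1.0, 2.0), (1.5, 1.0)]

    def test_empty_diagram(self):
        assert len(rrpd(make_diagram([]))) == 0

    def test_zero_lifetime_point(self):
        r = rrpd(make_diagram([(3, 3)]))
        assert list(zip(r.mean_ages, r.lifetimes)) == [(3.0, 0.0)]

    def test_infinite_death_rejected(self):
        with pytest.raises(ValueError):
            rrpd(PersistenceDiagram(np.array([0.0]), np.array([np.inf]),
                                    np.array([True]), dim=0))


class TestAPFCurve:
    def test_cumulative_lifetime_sum(self):
        curve = apf_curve(rrpd(make_diagram([(0, 2), (1, 2)])))
        assert curve(0.9) == 0.0
        assert curve(1.0) == 2.0
        assert curve(1.5) == 3.0
        assert curve(10.0) == 3.0

    def test_empty_rrpd_gives_zero_curve(self):
        curve = apf_curve(rrpd(make_diagram([])))
        assert curve(0.0) == 0.0 and curve.total == 0.0

    def test_ties_merge_into_one_step(self):
        # two features with equal mean age 2: lifetimes 1 ((1.5,2.5)) and 2 ((1,3))
        curve = apf_curve(rrpd(make_diagram([(1.5, 2.5), (1.0, 3.0)])))
        assert curve.breakpoints.tolist() == [2.0]
        assert curve(2.0) == 3.0

    def test_curve_is_right_continuous_and_non_decreasing(self, rng):
        pairs = np.sort(rng.random((20, 2)), axis=1)
        curve = apf_curve(rrpd(make_diagram(pairs.tolist())))
        grid = np.linspace(-1, 2, 400)
        vals = curve(grid)
        assert np.all(np.diff(vals) >= 0)
        assert np.allclose(curve(curve.breakpoints), curve.cumulative)


class TestRevaMeasure:
    def test_identical_curves_give_zero_at_first_breakpoint(self):
        curve = apf_curve(rrpd(make_diagram([(0, 2), (1, 2)])))
        value, m_max = reva(curve, curve)
        assert value == 0.0
        assert m_max == curve.breakpoints[0]

    def test_signed_difference_at_supremum(self):
        left = apf_curve(rrpd(make_diagram([(0, 2), (1, 2)])))   # steps 0->2->3 at m=1,1.5
        right = apf_curve(rrpd(make_diagram([(0, 2)])))          # step 0->2 at m=1
        value, m_max = reva(left, right)
        assert value == -1.0
        assert m_max == 1.5

    def test_antisymmetric_in_arguments(self, rng):
        a = apf_curve(rrpd(make_diagram(np.sort(rng.random((8, 2)), axis=1).tolist())))
        b = apf_curve(rrpd(make_diagram(np.sort(rng.random((5, 2)), axis=1).tolist())))
        v_ab, m_ab = reva(a, b)
        v_ba, m_ba = reva(b, a)
        assert v_ab == -v_ba and m_ab == m_ba

    def test_dim_mismatch_rejected(self):
        c0 = apf_curve(rrpd(make_diagram([(0, 1)], dim=0)))
        c1 = apf_curve(rrpd(make_diagram([(0, 1)], dim=1)))
        with pytest.raises(ValueError):
            reva(c0, c1)

    def test_transform_mismatch_rejected(self):
        a = APFCurve(np.array([1.0]), np.array([1.0]), dim=0, transform="unit")
        b = APFCurve(np.array([1.0]), np.array([1.0]), dim=0, transform="z")
        with pytest.raises(ValueError):
            reva(a, b)

    def test_supremum_dominates_dense_grid(self, rng):
        a = apf_curve(rrpd(make_diagram(np.sort(rng.random((15, 2)), axis=1).tolist())))
        b = apf_curve(rrpd(make_diagram(np.sort(rng.random((9, 2)), axis=1).tolist())))
        value, _ = reva(a, b)
        grid = np.linspace(-0.5, 1.5, 2000)
        assert np.abs(value) >= np.max(np.abs(b(grid) - a(grid))) - 1e-12

    def test_bounded_by_total_lifetimes(self, rng):
        a = apf_curve(rrpd(make_diagram(np.sort(rng.random((15, 2)), axis=1).tolist())))
        b = apf_curve(rrpd(make_diagram(np.sort(rng.random((9, 2)), axis=1).tolist())))
        value, _ = reva(a, b)
        assert np.abs(value) <= a.total + b.total


class TestComputeRevaPair:
    def test_identical_images_give_exact_zero(self, rng):
        z = random_small_image(rng, max_side=8)
        for transform in ("unit", "z"):
            res = compute_reva_pair(z, z, transform=transform)
            assert res.reva0 == 0.0 and res.reva1 == 0.0

    def test_swapping_sides_negates_both_dimensions(self):
        left, right = make_pair((48, 48), VesselParams(), 0.4, seed=17)
        fwd = compute_reva_pair(left, right)
        rev = compute_reva_pair(right, left)
        assert fwd.reva0 == -rev.reva0
        assert fwd.reva1 == -rev.reva1
        assert fwd.m0_max == rev.m0_max

    def test_added_lesion_blob_produces_nonzero_asymmetry(self):
        left = make_vessel_image((48, 48), seed=23)
        lesion = left.values.copy()
        lesion[10:16, 30:36] = 1.0  # bright blob on the right image only
        res = compute_reva_pair(left.values, lesion)
        assert abs(res.reva0) > 0

    def test_shape_mismatch_warns(self, rng):
        with pytest.warns(UserWarning, match="pre-aligned"):
            compute_reva_pair(rng.random((5, 5)), rng.random((6, 5)))

    def test_unknown_transform_rejected(self, rng):
        z = rng.random((4, 4))
        with pytest.raises(ValueError):
            compute_reva_pair(z, z, transform="minmax")


class TestReVAExtractor:
    def test_transform_matches_function_and_sklearn_contract(self, rng):
        from sklearn.base import clone

        pairs = [
            (rng.random((6, 6)), rng.random((6, 6))),
            (rng.random((6, 6)), rng.random((6, 6))),
        ]
        est = ReVAExtractor(intensity_transform="unit")
        assert clone(est).get_params() == est.get_params()
        out = est.fit_transform(pairs)
        assert out.shape == (2, 4)
        ref = compute_reva_pair(pairs[0][0], pairs[0][1])
        assert out[0].tolist() == [ref.reva0, ref.reva1, ref.m0_max, ref.m1_max]
        assert list(est.get_feature_names_out()) == ["reva0", "reva1", "m0_max", "m1_max"]
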