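import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cilioscope import (
    CohortModel,
    assign_cluster,
    bland_altman,
    ellipses_overlap,
    fit_cohort_model,
    leave_one_out_assignment,
    paired_two_sided_t,
)
from cilioscope.reference import GROUP_CENTROIDS, sample_cohort_medians


class TestBlandAltman:
    def test_identical_series(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a)
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.all_within

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a + 0.3)
        assert res.bias == pytest.approx(-0.3)
        assert res.sd == pytest.approx(0.0)
        assert res.loa_low == pytest.approx(-0.3)
        assert res.loa_high == pytest.approx(-0.3)

    def test_normal_differences_coverage_near_954(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 200)
        b = np.zeros(200)
        res = bland_altman(a, b)
        frac = np.mean((res.differences >= res.loa_low)
                       & (res.differences <= res.loa_high))
        assert frac == pytest.approx(0.954, abs=0.03)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=20))
    def test_antisymmetric_in_its_arguments(self, vals):
        a = np.asarray(vals)
        b = a[::-1].copy()
        fwd = bland_altman(a, b)
        rev = bland_altman(b, a)
        assert fwd.bias == pytest.approx(-rev.bias, abs=1e-9)
        assert fwd.loa_low == pytest.approx(-rev.loa_high, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            bland_altman([1.0], [2.0])


class TestPairedT:
    def test_identical_series_p_one(self):
        t, p = paired_two_sided_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_differences(self):
        # d = [1,2,3,4]: t = 2.5 / (1.29099/2) = 3.873
        b = np.array([10.0, 20.0, 30.0, 40.0])
        a = b + np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_two_sided_t(a, b)
        assert t == pytest.approx(3.873, abs=1e-3)
        assert 0 < p < 0.05

    def test_sign_flip_negates_t_keeps_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.3, 1, 30)
        t1, p1 = paired_two_sided_t(a, b)
        t2, p2 = paired_two_sided_t(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_constant_nonzero_difference(self):
        t, p = paired_two_sided_t([1.0, 2.0], [0.5, 1.5])
        assert t == np.inf
        assert p == 0.0


def _printed_model(ift_sd=0.05, len_sd=0.2):
    groups = {}
    rng = np.random.default_rng(0)
    for name, (cx, cy) in GROUP_CENTROIDS.items():
        pts = np.column_stack([
            rng.normal(cx, len_sd, 5), rng.normal(cy, ift_sd, 5)
        ])
        groups[name] = pts
    return fit_cohort_model(groups)


class TestCohortModel:
    def test_isotropic_unit_covariance_ellipse_radius(self):
        pts = np.array([[0.0, 0.0]])
        model = CohortModel(groups={}, levels=(0.5, 0.9))
        assert np.sqrt(model.chi2_radius(0.9)) == pytest.approx(2.146, abs=1e-3)
        assert model.chi2_radius(0.5) == pytest.approx(1.3863, abs=1e-3)

    def test_identical_lines_regularized(self):
        groups = {"g": np.array([[3.7, 0.43]] * 4)}
        model = fit_cohort_model(groups, cov_floor=None)
        g = model.groups["g"]
        np.testing.assert_allclose(g.centroid, [3.7, 0.43])
        assert np.linalg.det(g.cov) > 0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_cohort_model({"g": np.array([[1.0, 1.0], [2.0, 2.0]])})

    def test_json_round_trip(self, tmp_path):
        model = _printed_model()
        model.to_json(tmp_path / "m.json")
        back = CohortModel.from_json(tmp_path / "m.json")
        for name in model.groups:
            np.testing.assert_allclose(back.groups[name].centroid,
                                       model.groups[name].centroid)
            np.testing.assert_allclose(back.groups[name].cov,
                                       model.groups[name].cov)

    def test_membership_at_05_implies_09(self):
        model = _printed_model()
        rng = np.random.default_rng(1)
        for _ in range(200):
            pt = rng.uniform([1.5, 0.2], [5.5, 1.2])
            for g in model.groups:
                if model.inside(pt, g, 0.5):
                    assert model.inside(pt, g, 0.9)


class TestAssignment:
    def test_centroid_assigns_to_own_group_distance_zero(self):
        model = _printed_model()
        for name, g in model.groups.items():
            res = assign_cluster(g.centroid, model)
            assert res.label == name
            assert res.distances[name] == pytest.approx(0.0, abs=1e-6)

    def test_atd_point_assigned_atd(self):
        model = _printed_model()
        assert assign_cluster((4.81, 0.54), model).label == "ATD"

    def test_far_point_outside_all_09_ellipses(self):
        model = _printed_model()
        res = assign_cluster((10.0, 5.0), model)
        assert not any(res.inside_09.values())
        assert res.label in model.groups

    def test_nonfinite_point_rejected(self):
        model = _printed_model()
        with pytest.raises(ValueError):
            assign_cluster((np.nan, 0.4), model)


class TestSeparationAndRecovery:
    def test_overlap_detects_coincident_groups(self):
        pts = np.random.default_rng(0).normal(0, 1, (6, 2)) + [3.7, 0.43]
        model = fit_cohort_model({"a": pts, "b": pts + 0.01})
        assert ellipses_overlap(model, "a", "b", 0.9)

    def test_printed_cohorts_separate_atd_from_ced(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            groups = sample_cohort_medians({"control": 6, "ATD": 5, "CED": 3},
                                           rng)
            model = fit_cohort_model(groups)
            assert not ellipses_overlap(model, "ATD", "CED", 0.9)

    def test_leave_one_out_recovery_printed_spreads(self):
        rng = np.random.default_rng(0)
        groups = sample_cohort_medians({"control": 6, "ATD": 5, "CED": 3}, rng)
        correct, total = leave_one_out_assignment(groups)
        assert total == 14
        assert correct >= 13
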