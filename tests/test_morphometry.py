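import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cilioscope import (
    FieldImage,
    LengthCalibration,
    calibrate_length,
    classify_structure,
    ift_area,
    match_to_truth,
    merge_axoneme,
    segment_cilia,
    skeleton_length,
)
from cilioscope.detect import CiliumCandidate
from cilioscope.morphometry import circularity
from cilioscope.synth import _paint_disk

PX = 0.1


def _candidate_from_mask(mask):
    cands = segment_cilia(mask.astype(float), PX)
    assert len(cands) == 1
    return cands[0]


def _line_candidate(n_px=38):
    mask = np.zeros((80, 80))
    mask[40:42, 20:20 + n_px] = 1.0
    return _candidate_from_mask(mask)


def _manual_candidate(mask):
    """Candidate built straight from a boolean mask, bypassing the
    segmentation chain (no closing, no area filter)."""
    from cilioscope.detect import _longest_geodesic
    from skimage.morphology import skeletonize

    path, length = _longest_geodesic(skeletonize(mask), spur_px=3)
    rows, cols = np.nonzero(mask)
    return CiliumCandidate(
        cilium_id=0, mask=mask, skeleton=path, skeleton_length_px=length,
        area_um2=mask.sum() * PX**2,
        bbox=(rows.min(), cols.min(), rows.max() + 1, cols.max() + 1),
    )


class TestSkeletonLength:
    def test_straight_38px_skeleton_is_3_7_um(self):
        cand = _line_candidate(38)
        assert skeleton_length(cand, PX) == pytest.approx(3.7, abs=0.01)

    def test_diagonal_skeleton_uses_sqrt2_steps(self):
        mask = np.zeros((30, 30), dtype=bool)
        for i in range(11):
            mask[10 + i, 10 + i] = True
        cand = _manual_candidate(mask)
        # 10 diagonal unit steps of sqrt(2) * 0.1 µm
        assert skeleton_length(cand, PX) == pytest.approx(10 * np.sqrt(2) * PX)

    def test_scale_equivariance(self):
        cand = _line_candidate(38)
        assert skeleton_length(cand, 0.2) == pytest.approx(
            2 * skeleton_length(cand, 0.1)
        )

    def test_curved_cilium_raw_length_close_to_truth(self, clean_field):
        img, truth = clean_field
        cands = segment_cilia(merge_axoneme(img), PX)
        matches = match_to_truth([c.endpoints for c in cands], truth, PX)
        tb = {c.cell_id: c for c in truth.cells}
        errs = [
            abs(skeleton_length(cands[k], PX) - tb[cid].true_length_um)
            / tb[cid].true_length_um
            for k, cid in matches.items()
        ]
        assert np.median(errs) < 0.05

    def test_longer_painted_cilium_measures_longer(self):
        from cilioscope import SyntheticSpec, render_field

        medians = []
        for true_len in (3.0, 4.5):
            spec = SyntheticSpec(
                n_cells=8, frac_ciliated=1.0, frac_spot=0.0,
                length_dist=("constant", (true_len,)),
                noise_gaussian_sd=0.0, seed=21,
            )
            img, _ = render_field(spec)
            cands = segment_cilia(merge_axoneme(img), PX)
            medians.append(np.median([skeleton_length(c, PX) for c in cands]))
        assert medians[1] > medians[0]


class TestCalibration:
    def test_identity_pairs_give_identity_fit(self):
        x = np.array([2.0, 3.0, 4.0, 5.0])
        cal = calibrate_length(x, x)
        assert cal.slope == pytest.approx(1.0, abs=1e-9)
        assert cal.offset == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_recovered(self):
        truth = np.array([2.0, 3.0, 4.0, 5.0])
        cal = calibrate_length(truth + 0.2, truth)
        assert cal.slope == pytest.approx(1.0, abs=1e-9)
        assert cal.offset == pytest.approx(-0.2, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(slope=st.floats(0.5, 2.0), offset=st.floats(-0.5, 0.5))
    def test_affine_distortion_recovered_exactly(self, slope, offset):
        truth = np.linspace(1.0, 5.0, 9)
        measured = (truth - offset) / slope
        cal = calibrate_length(measured, truth)
        assert cal.slope == pytest.approx(slope, abs=1e-6)
        assert cal.offset == pytest.approx(offset, abs=1e-6)

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            calibrate_length([1.0, 2.0], [1.0, 2.0])

    def test_degenerate_measurements_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_length([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_apply_clips_at_zero(self):
        cal = LengthCalibration(slope=1.0, offset=-1.0)
        assert cal.apply(0.5) == 0.0

    def test_json_round_trip(self, tmp_path):
        cal = LengthCalibration(0.93, 0.12, fitted_on="artificial")
        cal.to_json(tmp_path / "cal.json")
        back = LengthCalibration.from_json(tmp_path / "cal.json")
        assert (back.slope, back.offset) == (cal.slope, cal.offset)


class TestClassification:
    def test_elongated_candidate_is_cilium(self):
        cand = _line_candidate(35)
        assert classify_structure(cand, corrected_length_um=3.5) == "cilium"

    def test_round_short_blob_is_spot(self):
        mask = np.zeros((64, 64))
        _paint_disk(mask, np.array([32.0, 32.0]), 4.0, 1.0)
        cand = _candidate_from_mask(mask)
        assert circularity(cand) > 0.6
        assert classify_structure(cand, corrected_length_um=0.5) == "spot"

    def test_short_but_elongated_is_cilium(self):
        # 1.2 µm x 0.2 µm thin bar: low circularity, stays a cilium
        mask = np.zeros((30, 30), dtype=bool)
        mask[15:17, 8:20] = True
        cand = _manual_candidate(mask)
        assert circularity(cand) <= 0.6
        assert classify_structure(cand, corrected_length_um=0.8) == "cilium"

    def test_mixture_field_agreement_with_truth(self, mixed_field):
        from cilioscope import analyze_field

        img, truth = mixed_field
        res = analyze_field(img)
        true_counts = {c: sum(t.true_class == c for t in truth.cells)
                       for c in ("cilium", "spot", "none")}
        meas_counts = {c: res.cell_classes.count(c)
                       for c in ("cilium", "spot", "none")}
        assert meas_counts == true_counts


class TestIftArea:
    def _field_with_transport(self, transport):
        zeros = np.zeros_like(transport)
        return FieldImage(
            {"nucleus": zeros, "axoneme": zeros, "membrane": zeros,
             "transport": transport}, PX)

    def test_area_is_pixel_count_times_pixel_area(self):
        cand = _line_candidate(40)
        transport = np.zeros((80, 80))
        # 43 bright pixels inside the search region
        transport[40:41, 20:63] = 1.0
        field = self._field_with_transport(transport)
        assert ift_area(field, cand) == pytest.approx(43 * PX**2)

    def test_blank_transport_plane_measures_zero(self):
        cand = _line_candidate(40)
        field = self._field_with_transport(np.zeros((80, 80)))
        assert ift_area(field, cand) == 0.0

    def test_disjoint_accumulations_add(self):
        cand = _line_candidate(40)
        t1 = np.zeros((80, 80))
        t1[40:43, 22:28] = 1.0
        t2 = np.zeros((80, 80))
        t2[40:43, 50:56] = 1.0
        f1 = self._field_with_transport(t1)
        f2 = self._field_with_transport(t2)
        f12 = self._field_with_transport(np.maximum(t1, t2))
        assert ift_area(f12, cand) == pytest.approx(
            ift_area(f1, cand) + ift_area(f2, cand)
        )

    def test_recovers_painted_tip_area_over_background(self, clean_field):
        img, truth = clean_field
        cands = segment_cilia(merge_axoneme(img), PX)
        matches = match_to_truth([c.endpoints for c in cands], truth, PX)
        tb = {c.cell_id: c for c in truth.cells}
        errs = [
            abs(ift_area(img, cands[k]) - tb[cid].true_ift_area_um2)
            / tb[cid].true_ift_area_um2
            for k, cid in matches.items()
        ]
        assert np.median(errs) < 0.15

    def test_missing_transport_plane_raises(self):
        cand = _line_candidate(40)
        field = FieldImage({"nucleus": np.zeros((80, 80))}, PX)
        with pytest.raises(KeyError, match="transport"):
            ift_area(field, cand)
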