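import numpy as np
import pytest

from cilioscope import (
    FieldImage,
    assign_cilia_to_cells,
    detect_basal_bodies,
    merge_axoneme,
    segment_cilia,
    segment_nuclei,
)
from cilioscope.detect import NucleusSet, _longest_geodesic
from cilioscope.synth import _paint_disk, _paint_ellipse, _paint_gaussian

PX = 0.1


def _nucleus_field(paint):
    plane = np.zeros((256, 256))
    paint(plane)
    return FieldImage({"nucleus": plane}, pixel_size_um=PX)


class TestSegmentNuclei:
    def test_counts_separated_nuclei_exactly(self, clean_field):
        img, truth = clean_field
        assert segment_nuclei(img).count == truth.n_nuclei

    def test_blank_plane_counts_zero(self):
        field = _nucleus_field(lambda p: None)
        ns = segment_nuclei(field)
        assert ns.count == 0
        assert ns.label_raster.max() == 0

    def test_size_filter_keeps_nucleus_drops_speck(self):
        # a 60 µm² ellipse counts; a 10 µm² speck does not
        big = _nucleus_field(
            lambda p: _paint_ellipse(p, np.array([128.0, 128.0]), 50, 38, 0.3, 0.8)
        )
        assert segment_nuclei(big).count == 1
        speck = _nucleus_field(
            lambda p: _paint_disk(p, np.array([128.0, 128.0]), 17.8, 0.8)
        )
        assert segment_nuclei(speck).count == 0

    def test_labels_are_contiguous(self, clean_field):
        img, _ = clean_field
        ns = segment_nuclei(img)
        labels = np.unique(ns.label_raster)
        np.testing.assert_array_equal(labels, np.arange(ns.count + 1))

    def test_missing_plane_raises(self):
        field = FieldImage({"axoneme": np.zeros((16, 16))}, PX)
        with pytest.raises(KeyError, match="nucleus"):
            segment_nuclei(field)


def _segment_planes(gap_channel=None):
    """One horizontal 40-px tube; optionally a 10-px gap in one channel,
    covered by the other (the complementary-staining situation)."""
    a = np.zeros((64, 64))
    m = np.zeros((64, 64))
    cols = np.arange(12, 52)
    for c in cols:
        in_gap = 28 <= c < 38
        if not (gap_channel == "axoneme" and in_gap):
            a[30:33, c] = 0.8
        if not (gap_channel == "membrane" and in_gap):
            m[30:33, c] = 0.8
    return a, m


class TestMergeAxoneme:
    def test_blank_membrane_yields_normalized_axoneme(self):
        a, _ = _segment_planes()
        field = FieldImage({"axoneme": a, "membrane": np.zeros_like(a),
                            "nucleus": np.zeros_like(a)}, PX)
        merged = merge_axoneme(field)
        assert merged.max() == pytest.approx(1.0)
        np.testing.assert_array_equal(merged > 0.5, a > 0.5)

    def test_commutative(self, mixed_field):
        img, _ = mixed_field
        merged = merge_axoneme(img)
        swapped = FieldImage(
            {"nucleus": img.plane("nucleus"),
             "axoneme": img.plane("membrane"),
             "membrane": img.plane("axoneme")}, PX)
        np.testing.assert_array_equal(merged, merge_axoneme(swapped))

    @pytest.mark.parametrize("gap_channel", ["axoneme", "membrane"])
    def test_gap_in_one_channel_is_bridged(self, gap_channel):
        a, m = _segment_planes(gap_channel)
        field = FieldImage({"axoneme": a, "membrane": m,
                            "nucleus": np.zeros_like(a)}, PX)
        merged = merge_axoneme(field)
        cands = segment_cilia(merged, PX)
        assert len(cands) == 1  # no fragmentation
        # single gapped channel alone fragments into two pieces
        gapped = a if gap_channel == "axoneme" else m
        alone = segment_cilia(gapped / gapped.max(), PX)
        assert len(alone) == 2


class TestSegmentCilia:
    def test_recovers_painted_count(self, clean_field):
        img, truth = clean_field
        cands = segment_cilia(merge_axoneme(img), PX)
        assert len(cands) == len(truth.of_class("cilium"))

    def test_blank_raster_yields_nothing(self):
        assert segment_cilia(np.zeros((64, 64)), PX) == []

    def test_tiny_component_filtered(self):
        raster = np.zeros((64, 64))
        raster[30, 30:32] = 1.0  # 2 px = 0.02 µm² < 0.15 µm²
        assert segment_cilia(raster, PX) == []

    def test_border_touching_component_discarded(self):
        raster = np.zeros((64, 64))
        raster[0:10, 30:33] = 1.0
        assert segment_cilia(raster, PX) == []

    def test_nonfinite_input_rejected(self):
        raster = np.zeros((16, 16))
        raster[5, 5] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            segment_cilia(raster, PX)


class TestLongestGeodesic:
    def test_straight_line(self):
        skel = np.zeros((20, 50), dtype=bool)
        skel[10, 5:43] = True  # 38 px → 37 unit steps
        _, length = _longest_geodesic(skel, spur_px=3)
        assert length == pytest.approx(37.0)

    def test_diagonal_line(self):
        skel = np.zeros((20, 20), dtype=bool)
        for i in range(11):
            skel[4 + i, 4 + i] = True
        _, length = _longest_geodesic(skel, spur_px=0)
        assert length == pytest.approx(10 * np.sqrt(2))

    def test_short_spur_is_pruned(self):
        skel = np.zeros((20, 50), dtype=bool)
        skel[10, 5:43] = True
        skel[11, 20] = skel[12, 20] = True  # 2-px spur off the shaft
        _, length = _longest_geodesic(skel, spur_px=3)
        assert length == pytest.approx(37.0)


class TestDetectBasalBodies:
    def test_recovers_painted_puncta_within_one_pixel(self, clean_field):
        img, truth = clean_field
        centers = detect_basal_bodies(img)
        bases = np.array([c.base_px for c in truth.of_class("cilium")])
        assert len(centers) == len(bases)
        for b in bases:
            assert np.min(np.linalg.norm(centers - b, axis=1)) <= 1.0

    def test_blank_plane_yields_empty(self):
        field = FieldImage({"basal_body": np.zeros((64, 64))}, PX)
        assert len(detect_basal_bodies(field)) == 0

    def test_two_close_puncta_resolved(self):
        plane = np.zeros((64, 64))
        _paint_gaussian(plane, np.array([30.0, 25.0]), 1.2, 0.9)
        _paint_gaussian(plane, np.array([30.0, 35.0]), 1.2, 0.9)
        field = FieldImage({"basal_body": plane}, PX)
        assert len(detect_basal_bodies(field)) == 2

    def test_missing_plane_yields_empty(self):
        field = FieldImage({"nucleus": np.zeros((16, 16))}, PX)
        assert detect_basal_bodies(field).shape == (0, 2)


class TestAssignment:
    def test_one_to_one_on_clean_field(self, clean_field):
        img, truth = clean_field
        nuclei = segment_nuclei(img)
        cands = segment_cilia(merge_axoneme(img), PX)
        bbs = detect_basal_bodies(img)
        assignment = assign_cilia_to_cells(cands, nuclei, bbs, PX)
        assigned = [v for v in assignment.nucleus_candidate.values()
                    if v is not None]
        assert len(assigned) == truth.n_nuclei
        assert sorted(assigned) == sorted(c.cilium_id for c in cands)

    def test_no_candidates_gives_all_none(self, clean_field):
        img, _ = clean_field
        nuclei = segment_nuclei(img)
        assignment = assign_cilia_to_cells([], nuclei, np.empty((0, 2)), PX)
        assert all(v is None for v in assignment.nucleus_candidate.values())

    def test_contested_nucleus_goes_to_larger_candidate(self):
        # one nucleus, two nearby candidates of areas 2.0 vs 0.5 µm²
        big = np.zeros((128, 128))
        big[60:64, 40:90] = 1.0  # 200 px = 2.0 µm²
        small = np.zeros((128, 128))
        small[70:72, 40:65] = 1.0  # 50 px = 0.5 µm²
        cands = segment_cilia(np.maximum(big, small), PX)
        assert len(cands) == 2
        label = np.zeros((128, 128), dtype=np.int32)
        label[40:56, 20:40] = 1
        nuclei = NucleusSet(label, 1)
        assignment = assign_cilia_to_cells(cands, nuclei, np.empty((0, 2)), PX)
        winner = assignment.nucleus_candidate[1]
        areas = {c.cilium_id: c.area_um2 for c in cands}
        assert areas[winner] == max(areas.values())
        losers = [cid for cid, lab in assignment.candidate_nucleus.items()
                  if lab is None]
        assert len(losers) == 1
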