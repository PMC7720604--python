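import json

import pytest
from hypothesis import given, settings, strategies as st

from bloompheno.detections import (
    BBox,
    Detection,
    ImageDetections,
    AmbiguousViewError,
    DetectionParseError,
    TaxonomyError,
    centroid,
    filter_by_confidence,
    group_scans,
    read_detections,
    read_detections_coco,
    read_detections_csv,
    write_detections_coco,
    write_detections_csv,
)


def det(conf, label="emerging_bloom", box=(0, 0, 10, 10)):
    return Detection(BBox(*box), label, conf)


class TestBBox:
    def test_centroid(self):
        assert centroid(BBox(0, 0, 10, 10)) == (5, 5)
        assert centroid(BBox(2, 4, 6, 8)) == (4, 6)

    def test_corner_order_normalized(self):
        assert BBox.from_corners(30, 40, 10, 20) == BBox(10, 20, 30, 40)
        assert centroid(BBox.from_corners(30, 40, 10, 20)) == centroid(
            BBox.from_corners(10, 20, 30, 40)
        )

    @pytest.mark.parametrize("coords", [(10, 0, 5, 10), (0, 0, 10, 0), (-1, 0, 5, 5),
                                        (0, float("nan"), 5, 5)])
    def test_invalid_boxes_rejected(self, coords):
        with pytest.raises(ValueError):
            BBox(*coords)

    def test_containment_is_boundary_inclusive(self):
        b = BBox(0, 0, 100, 100)
        assert b.contains(100, 50) and b.contains(0, 0)
        assert not b.contains(100.001, 50)


class TestTaxonomy:
    def test_unknown_label_rejected(self):
        with pytest.raises(TaxonomyError):
            det(0.9, label="flower")

    def test_three_class_reduction_is_surjective_and_lossless(self):
        five = [det(0.9, "target_plant"), det(0.8), det(0.7, "opened_boll"),
                det(0.6, "specular_region"), det(0.5, "other")]
        three = [d.to_three_class() for d in five]
        assert len(three) == len(five)
        assert [d.label for d in three] == [
            "target_plant", "emerging_bloom", "non_bloom", "non_bloom", "non_bloom"
        ]
        # plant and bloom records untouched, including geometry and score
        assert three[0] == five[0].to_three_class()
        assert three[1].bbox == five[1].bbox and three[1].confidence == five[1].confidence


class TestConfidenceFilter:
    def test_boundary_kept(self):
        dets = [det(0.69), det(0.70), det(0.95)]
        kept = filter_by_confidence(dets, 0.7)
        assert [d.confidence for d in kept] == [0.70, 0.95]

    def test_vacuous_and_total_filters(self):
        dets = [det(0.3), det(0.6)]
        assert filter_by_confidence(dets, 0.0) == dets
        assert filter_by_confidence(dets, 1.0) == []

    @given(st.lists(st.floats(0, 1), max_size=20), st.floats(0, 1), st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_idempotent(self, confs, t1, t2):
        dets = [det(c) for c in confs]
        lo, hi = sorted([t1, t2])
        kept_lo = filter_by_confidence(dets, lo)
        kept_hi = filter_by_confidence(dets, hi)
        assert set(id(d) for d in kept_hi) <= set(id(d) for d in kept_lo)
        assert filter_by_confidence(kept_lo, lo) == kept_lo


class TestGrouping:
    def test_four_views_grouped(self):
        imgs = [ImageDetections("A", 70, v) for v in range(4)]
        scans = group_scans(imgs)
        assert len(scans) == 1 and len(scans[0].views) == 4

    def test_missing_view_tolerated_and_logged(self, caplog):
        imgs = [ImageDetections("A", 70, v) for v in range(3)]
        with caplog.at_level("WARNING"):
            scans = group_scans(imgs)
        assert len(scans[0].views) == 3
        assert any("3 view" in r.message for r in caplog.records)

    def test_duplicate_view_rejected(self):
        imgs = [ImageDetections("A", 70, 2), ImageDetections("A", 70, 2)]
        with pytest.raises(AmbiguousViewError):
            group_scans(imgs)


class TestIO:
    def test_coco_xywh_dialect(self, tmp_path):
        doc = {
            "images": [{"id": 1, "plant_id": "A", "date_or_dap": 70, "view_index": 0}],
            "categories": [{"id": 5, "name": "emerging_bloom"}],
            "annotations": [
                {"image_id": 1, "category_id": 5, "bbox": [10, 20, 30, 40], "score": 0.9}
            ],
        }
        p = tmp_path / "d.json"
        p.write_text(json.dumps(doc))
        (img,) = read_detections(p, "coco_json")
        (d,) = img.detections
        assert d.bbox == BBox(10, 20, 40, 60)
        assert d.confidence == 0.9

    def test_empty_image_preserved(self, tmp_path):
        imgs = [ImageDetections("A", 70, 0)]
        p = tmp_path / "d.csv"
        write_detections_csv(imgs, p)
        (back,) = read_detections_csv(p)
        assert back.plant_id == "A" and back.detections == []

    def test_csv_unknown_category_raises(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "plant_id,date_or_dap,view_index,label,confidence,xmin,ymin,xmax,ymax\n"
            "A,70,0,flower,0.9,0,0,10,10\n"
        )
        with pytest.raises(TaxonomyError):
            read_detections_csv(p)

    def test_malformed_row_names_record(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "plant_id,date_or_dap,view_index,label,confidence,xmin,ymin,xmax,ymax\n"
            "A,not-a-date,0,emerging_bloom,0.9,0,0,10,10\n"
        )
        with pytest.raises(DetectionParseError, match=":2"):
            read_detections_csv(p)

    def test_calendar_dates_converted_to_dap(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text(
            "plant_id,date_or_dap,view_index,label,confidence,xmin,ymin,xmax,ymax\n"
            "A,2018-08-20,0,emerging_bloom,0.9,0,0,10,10\n"
        )
        (img,) = read_detections_csv(p)
        assert img.dap == 68  # planting 13 June 2018

    def test_csv_roundtrip_exact(self, tmp_path, small_noisy_ds):
        imgs = small_noisy_ds.images[:200]
        p = tmp_path / "d.csv"
        write_detections_csv(imgs, p)
        back = read_detections_csv(p)
        flat = lambda ims: [
            (i.plant_id, i.dap, i.view_index, d.label, d.confidence,
             d.bbox.xmin, d.bbox.ymin, d.bbox.xmax, d.bbox.ymax)
            for i in ims for d in i.detections
        ]
        assert sorted(flat(back)) == sorted(flat(imgs))

    def test_coco_roundtrip_exact(self, tmp_path, small_noisy_ds):
        imgs = small_noisy_ds.images[:100]
        p = tmp_path / "d.json"
        write_detections_coco(imgs, p)
        back = read_detections_coco(p)
        flat = lambda ims: [
            (i.plant_id, i.dap, i.view_index, d.label, round(d.confidence, 12),
             round(d.bbox.xmin, 9), round(d.bbox.ymax, 9))
            for i in ims for d in i.detections
        ]
        assert sorted(flat(back)) == sorted(flat(imgs))
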