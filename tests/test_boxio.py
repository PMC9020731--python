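import numpy as np
import pytest

from wormbox.boxio import (
    Box,
    CalibrationConfig,
    DetectionRecord,
    FrameRecord,
    filter_confidence,
    read_detections,
    read_voc,
    write_detections_coco,
    write_detections_csv,
    write_voc,
)

from conftest import random_box


class TestBox:
    def test_area_and_center(self):
        b = Box(2, 4, 6, 12)
        assert b.area == 32
        assert b.center == (4, 8)

    @pytest.mark.parametrize("coords", [(5, 0, 5, 10), (0, 0, -1, 10), (0, 3, 10, 3)])
    def test_degenerate_boxes_rejected(self, coords):
        with pytest.raises(ValueError):
            Box(*coords)

    def test_detection_confidence_validated(self):
        with pytest.raises(ValueError):
            DetectionRecord(Box(0, 0, 1, 1), "worm", 1.2)
        with pytest.raises(ValueError):
            DetectionRecord(Box(0, 0, 1, 1), "", 0.5)


class TestVoc:
    def test_inclusive_pixel_convention(self, tmp_path):
        """VOC object xmin=1..xmax=10 spans 10 pixels -> continuous [0, 10]."""
        fr = FrameRecord("img0", image_size=(100, 80),
                         ground_truth=[(Box(0, 0, 10, 10), "worm")])
        p = tmp_path / "a.xml"
        write_voc(fr, p)
        back = read_voc(p)
        box, label = back.ground_truth[0]
        assert (box.x_min, box.x_max) == (0, 10)
        assert box.width == 10
        assert label == "worm"

    def test_empty_annotation_file(self, tmp_path):
        p = tmp_path / "empty.xml"
        write_voc(FrameRecord("img1", image_size=(10, 10)), p)
        assert read_voc(p).ground_truth == []

    def test_malformed_xml_names_file(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<annotation><object>")
        with pytest.raises(ValueError, match="bad.xml"):
            read_voc(p)

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "inv.xml"
        p.write_text(
            "<annotation><filename>x</filename><object><name>worm</name>"
            "<bndbox><xmin>10</xmin><ymin>1</ymin><xmax>5</xmax><ymax>9</ymax>"
            "</bndbox></object></annotation>"
        )
        with pytest.raises(ValueError):
            read_voc(p)

    def test_roundtrip_exact_on_random_fixtures(self, tmp_path, rng):
        """write_voc . read_voc reproduces integer coordinates exactly."""
        for i in range(100):
            coords = np.sort(rng.integers(1, 500, size=4).astype(float))
            boxes = [(Box(coords[0], coords[1], coords[2] + 1, coords[3] + 2), "worm"),
                     (random_box(rng), "egg")]
            # snap the second box to integers for the integer-exactness claim
            b2 = boxes[1][0]
            boxes[1] = (Box(*np.floor([b2.x_min, b2.y_min]), *np.ceil([b2.x_max, b2.y_max])), "egg")
            fr = FrameRecord(f"img{i}", image_size=(600, 600), ground_truth=boxes)
            p = tmp_path / f"{i}.xml"
            write_voc(fr, p)
            back = read_voc(p)
            assert back.frame_id == fr.frame_id
            for (ba, la), (bb, lb) in zip(fr.ground_truth, back.ground_truth):
                assert la == lb
                assert (ba.x_min, ba.y_min, ba.x_max, ba.y_max) == (
                    bb.x_min, bb.y_min, bb.x_max, bb.y_max)


class TestDetectionIO:
    def _frames(self, rng, n=20):
        frames = []
        for i in range(n):
            dets = [
                DetectionRecord(random_box(rng), lbl, float(rng.random()))
                for lbl in rng.choice(["worm", "egg"], size=rng.integers(0, 5))
            ]
            frames.append(FrameRecord(f"fr{i:03d}", image_size=(200, 200), detections=dets))
        return frames

    def test_csv_roundtrip_lossless(self, tmp_path, rng):
        frames = self._frames(rng)
        p = tmp_path / "det.csv"
        write_detections_csv(frames, p)
        back = {fr.frame_id: fr for fr in read_detections(p, "csv")}
        assert set(back) == {fr.frame_id for fr in frames}
        for fr in frames:
            got = back[fr.frame_id].detections
            assert len(got) == len(fr.detections)
            for d0, d1 in zip(fr.detections, got):
                assert d0.label == d1.label
                assert d0.confidence == d1.confidence
                assert d0.box == d1.box

    def test_coco_roundtrip_lossless(self, tmp_path, rng):
        frames = self._frames(rng)
        p = tmp_path / "det.json"
        write_detections_coco(frames, p)
        back = read_detections(p, "coco_json")
        for fr0, fr1 in zip(frames, back):
            assert fr0.frame_id == fr1.frame_id
            for d0, d1 in zip(fr0.detections, fr1.detections):
                assert d0.label == d1.label
                assert d0.confidence == d1.confidence
                assert d0.box.x_max == pytest.approx(d1.box.x_max, abs=1e-12)

    def test_coco_bbox_convention(self, tmp_path):
        """COCO [x, y, w, h] = [5, 5, 10, 20] becomes the box (5, 5, 15, 25)."""
        import json
        doc = {
            "images": [{"id": 1, "file_name": "a", "width": 50, "height": 50}],
            "annotations": [
                {"id": 1, "image_id": 1, "category_id": 1, "bbox": [5, 5, 10, 20], "score": 0.9}
            ],
            "categories": [{"id": 1, "name": "worm"}],
        }
        p = tmp_path / "c.json"
        p.write_text(json.dumps(doc))
        (fr,) = read_detections(p, "coco_json")
        assert fr.detections[0].box == Box(5, 5, 15, 25)

    def test_coco_unknown_category_and_negative_extent(self, tmp_path):
        import json
        base = {
            "images": [{"id": 1, "file_name": "a"}],
            "categories": [{"id": 1, "name": "worm"}],
        }
        p = tmp_path / "c.json"
        bad_cat = dict(base, annotations=[
            {"id": 1, "image_id": 1, "category_id": 9, "bbox": [0, 0, 5, 5], "score": 0.5}])
        p.write_text(json.dumps(bad_cat))
        with pytest.raises(ValueError):
            read_detections(p, "coco_json")
        bad_wh = dict(base, annotations=[
            {"id": 1, "image_id": 1, "category_id": 1, "bbox": [0, 0, -5, 5], "score": 0.5}])
        p.write_text(json.dumps(bad_wh))
        with pytest.raises(ValueError):
            read_detections(p, "coco_json")

    def test_csv_confidence_out_of_range(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("frame_id,label,confidence,x_min,y_min,x_max,y_max\n"
                     "f0,worm,1.2,0,0,5,5\n")
        with pytest.raises(ValueError):
            read_detections(p, "csv")

    def test_empty_frames_preserved(self, tmp_path):
        frames = [FrameRecord("f0"), FrameRecord("f1")]
        p = tmp_path / "d.csv"
        write_detections_csv(frames, p)
        back = read_detections(p, "csv")
        assert [fr.frame_id for fr in back] == ["f0", "f1"]
        assert all(not fr.detections for fr in back)


class TestFilterConfidence:
    def _frame(self, confs, label="egg"):
        dets = [DetectionRecord(Box(0, 0, 5, 5), label, c) for c in confs]
        return FrameRecord("f0", detections=dets)

    def test_counting_example(self):
        out = filter_confidence([self._frame([0.005, 0.02, 0.7])], "egg", 0.01)
        assert len(out[0].detections) == 2

    def test_inclusive_at_threshold_and_other_labels_untouched(self):
        fr = FrameRecord("f0", detections=[
            DetectionRecord(Box(0, 0, 5, 5), "egg", 0.5),
            DetectionRecord(Box(0, 0, 5, 5), "worm", 0.1),
        ])
        out = filter_confidence([fr], "egg", 0.5)
        assert [d.label for d in out[0].detections] == ["egg", "worm"]

    def test_idempotent_and_monotone(self, rng):
        frames = [self._frame(rng.random(20).tolist()) for _ in range(5)]
        once = filter_confidence(frames, "egg", 0.5)
        twice = filter_confidence(once, "egg", 0.5)
        assert sum(len(f.detections) for f in once) == sum(len(f.detections) for f in twice)
        counts = [
            sum(len(f.detections) for f in filter_confidence(frames, "egg", thr))
            for thr in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_zero_is_identity(self):
        frames = [self._frame([0.0, 0.3, 1.0])]
        out = filter_confidence(frames, "egg", 0.0)
        assert len(out[0].detections) == 3


def test_calibration_yaml_roundtrip_and_validation(tmp_path):
    cal = CalibrationConfig(mm_per_pixel=0.0106, frame_interval=1.0)
    p = tmp_path / "cal.yaml"
    cal.to_yaml(p)
    assert CalibrationConfig.from_yaml(p) == cal
    with pytest.raises(ValueError):
        CalibrationConfig(mm_per_pixel=0, frame_interval=1)
    p.write_text("mm_per_pixel: 0.01\nframe_interval: 1\nbogus: 2\n")
    with pytest.raises(ValueError, match="bogus"):
        CalibrationConfig.from_yaml(p)
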