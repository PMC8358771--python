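"""Annotation I/O and the resize/pad/tile preprocessing chain."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stomakit.annotation_io import (AnnotationSet, BoundingBox, ImageRecord,
                                    TilingSpec, pad_to,
                                    prepare_training_tiles, read_coco,
                                    read_coco_results, read_labelbox,
                                    resize_with_boxes, split_tiles,
                                    write_coco, write_coco_results)


def make_set(boxes_per_image, width=1024, height=768):
    aset = AnnotationSet()
    for i, boxes in enumerate(boxes_per_image):
        aset.add_image(ImageRecord(id=f"img{i}", width_px=width,
                                   height_px=height), boxes)
    return aset


class TestBoundingBox:
    def test_rejects_degenerate_and_negative(self):
        with pytest.raises(ValueError):
            BoundingBox(10, 10, 10, 20)
        with pytest.raises(ValueError):
            BoundingBox(-1, 0, 5, 5)
        with pytest.raises(ValueError):
            BoundingBox(0, 0, 5, 5, score=1.5)

    def test_coco_conversion(self):
        b = BoundingBox.from_coco([10, 20, 30, 40])
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (10, 20, 40, 60)
        assert b.to_coco() == [10, 20, 30, 40]
        with pytest.raises(ValueError):
            BoundingBox.from_coco([10, 20, 0, 40])

    def test_clip_returns_none_outside_window(self):
        b = BoundingBox(10, 10, 20, 20)
        assert b.clip(30, 30, 40, 40) is None
        c = b.clip(15, 0, 40, 40)
        assert (c.xmin, c.xmax) == (15, 20)


@st.composite
def annotation_sets(draw):
    n_images = draw(st.integers(0, 3))
    sets = []
    for _ in range(n_images):
        n_boxes = draw(st.integers(0, 4))
        boxes = []
        for _ in range(n_boxes):
            x = draw(st.floats(0, 900))
            y = draw(st.floats(0, 600))
            w = draw(st.floats(1, 100))
            h = draw(st.floats(1, 100))
            boxes.append(BoundingBox(x, y, min(x + w, 1024.0),
                                     min(y + h, 768.0)))
        sets.append(boxes)
    return make_set(sets)


class TestCocoRoundTrip:
    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(annotation_sets())
    def test_write_read_is_identity(self, tmp_path_factory, aset):
        path = tmp_path_factory.mktemp("coco") / "gt.json"
        write_coco(aset, path)
        back = read_coco(path)
        assert list(back.images) == list(aset.images)
        for iid in aset.images:
            assert back.images[iid].width_px == aset.images[iid].width_px
            a = [(b.xmin, b.ymin, b.xmax, b.ymax) for b in aset.boxes(iid)]
            b = [(b.xmin, b.ymin, b.xmax, b.ymax) for b in back.boxes(iid)]
            assert a == pytest.approx(b)

    def test_empty_annotation_list_is_valid(self, tmp_path):
        aset = make_set([[]])
        write_coco(aset, tmp_path / "gt.json")
        back = read_coco(tmp_path / "gt.json")
        assert back.n_boxes == 0 and len(back.images) == 1

    def test_malformed_and_missing_keys_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_coco(p)
        p.write_text(json.dumps({"images": []}))
        with pytest.raises(ValueError, match="missing required key"):
            read_coco(p)

    def test_nonpositive_box_rejected_with_image_id(self, tmp_path):
        payload = {
            "images": [{"id": 1, "file_name": "imgA.png", "width": 100,
                        "height": 100}],
            "annotations": [{"id": 1, "image_id": 1, "category_id": 1,
                             "bbox": [5, 5, -3, 10], "area": 0,
                             "iscrowd": 0}],
            "categories": [{"id": 1, "name": "stoma"}],
        }
        p = tmp_path / "neg.json"
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="imgA"):
            read_coco(p)

    def test_results_round_trip_preserves_scores(self, tmp_path):
        dets = {"imgA": [BoundingBox(1, 2, 11, 22, score=0.9),
                         BoundingBox(5, 5, 25, 45, score=0.4)]}
        p = tmp_path / "res.json"
        write_coco_results(dets, p)
        back = read_coco_results(p)
        assert [b.score for b in back["imgA"]] == pytest.approx([0.9, 0.4])
        assert back["imgA"][0].to_coco() == pytest.approx([1, 2, 10, 20])


class TestLabelbox:
    def _write(self, tmp_path, records):
        p = tmp_path / "lb.json"
        p.write_text(json.dumps(records))
        return p

    def test_convention_mapping(self, tmp_path):
        rec = [{"external_id": "a",
                "media_attributes": {"width": 3072, "height": 2048},
                "objects": [{"title": "stoma",
                             "bbox": {"top": 20, "left": 10,
                                      "height": 40, "width": 30}}]}]
        aset = read_labelbox(self._write(tmp_path, rec))
        b = aset.boxes("a")[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (10, 20, 40, 60)

    def test_count_conservation_and_empty_record(self, tmp_path):
        def obj(left):
            return {"bbox": {"top": 10, "left": left, "height": 20,
                             "width": 20}}

        rec = [
            {"external_id": "a",
             "media_attributes": {"width": 1024, "height": 768},
             "objects": [obj(0), obj(50), obj(100)]},
            {"external_id": "b",
             "media_attributes": {"width": 1024, "height": 768},
             "objects": [obj(0), obj(50)]},
            {"external_id": "c",
             "media_attributes": {"width": 1024, "height": 768},
             "objects": []},
        ]
        aset = read_labelbox(self._write(tmp_path, rec))
        assert aset.n_boxes == 5
        assert "c" in aset.images and aset.boxes("c") == []

    def test_unknown_geometry_skipped_missing_dims_error(self, tmp_path,
                                                         caplog):
        rec = [{"external_id": "a",
                "media_attributes": {"width": 100, "height": 100},
                "objects": [{"polygon": [[0, 0], [1, 1]]}]}]
        with caplog.at_level("WARNING"):
            aset = read_labelbox(self._write(tmp_path, rec))
        assert aset.n_boxes == 0 and "unknown geometry" in caplog.text
        rec = [{"external_id": "a", "objects": []}]
        with pytest.raises(ValueError, match="dimensions"):
            read_labelbox(self._write(tmp_path, rec))


class TestResizePadSplit:
    def test_halving_full_resolution_micrograph(self):
        img = ImageRecord(id="x", width_px=3072, height_px=2048)
        out, _ = resize_with_boxes(img, [], 0.5)
        assert (out.width_px, out.height_px) == (1536, 1024)

    def test_box_rescale_and_identity(self):
        img = ImageRecord(id="x", width_px=400, height_px=300)
        box = BoundingBox(100, 100, 150, 130)
        _, [b] = resize_with_boxes(img, [box], 0.5)
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (50, 50, 75, 65)
        _, [b1] = resize_with_boxes(img, [box], 1.0)
        assert b1 == box

    def test_resize_inverse_recovers_boxes(self, rng):
        img = ImageRecord(id="x", width_px=1000, height_px=800)
        boxes = []
        for _ in range(10):
            x, y = rng.uniform(0, 900), rng.uniform(0, 700)
            boxes.append(BoundingBox(x, y, x + rng.uniform(5, 90),
                                     y + rng.uniform(5, 60)))
        small, sboxes = resize_with_boxes(img, boxes, 0.37)
        _, back = resize_with_boxes(small, sboxes, 1 / 0.37)
        for b0, b1 in zip(boxes, back):
            assert abs(b0.xmin - b1.xmin) < 1 and abs(b0.ymax - b1.ymax) < 1

    def test_resize_to_zero_errors(self):
        img = ImageRecord(id="x", width_px=10, height_px=10)
        with pytest.raises(ValueError):
            resize_with_boxes(img, [], 0.01)

    def test_pad_appends_black_right_and_bottom(self):
        px = np.full((3, 4), 7, dtype=np.uint8)
        img = ImageRecord(id="x", width_px=4, height_px=3, pixels=px)
        box = BoundingBox(1, 1, 3, 2)
        out, [b] = pad_to(img, [box], 6, 5)
        assert (out.width_px, out.height_px) == (6, 5)
        assert out.pixels[:3, :4].min() == 7
        assert out.pixels[3:, :].max() == 0 and out.pixels[:, 4:].max() == 0
        assert b == box  # origin fixed -> coordinates unchanged

    def test_pad_identity_and_error(self):
        img = ImageRecord(id="x", width_px=4, height_px=3)
        out, _ = pad_to(img, [], 4, 3)
        assert (out.width_px, out.height_px) == (4, 3)
        with pytest.raises(ValueError):
            pad_to(img, [], 2, 3)

    def test_split_two_tiles_with_offset_remap(self):
        img = ImageRecord(id="p", width_px=2048, height_px=1024)
        box = BoundingBox(1050, 250, 1100, 280)
        tiles = split_tiles(img, [box], TilingSpec())
        assert len(tiles) == 2
        assert [t.id for t, _ in tiles] == ["p_t0", "p_t1"]
        assert tiles[0][1] == []
        [b] = tiles[1][1]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (26, 250, 76, 280)

    def test_seam_box_retention_rule(self):
        # box (1000,100,1050,140): 48% of area in tile 1 (dropped at the
        # 50% threshold), 52% in tile 2 (kept)
        img = ImageRecord(id="p", width_px=2048, height_px=1024)
        box = BoundingBox(1000, 100, 1050, 140)
        tiles = split_tiles(img, [box], TilingSpec())
        assert tiles[0][1] == []
        [b] = tiles[1][1]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (0, 100, 26, 140)

    def test_split_indivisible_errors(self):
        img = ImageRecord(id="p", width_px=2000, height_px=1024)
        with pytest.raises(ValueError, match="pad_to"):
            split_tiles(img, [], TilingSpec())

    def test_tile_local_coordinates_in_bounds(self, rng):
        img = ImageRecord(id="p", width_px=2048, height_px=1024)
        boxes = []
        for _ in range(50):
            x = rng.uniform(0, 2000)
            y = rng.uniform(0, 980)
            boxes.append(BoundingBox(x, y, min(x + rng.uniform(5, 90), 2048),
                                     min(y + rng.uniform(5, 60), 1024)))
        spec = TilingSpec(min_box_retention_fraction=0.3)
        total_in = sum(b.area for b in boxes)
        total_out = 0.0
        for tile, tboxes in split_tiles(img, boxes, spec):
            for b in tboxes:
                assert 0 <= b.xmin < b.xmax <= tile.width_px
                assert 0 <= b.ymin < b.ymax <= tile.height_px
                total_out += b.area
        assert total_out <= total_in + 1e-9  # clipping only removes area


class TestPrepareTrainingTiles:
    def test_tile_count_doubles_images(self):
        aset = make_set([[] for _ in range(5)], width=3072, height=2048)
        out = prepare_training_tiles(aset)
        assert len(out.images) == 10
        assert all("_t" in iid for iid in out.images)

    def test_box_survives_full_chain(self):
        box = BoundingBox(2100, 500, 2200, 600)  # -> (1050..1100, 250..300)
        aset = make_set([[box]], width=3072, height=2048)
        out = prepare_training_tiles(aset)
        boxes = [b for iid in out.images for b in out.boxes(iid)]
        assert len(boxes) == 1
        b = boxes[0]
        assert (b.xmin, b.ymin, b.xmax, b.ymax) == (26, 250, 76, 300)
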