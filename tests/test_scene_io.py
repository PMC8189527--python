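import json

import numpy as np
import pandas as pd
import pytest

from ogd._errors import SchemaError, ValidationError
from ogd.core import compute_ogd_series
from ogd.io import (
    Fixation,
    FrameSegmentation,
    read_coco_segmentations,
    read_fixations,
    read_label_png_masks,
    read_ogd_series,
    write_coco_segmentations,
    write_label_png_masks,
    write_ogd_series,
)
from tests.conftest import make_scene


def write_csv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


class TestFixationTable:
    COLUMNS = ["fixation_id", "start_s", "duration_s", "gaze_x", "gaze_y"]
    ROWS = [
        (0, 0.0, 0.2, 10.0, 20.0),
        (1, 0.3, 0.1, 30.0, 40.0),
        (2, 0.5, 0.2, 50.0, 60.0),
        (3, 0.8, 0.4, 70.0, 80.0),
    ]

    def test_well_formed_read(self, tmp_path):
        p = tmp_path / "fix.csv"
        write_csv(p, self.ROWS, self.COLUMNS)
        fixations = read_fixations(p)
        assert [f.fixation_id for f in fixations] == [0, 1, 2, 3]
        assert fixations[2].gaze_x == 50.0

    def test_column_order_independent(self, tmp_path):
        shuffled = ["gaze_y", "fixation_id", "duration_s", "gaze_x", "start_s"]
        p = tmp_path / "fix.csv"
        df = pd.DataFrame(self.ROWS, columns=self.COLUMNS)[shuffled]
        df.to_csv(p, index=False)
        assert read_fixations(p) == read_fixations_reference(tmp_path, self.ROWS)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "fix.csv"
        write_csv(p, [r[:-1] for r in self.ROWS], self.COLUMNS[:-1])
        with pytest.raises(SchemaError, match="gaze_y"):
            read_fixations(p)

    def test_unsorted_input_sorted_with_warning(self, tmp_path):
        p = tmp_path / "fix.csv"
        write_csv(p, [self.ROWS[1], self.ROWS[0]], self.COLUMNS)
        with pytest.warns(UserWarning, match="sorted"):
            fixations = read_fixations(p)
        assert [f.fixation_id for f in fixations] == [0, 1]

    def test_overlap_is_hard_error_naming_ids(self, tmp_path):
        rows = list(self.ROWS)
        rows[2] = (2, 0.35, 0.2, 50.0, 60.0)  # starts inside fixation 1
        p = tmp_path / "fix.csv"
        write_csv(p, rows, self.COLUMNS)
        with pytest.raises(ValidationError, match="1 and 2"):
            read_fixations(p)

    def test_nonpositive_duration_rejected(self, tmp_path):
        p = tmp_path / "fix.csv"
        write_csv(p, [(0, 0.0, 0.0, 1.0, 1.0)], self.COLUMNS)
        with pytest.raises(ValidationError, match="duration"):
            read_fixations(p)


def read_fixations_reference(tmp_path, rows):
    p = tmp_path / "ref.csv"
    write_csv(p, rows, TestFixationTable.COLUMNS)
    return read_fixations(p)


class TestLabelPng:
    def make_frames(self, tmp_path, arrays, labelmap):
        from PIL import Image

        d = tmp_path / "masks"
        d.mkdir()
        for i, arr in enumerate(arrays):
            Image.fromarray(arr.astype(np.uint8), mode="L").save(d / f"{i:05d}.png")
        lm = tmp_path / "labelmap.json"
        lm.write_text(json.dumps({str(k): v for k, v in labelmap.items()}))
        return d, lm

    def test_background_only_frame_has_empty_map(self, tmp_path):
        d, lm = self.make_frames(tmp_path, [np.zeros((8, 10))], {1: "screw"})
        frames = read_label_png_masks(d, lm)
        assert frames[0].masks == {}

    def test_two_labels_become_two_masks(self, tmp_path):
        arr = np.zeros((8, 10))
        arr[1:3, 1:4] = 1
        arr[5:7, 6:9] = 2
        d, lm = self.make_frames(tmp_path, [arr], {1: "screw", 2: "screwdriver"})
        frames = read_label_png_masks(d, lm)
        assert set(frames[0].masks) == {"screw", "screwdriver"}
        assert frames[0].masks["screw"][0].sum() == 6
        assert frames[0].masks["screwdriver"][0].sum() == 6

    def test_unknown_pixel_value_is_error(self, tmp_path):
        arr = np.zeros((8, 10))
        arr[0, 0] = 7
        d, lm = self.make_frames(tmp_path, [arr], {1: "screw"})
        with pytest.raises(SchemaError, match="7"):
            read_label_png_masks(d, lm)

    def test_size_mismatch_with_camera(self, tmp_path, small_camera):
        d, lm = self.make_frames(tmp_path, [np.zeros((8, 10))], {1: "screw"})
        with pytest.raises(ValidationError, match="resolution"):
            read_label_png_masks(d, lm, small_camera)

    def test_roundtrip_write_read(self, tmp_path, small_camera):
        bundle, _ = make_scene(small_camera, n_fixations=5, seed=3)
        out = tmp_path / "masks"
        labelmap = write_label_png_masks(bundle.frames, out)
        frames = read_label_png_masks(out, out / "labelmap.json", small_camera)
        assert len(frames) == len(bundle.frames)
        for orig, rt in zip(bundle.frames, frames):
            assert set(orig.masks) == set(rt.masks)
            for lbl in orig.masks:
                merged = np.zeros_like(orig.masks[lbl][0])
                for m in orig.masks[lbl]:
                    merged |= m
                assert np.array_equal(merged, rt.masks[lbl][0])
        assert set(labelmap.values()) == {"screw", "screwdriver"}


class TestCoco:
    def doc(self, camera, annotations, n_frames=1, categories=None):
        return {
            "images": [
                {"id": i, "width": camera.width_px, "height": camera.height_px}
                for i in range(n_frames)
            ],
            "categories": categories
            or [{"id": 1, "name": "screw"}, {"id": 2, "name": "screwdriver"}],
            "annotations": annotations,
        }

    def write(self, tmp_path, doc):
        p = tmp_path / "ann.json"
        p.write_text(json.dumps(doc))
        return p

    def test_polygon_square_rasterizes_to_exact_area(self, tmp_path, small_camera):
        ann = [{
            "id": 1, "image_id": 0, "category_id": 1,
            "segmentation": [[0.0, 0.0, 10.0, 0.0, 10.0, 10.0, 0.0, 10.0]],
        }]
        p = self.write(tmp_path, self.doc(small_camera, ann))
        frames = read_coco_segmentations(p, small_camera)
        mask = frames[0].masks["screw"][0]
        assert mask.sum() == 100
        assert mask[:10, :10].all()

    def test_empty_annotations_give_empty_maps(self, tmp_path, small_camera):
        p = self.write(tmp_path, self.doc(small_camera, [], n_frames=3))
        frames = read_coco_segmentations(p, small_camera)
        assert len(frames) == 3
        assert all(fr.masks == {} for fr in frames)

    def test_two_same_category_polygons_become_two_instances(
        self, tmp_path, small_camera
    ):
        sq = lambda x0, y0: [[x0, y0, x0 + 5.0, y0, x0 + 5.0, y0 + 5.0, x0, y0 + 5.0]]
        ann = [
            {"id": 1, "image_id": 0, "category_id": 1, "segmentation": sq(0.0, 0.0)},
            {"id": 2, "image_id": 0, "category_id": 1, "segmentation": sq(50.0, 50.0)},
        ]
        p = self.write(tmp_path, self.doc(small_camera, ann))
        frames = read_coco_segmentations(p, small_camera)
        assert len(frames[0].masks["screw"]) == 2

    def test_uncompressed_rle_roundtrip(self, tmp_path, small_camera):
        rng = np.random.default_rng(5)
        mask = rng.random((small_camera.height_px, small_camera.width_px)) < 0.2
        fr = FrameSegmentation(frame_index=0, masks={"screw": [mask]})
        p = tmp_path / "rle.json"
        write_coco_segmentations([fr], small_camera, p)
        back = read_coco_segmentations(p, small_camera)
        assert np.array_equal(back[0].masks["screw"][0], mask)

    def test_compressed_rle_rejected_by_name(self, tmp_path, small_camera):
        ann = [{
            "id": 1, "image_id": 0, "category_id": 1,
            "segmentation": {"size": [240, 320], "counts": "abc0"},
        }]
        p = self.write(tmp_path, self.doc(small_camera, ann))
        with pytest.raises(SchemaError, match="compressed RLE"):
            read_coco_segmentations(p, small_camera)

    def test_cross_format_equivalence_on_synthetic_scene(
        self, tmp_path, small_camera
    ):
        """PNG and COCO encodings of one scene decode to identical masks."""
        bundle, _ = make_scene(small_camera, n_fixations=4, seed=9)
        png_dir = tmp_path / "png"
        write_label_png_masks(bundle.frames, png_dir)
        coco_path = tmp_path / "scene.json"
        write_coco_segmentations(bundle.frames, small_camera, coco_path)
        via_png = read_label_png_masks(png_dir, png_dir / "labelmap.json", small_camera)
        via_coco = read_coco_segmentations(coco_path, small_camera)
        for a, b in zip(via_png, via_coco):
            assert set(a.masks) == set(b.masks)
            for lbl in a.masks:
                merged = np.zeros_like(b.masks[lbl][0])
                for m in b.masks[lbl]:
                    merged |= m
                assert np.array_equal(a.masks[lbl][0], merged)


class TestSeriesRoundtrip:
    def test_cardinality_and_roundtrip(self, tmp_path, small_scene, small_camera):
        bundle, _ = small_scene
        series = compute_ogd_series(bundle)
        p = tmp_path / "series.csv"
        write_ogd_series(series, p)
        df = read_ogd_series(p)
        assert len(df) == len(bundle.fixations) * 2
        by_key = {
            (r.fixation_id, r.aoi_label): r for r in series.records
        }
        for row in df.itertuples(index=False):
            rec = by_key[(row.fixation_id, row.aoi_label)]
            # CSV stores 9 significant digits
            assert row.ogd_px == pytest.approx(rec.ogd_px, rel=1e-8, abs=1e-8)
            assert bool(row.sentinel_flag) == rec.sentinel

    def test_sentinel_rows_carry_diagonal(self, tmp_path, small_scene, small_camera):
        bundle, truth = small_scene
        series = compute_ogd_series(bundle)
        p = tmp_path / "series.csv"
        write_ogd_series(series, p)
        df = read_ogd_series(p)
        sent = df[df.sentinel_flag]
        assert len(sent) > 0
        assert np.allclose(sent.ogd_px, small_camera.diagonal_px)
        assert (sent.vision_band == "undetected").all()

    def test_record_count_conserved_reading_back(self, tmp_path, small_scene):
        bundle, _ = small_scene
        series = compute_ogd_series(bundle)
        p = tmp_path / "series.csv"
        write_ogd_series(series, p)
        assert len(read_ogd_series(p)) == len(series.records)
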