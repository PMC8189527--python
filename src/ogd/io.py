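"""Readers and writers for fixation tables, mask streams and results.

Supported on-disk formats:

* fixation tables — CSV with columns ``fixation_id, start_s, duration_s,
  gaze_x, gaze_y`` (header-driven, any column order);
* per-frame AOI masks — either a directory of 8-bit label PNGs (one per frame,
  named by frame index, with a JSON label map ``{"1": "screw", ...}``) or a
  single COCO-style JSON file with polygon or uncompressed-RLE segmentations;
* camera configuration — YAML or JSON with keys ``width_px, height_px,
  hfov_deg, vfov_deg, fps``;
* object-gaze distance series — long-format CSV, one row per
  fixation x AOI.

Coordinate convention: 0-based pixel indices, origin top-left, x rightward,
y downward; gaze coordinates are continuous floats.  Gaze points outside the
frame are kept (and flagged by consumers), never clamped.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from ._errors import SchemaError, ValidationError
from .camera import CameraModel, VisionFieldSpec, classify_vision_field, default_field_spec

logger = logging.getLogger(__name__)

__all__ = [
    "Fixation",
    "FrameSegmentation",
    "TrialBundle",
    "read_camera_config",
    "write_camera_config",
    "read_fixations",
    "write_fixations",
    "read_label_png_masks",
    "write_label_png_masks",
    "read_coco_segmentations",
    "write_coco_segmentations",
    "write_ogd_series",
    "read_ogd_series",
]

_FIXATION_COLUMNS = ("fixation_id", "start_s", "duration_s", "gaze_x", "gaze_y")


@dataclass(frozen=True)
class Fixation:
    """One fixation event: a time span plus a scene-camera gaze coordinate."""

    fixation_id: int
    start_s: float
    duration_s: float
    gaze_x: float
    gaze_y: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError(
                f"fixation {self.fixation_id}: duration must be positive, "
                f"got {self.duration_s}"
            )
        if self.start_s < 0:
            raise ValidationError(
                f"fixation {self.fixation_id}: start time must be non-negative, "
                f"got {self.start_s}"
            )

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def in_frame(self, camera: CameraModel) -> bool:
        """Whether the gaze coordinate lies inside the camera frame."""
        return 0 <= self.gaze_x < camera.width_px and 0 <= self.gaze_y < camera.height_px


@dataclass
class FrameSegmentation:
    """Per-frame map of AOI label -> list of binary instance masks.

    A label absent from ``masks`` means the AOI was not detected in this
    frame.  Each mask is a boolean ``(height, width)`` array.
    """

    frame_index: int
    masks: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def instances(self, label: str) -> list[np.ndarray]:
        return self.masks.get(label, [])


@dataclass
class TrialBundle:
    """Everything needed to compute an OGD series for one trial."""

    camera: CameraModel
    fixations: list[Fixation]
    frames: list[FrameSegmentation]
    aoi_labels: frozenset[str]

    def __post_init__(self) -> None:
        for i, frame in enumerate(self.frames):
            if frame.frame_index != i:
                raise ValidationError(
                    f"frame indices must be contiguous from 0; "
                    f"position {i} holds frame_index {frame.frame_index}"
                )


# ---------------------------------------------------------------------------
# camera configuration


def read_camera_config(path: str | Path) -> CameraModel:
    """Read a camera model from a YAML or JSON config file."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(data, Mapping):
        raise SchemaError(f"{path}: camera config must be a mapping")
    required = ("width_px", "height_px", "hfov_deg", "vfov_deg", "fps")
    missing = [k for k in required if k not in data]
    if missing:
        raise SchemaError(f"{path}: camera config missing key(s) {missing}")
    return CameraModel(
        width_px=int(data["width_px"]),
        height_px=int(data["height_px"]),
        hfov_deg=float(data["hfov_deg"]),
        vfov_deg=float(data["vfov_deg"]),
        fps=float(data["fps"]),
    )


def write_camera_config(camera: CameraModel, path: str | Path) -> None:
    path = Path(path)
    data = {
        "width_px": camera.width_px,
        "height_px": camera.height_px,
        "hfov_deg": camera.hfov_deg,
        "vfov_deg": camera.vfov_deg,
        "fps": camera.fps,
    }
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(data, fh, sort_keys=True)
        else:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# fixations


def read_fixations(path: str | Path) -> list[Fixation]:
    """Read and validate a fixation table.

    Columns are matched by header name, so column order is irrelevant.
    Unsorted rows are sorted by start time with a warning; overlapping
    fixations are a hard error (a subject has one gaze at a time).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: fixation table missing column(s) {missing}")
    fixations = [
        Fixation(
            fixation_id=int(row.fixation_id),
            start_s=float(row.start_s),
            duration_s=float(row.duration_s),
            gaze_x=float(row.gaze_x),
            gaze_y=float(row.gaze_y),
        )
        for row in df.itertuples(index=False)
    ]
    return validate_fixation_sequence(fixations, source=str(path))


def validate_fixation_sequence(
    fixations: Sequence[Fixation], source: str = "<memory>"
) -> list[Fixation]:
    """Sort fixations by start time and reject temporal overlaps."""
    ordered = sorted(fixations, key=lambda f: f.start_s)
    if list(ordered) != list(fixations):
        warnings.warn(f"{source}: fixations were not sorted by start_s; sorted")
        logger.warning("%s: fixations were not sorted by start_s; sorted", source)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.start_s < prev.end_s - 1e-9:
            raise ValidationError(
                f"{source}: fixations {prev.fixation_id} and {cur.fixation_id} "
                f"overlap in time ({prev.start_s:.4f}-{prev.end_s:.4f} s vs "
                f"start {cur.start_s:.4f} s)"
            )
    return list(ordered)


def write_fixations(fixations: Iterable[Fixation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "fixation_id": f.fixation_id,
                "start_s": f.start_s,
                "duration_s": f.duration_s,
                "gaze_x": f.gaze_x,
                "gaze_y": f.gaze_y,
            }
            for f in fixations
        ],
        columns=list(_FIXATION_COLUMNS),
    )
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# label-PNG mask streams

_FRAME_NAME_RE = re.compile(r"(\d+)\.png$", re.IGNORECASE)


def read_label_png_masks(
    directory: str | Path,
    labelmap: str | Path | Mapping[int, str],
    camera: CameraModel | None = None,
) -> list[FrameSegmentation]:
    """Read a directory of 8-bit label PNGs into per-frame segmentations.

    Pixel value 0 is background; every other value must appear in the label
    map.  A value absent from a frame means that AOI was not detected there.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise SchemaError(f"mask directory not found: {directory}")
    if not isinstance(labelmap, Mapping):
        with open(labelmap) as fh:
            raw = json.load(fh)
        labelmap = {int(k): str(v) for k, v in raw.items()}
    labelmap = dict(labelmap)
    if 0 in labelmap:
        raise SchemaError("label map must not assign a label to background value 0")

    paths: dict[int, Path] = {}
    for p in sorted(directory.iterdir()):
        m = _FRAME_NAME_RE.search(p.name)
        if m:
            paths[int(m.group(1))] = p
    if not paths:
        raise SchemaError(f"no frame PNGs found in {directory}")
    expected = list(range(max(paths) + 1))
    missing = [i for i in expected if i not in paths]
    if missing:
        raise SchemaError(f"{directory}: missing frame index(es) {missing[:10]}")

    frames: list[FrameSegmentation] = []
    for idx in expected:
        img = Image.open(paths[idx])
        if img.mode not in ("L", "P"):
            raise SchemaError(
                f"{paths[idx]}: expected an 8-bit single-channel PNG, got mode "
                f"{img.mode!r}"
            )
        arr = np.asarray(img, dtype=np.uint8)
        if camera is not None and arr.shape != (camera.height_px, camera.width_px):
            raise ValidationError(
                f"{paths[idx]}: mask size {arr.shape[1]}x{arr.shape[0]} does not "
                f"match camera resolution {camera.width_px}x{camera.height_px}"
            )
        values = np.unique(arr)
        unknown = [int(v) for v in values if v != 0 and int(v) not in labelmap]
        if unknown:
            raise SchemaError(
                f"{paths[idx]}: pixel value(s) {unknown} not in label map "
                f"{sorted(labelmap)}"
            )
        masks: dict[str, list[np.ndarray]] = {}
        for v in values:
            if v == 0:
                continue
            masks.setdefault(labelmap[int(v)], []).append(arr == v)
        frames.append(FrameSegmentation(frame_index=idx, masks=masks))
    return frames


def write_label_png_masks(
    frames: Sequence[FrameSegmentation],
    directory: str | Path,
    labelmap: Mapping[int, str] | None = None,
) -> dict[int, str]:
    """Write frames as 8-bit label PNGs plus a ``labelmap.json``.

    A label image cannot represent overlaps: multiple instances of one AOI
    collapse onto one pixel value, and where different AOIs overlap the
    higher label value wins (warned, since the encoding is then lossy).
    Returns the label map used.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if labelmap is None:
        labels = sorted({lbl for fr in frames for lbl in fr.masks})
        labelmap = {i + 1: lbl for i, lbl in enumerate(labels)}
    value_of = {lbl: v for v, lbl in labelmap.items()}
    width = max(5, len(str(max(len(frames) - 1, 0))))
    for fr in frames:
        shape = None
        for instances in fr.masks.values():
            for m in instances:
                shape = m.shape
                break
            if shape:
                break
        if shape is None:
            raise ValidationError(
                f"frame {fr.frame_index}: cannot infer image size from an "
                "all-background frame; pass frames from a generator that "
                "records camera size, or write at least one mask"
            )
        arr = np.zeros(shape, dtype=np.uint8)
        for v in sorted(value_of[lbl] for lbl in fr.masks):
            lbl = labelmap[v]
            for m in fr.masks[lbl]:
                if (arr[m] != 0).any():
                    warnings.warn(
                        f"frame {fr.frame_index}: AOI masks overlap; label "
                        f"image assigns shared pixels to {lbl!r}"
                    )
                arr[m] = v
        Image.fromarray(arr, mode="L").save(
            directory / f"{fr.frame_index:0{width}d}.png"
        )
    with open(directory / "labelmap.json", "w") as fh:
        json.dump({str(v): lbl for v, lbl in sorted(labelmap.items())}, fh, indent=2)
        fh.write("\n")
    return dict(labelmap)


# ---------------------------------------------------------------------------
# COCO-style segmentations


def _rasterize_polygon(
    coords: Sequence[float], height: int, width: int
) -> np.ndarray:
    """Rasterize a flat [x0, y0, x1, y1, ...] polygon to a boolean mask.

    A pixel (row i, column j) is set when its center (x=j, y=i), nudged by a
    half-pixel toward the lower-right and a tie-break epsilon, falls inside
    the polygon: an axis-aligned box [0, w] x [0, h] covers exactly w*h
    pixels, half-open on the max edges.
    """
    import shapely

    if len(coords) < 6 or len(coords) % 2:
        raise SchemaError(f"polygon must have >= 3 (x, y) pairs, got {coords!r}")
    xs = np.asarray(coords[0::2], dtype=float)
    ys = np.asarray(coords[1::2], dtype=float)
    poly = shapely.Polygon(zip(xs, ys))
    mask = np.zeros((height, width), dtype=bool)
    j0 = max(int(np.floor(xs.min())), 0)
    j1 = min(int(np.ceil(xs.max())) + 1, width)
    i0 = max(int(np.floor(ys.min())), 0)
    i1 = min(int(np.ceil(ys.max())) + 1, height)
    if j0 >= j1 or i0 >= i1:
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    eps = 1e-7
    inside = shapely.contains_xy(
        poly, jj.ravel() + 0.5 - eps, ii.ravel() + 0.5 - eps
    )
    mask[i0:i1, j0:j1] = inside.reshape(ii.shape)
    return mask


def _decode_uncompressed_rle(counts: Sequence[int], height: int, width: int) -> np.ndarray:
    """Decode COCO uncompressed RLE (column-major, starting with zeros)."""
    total = int(np.sum(counts))
    if total != height * width:
        raise SchemaError(
            f"RLE counts sum to {total}, expected {height * width} "
            f"for size [{height}, {width}]"
        )
    values = np.zeros(len(counts), dtype=bool)
    values[1::2] = True
    flat = np.repeat(values, counts)
    return flat.reshape((width, height)).T  # column-major order


def _encode_uncompressed_rle(mask: np.ndarray) -> list[int]:
    flat = np.asarray(mask, dtype=bool).T.ravel()  # column-major
    if flat.size == 0:
        return [0]
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    runs = np.diff(np.concatenate(([0], change, [flat.size]))).tolist()
    if flat[0]:  # counts must start with a (possibly zero) run of zeros
        runs = [0] + runs
    return [int(r) for r in runs]


def read_coco_segmentations(
    path: str | Path, camera: CameraModel
) -> list[FrameSegmentation]:
    """Read COCO-style annotations into per-frame segmentations.

    Image ids are the frame indices.  Polygon and uncompressed-RLE
    segmentations are supported; compressed (string-counts) RLE is rejected.
    Multiple annotations sharing a category in one frame become multiple
    instances under one label.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise SchemaError(f"{path}: COCO document missing key {key!r}")
    cat_name = {int(c["id"]): str(c["name"]) for c in doc["categories"]}
    h, w = camera.height_px, camera.width_px
    frame_ids = sorted(int(img["id"]) for img in doc["images"])
    if frame_ids != list(range(len(frame_ids))):
        raise SchemaError(
            f"{path}: image ids must be contiguous frame indices from 0, "
            f"got {frame_ids[:10]}..."
        )
    for img in doc["images"]:
        iw, ih = int(img.get("width", w)), int(img.get("height", h))
        if (iw, ih) != (w, h):
            raise ValidationError(
                f"{path}: image {img['id']} size {iw}x{ih} does not match "
                f"camera resolution {w}x{h}"
            )
    frames = [FrameSegmentation(frame_index=i) for i in frame_ids]
    for ann in doc["annotations"]:
        frame = frames[int(ann["image_id"])]
        cid = int(ann["category_id"])
        if cid not in cat_name:
            raise SchemaError(f"{path}: annotation references unknown category {cid}")
        seg = ann["segmentation"]
        if isinstance(seg, list):  # one or more polygons -> one instance
            mask = np.zeros((h, w), dtype=bool)
            for poly in seg:
                mask |= _rasterize_polygon(poly, h, w)
        elif isinstance(seg, Mapping) and "counts" in seg:
            counts = seg["counts"]
            if isinstance(counts, (bytes, str)):
                raise SchemaError(
                    "compressed RLE segmentation is not supported; export "
                    "uncompressed RLE (integer counts) or polygons"
                )
            sh, sw = (int(v) for v in seg["size"])
            if (sh, sw) != (h, w):
                raise ValidationError(
                    f"{path}: RLE size [{sh}, {sw}] does not match camera "
                    f"resolution [{h}, {w}]"
                )
            mask = _decode_uncompressed_rle(counts, h, w)
        else:
            raise SchemaError(
                f"unsupported segmentation encoding: {type(seg).__name__}"
            )
        frame.masks.setdefault(cat_name[cid], []).append(mask)
    return frames


def write_coco_segmentations(
    frames: Sequence[FrameSegmentation], camera: CameraModel, path: str | Path
) -> None:
    """Write frames as a COCO-style JSON with uncompressed-RLE segmentations."""
    labels = sorted({lbl for fr in frames for lbl in fr.masks})
    cat_id = {lbl: i + 1 for i, lbl in enumerate(labels)}
    h, w = camera.height_px, camera.width_px
    doc = {
        "images": [
            {"id": fr.frame_index, "width": w, "height": h,
             "file_name": f"{fr.frame_index:05d}.png"}
            for fr in frames
        ],
        "categories": [{"id": i, "name": lbl} for lbl, i in cat_id.items()],
        "annotations": [],
    }
    ann_id = 1
    for fr in frames:
        for lbl in sorted(fr.masks):
            for mask in fr.masks[lbl]:
                doc["annotations"].append(
                    {
                        "id": ann_id,
                        "image_id": fr.frame_index,
                        "category_id": cat_id[lbl],
                        "segmentation": {
                            "size": [h, w],
                            "counts": _encode_uncompressed_rle(mask),
                        },
                        "area": int(np.count_nonzero(mask)),
                        "iscrowd": 0,
                    }
                )
                ann_id += 1
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


# ---------------------------------------------------------------------------
# OGD series CSV

_SERIES_COLUMNS = (
    "fixation_id",
    "aoi_label",
    "ogd_px",
    "sentinel_flag",
    "vision_band",
    "frame_index_used",
)


def write_ogd_series(
    series, path: str | Path, field_spec: VisionFieldSpec | None = None
) -> None:
    """Write an OGD series as a long-format CSV (one row per fixation x AOI).

    The vision band column is derived from ``field_spec`` (default: thresholds
    derived from the series' camera).
    """
    if field_spec is None:
        field_spec = default_field_spec(series.camera, "derived_from_camera")
    rows = [
        {
            "fixation_id": r.fixation_id,
            "aoi_label": r.aoi_label,
            "ogd_px": r.ogd_px,
            "sentinel_flag": r.sentinel,
            "vision_band": classify_vision_field(
                r.ogd_px, field_spec, sentinel=r.sentinel
            ).value,
            "frame_index_used": r.frame_index_used,
        }
        for r in series.records
    ]
    df = pd.DataFrame(rows, columns=list(_SERIES_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9g")


def read_ogd_series(path: str | Path) -> pd.DataFrame:
    """Read back an OGD series CSV as a typed DataFrame."""
    df = pd.read_csv(path)
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: OGD series missing column(s) {missing}")
    df["sentinel_flag"] = df["sentinel_flag"].astype(bool)
    return df
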