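"""The object-gaze distance computation.

For every fixation and every AOI, the object-gaze distance (OGD) is the
minimal 2D Euclidean pixel distance between the fixation's gaze coordinate and
the AOI's segmented mask in the scene frame.  A gaze point inside the mask is
an AOI Hit (OGD = 0).  When the AOI is not detected in the frame(s) a fixation
maps to, the record carries the sentinel value: the frame diagonal (1600 px on
the reference camera), which also caps every distance.

Distances are measured to mask pixel *centers* (pixel (i, j) has its center at
continuous coordinate x = j, y = i), which makes an exhaustive minimum over
true pixels an exact oracle for the fast nearest-neighbour implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._errors import ValidationError
from .camera import CameraModel, frame_diagonal_px
from .io import Fixation, FrameSegmentation, TrialBundle

__all__ = [
    "OGDRecord",
    "OGDSeries",
    "min_distance_to_mask",
    "fixation_frame",
    "ogd_for_fixation",
    "compute_ogd_series",
]

_FRAME_EPS = 1e-9


@dataclass(frozen=True)
class OGDRecord:
    """One fixation x AOI distance record."""

    fixation_id: int
    aoi_label: str
    ogd_px: float
    sentinel: bool
    frame_index_used: int


@dataclass
class OGDSeries:
    """Complete fixation x AOI grid of OGD records for one trial.

    Unlike one-to-one AOI-Hit mapping, every fixation is mapped to every AOI,
    so ``len(records) == n_fixations * n_aoi_labels``.
    """

    records: list[OGDRecord]
    camera: CameraModel

    @property
    def aoi_labels(self) -> list[str]:
        return sorted({r.aoi_label for r in self.records})

    @property
    def fixation_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for r in self.records:
            seen.setdefault(r.fixation_id, None)
        return list(seen)

    def for_aoi(self, aoi_label: str) -> list[OGDRecord]:
        recs = [r for r in self.records if r.aoi_label == aoi_label]
        if not recs:
            raise ValidationError(
                f"unknown AOI {aoi_label!r}; known labels: {self.aoi_labels}"
            )
        return recs


def _containing_pixel(gx: float, gy: float) -> tuple[int, int]:
    # round-half-up: the pixel whose center is nearest, ties toward +x/+y
    return int(math.floor(gy + 0.5)), int(math.floor(gx + 0.5))


def min_distance_to_mask(gaze: tuple[float, float], mask: np.ndarray) -> float:
    """Minimal Euclidean distance (px) from a gaze point to a binary mask.

    Returns 0.0 when the gaze rounds into a true pixel (an AOI Hit);
    otherwise the minimum over all true pixels of the distance from the
    (continuous) gaze coordinate to the pixel center.

    Raises on an empty mask — absence of the AOI is the caller's concern and
    routes to the sentinel value instead.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    if not mask.any():
        raise ValidationError(
            "empty mask has no distance; route undetected AOIs to the sentinel"
        )
    gx, gy = float(gaze[0]), float(gaze[1])
    iy, ix = _containing_pixel(gx, gy)
    if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]:
        return 0.0
    tree = cKDTree(np.argwhere(mask))
    dist, _ = tree.query([gy, gx])
    return float(dist)


def fixation_frame(
    fixation: Fixation, camera: CameraModel, policy: str = "midpoint"
) -> list[int]:
    """Map a fixation's time span to scene-video frame index(es).

    ``midpoint`` picks the single frame nearest the fixation's temporal
    midpoint (``round((start + duration/2) * fps)``); ``all_frames`` returns
    every frame whose interval ``[k/fps, (k+1)/fps)`` overlaps the half-open
    fixation span ``[start, start + duration)``.
    """
    fps = camera.fps
    if policy == "midpoint":
        return [int(round((fixation.start_s + fixation.duration_s / 2.0) * fps))]
    if policy == "all_frames":
        first = int(math.floor(fixation.start_s * fps + _FRAME_EPS))
        last_exclusive = int(math.ceil(fixation.end_s * fps - _FRAME_EPS))
        return list(range(first, max(last_exclusive, first + 1)))
    raise ValidationError(
        f"unknown frame policy {policy!r}; expected 'midpoint' or 'all_frames'"
    )


_AGGREGATES = {
    "median": lambda v: float(np.median(v)),
    "min": lambda v: float(np.min(v)),
    "mean": lambda v: float(np.mean(v)),
}


def _frame_distance(
    gaze: tuple[float, float],
    frame: FrameSegmentation,
    aoi_label: str,
    diagonal: float,
) -> tuple[float, bool]:
    """Distance for one frame: nearest instance, or the diagonal if absent."""
    instances = frame.instances(aoi_label)
    if not instances:
        return diagonal, False
    d = min(min_distance_to_mask(gaze, m) for m in instances)
    return min(d, diagonal), True


def ogd_for_fixation(
    fixation: Fixation,
    frames: list[FrameSegmentation],
    aoi_label: str,
    camera: CameraModel,
    policy: str = "midpoint",
    aggregate: str = "median",
    known_labels: frozenset[str] | None = None,
) -> OGDRecord:
    """OGD record for one fixation against one AOI.

    Per selected frame the distance is the minimum over the AOI's instances
    (or the frame-diagonal cap if the AOI is absent); multi-frame values are
    combined by ``aggregate``.  The record is flagged sentinel only when the
    AOI is absent in *all* selected frames.
    """
    if known_labels is not None and aoi_label not in known_labels:
        raise ValidationError(
            f"unknown AOI {aoi_label!r}; known labels: {sorted(known_labels)}"
        )
    if aggregate not in _AGGREGATES:
        raise ValidationError(
            f"unknown aggregate {aggregate!r}; expected one of {sorted(_AGGREGATES)}"
        )
    indices = fixation_frame(fixation, camera, policy)
    if indices[0] < 0 or indices[-1] >= len(frames):
        raise ValidationError(
            f"fixation {fixation.fixation_id} maps to frame(s) "
            f"{indices[0]}..{indices[-1]} outside 0..{len(frames) - 1}"
        )
    diagonal = frame_diagonal_px(camera)
    gaze = (fixation.gaze_x, fixation.gaze_y)
    values: list[float] = []
    detected_any = False
    nearest_frame = indices[0]
    nearest_val = math.inf
    for idx in indices:
        d, detected = _frame_distance(gaze, frames[idx], aoi_label, diagonal)
        values.append(d)
        detected_any = detected_any or detected
        if d < nearest_val:
            nearest_val, nearest_frame = d, idx
    if not detected_any:
        return OGDRecord(fixation.fixation_id, aoi_label, diagonal, True, indices[0])
    return OGDRecord(
        fixation.fixation_id,
        aoi_label,
        _AGGREGATES[aggregate](values),
        False,
        nearest_frame,
    )


def compute_ogd_series(
    bundle: TrialBundle, policy: str = "midpoint", aggregate: str = "median"
) -> OGDSeries:
    """Compute the complete fixation x AOI OGD grid for one trial.

    Records are ordered by fixation start time, then AOI label.
    """
    labels = sorted(bundle.aoi_labels)
    records = [
        ogd_for_fixation(
            fixation,
            bundle.frames,
            label,
            bundle.camera,
            policy=policy,
            aggregate=aggregate,
            known_labels=bundle.aoi_labels,
        )
        for fixation in bundle.fixations
        for label in labels
    ]
    return OGDSeries(records=records, camera=bundle.camera)
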