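"""Synthetic scenes and series with analytic ground truth.

Real mobile eye-tracking recordings pair a scene video with fixation data and
network-segmented AOI masks; none of that is needed to validate the distance
pipeline.  This module builds trials from first principles: rigid disks and
rectangles moving through the frame, rasterized to masks, with seeded
detection dropout and a fixation track whose gaze points have closed-form
distances to every object (disk: ``max(0, ||g - c|| - r)``; rectangle:
distance to the axis-aligned box, 0 inside).

Rasterization includes a pixel when its center lies within half a pixel of
the continuous shape (sqrt(2)/2 px radially for disks, 0.5 px per axis for
rectangles).  With that convention every *nonzero* pipeline OGD provably
agrees with the analytic distance to within sqrt(2)/2 px for any sub-pixel
object position — a plain center-in test does not have this property (its
one-sided error reaches sqrt(2) px when the shape boundary passes just
beyond a row of pixel centers).  Hit-clamped records (OGD = 0 because the
gaze rounds into a mask pixel) are the one exception: pixel containment
quantizes the gaze to its cell, so a Hit can occur with the gaze up to
sqrt(2) px outside the continuous shape; no rasterization rule can tighten
that, because shrinking the mask to protect the Hit test re-opens the
distance-side gap.

Also home to the brute-force distance oracle — an exhaustive minimum over
true pixels, deliberately sharing no code with the fast implementation — and
to generators of noise-free multi-OGD series with embedded gaze patterns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ValidationError
from .camera import CameraModel
from .io import Fixation, FrameSegmentation, TrialBundle
from .patterns import PatternParams

__all__ = [
    "SceneObject",
    "SceneSpec",
    "GroundTruthRecord",
    "GroundTruth",
    "brute_force_min_distance",
    "generate_scene",
    "random_fixation_track",
    "embed_pattern_series",
    "inject_dropout",
]


def brute_force_min_distance(gaze: tuple[float, float], mask: np.ndarray) -> float:
    """Exhaustive minimal distance from a gaze point to a mask's true pixels.

    The reference oracle for the fast implementation: a plain loop over every
    true pixel center, with the same round-half-up containment rule for the
    0 px (Hit) case.  Deliberately shares no distance code with
    :func:`ogd.core.min_distance_to_mask`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty mask has no distance")
    gx, gy = float(gaze[0]), float(gaze[1])
    iy = int(math.floor(gy + 0.5))
    ix = int(math.floor(gx + 0.5))
    if 0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]:
        return 0.0
    best = math.inf
    for py, px in np.argwhere(mask):
        d = math.sqrt((float(py) - gy) ** 2 + (float(px) - gx) ** 2)
        if d < best:
            best = d
    return best


@dataclass(frozen=True)
class SceneObject:
    """A rigid object: a disk (size = radius) or axis-aligned rectangle
    (size = (width, height)), with a per-frame center trajectory in px."""

    label: str
    shape: str  # "disk" | "rectangle"
    size: float | tuple[float, float]
    trajectory: np.ndarray  # (n_frames, 2) centers (x, y), or (2,) static

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "rectangle"):
            raise ValidationError(f"unknown shape {self.shape!r}")
        if self.shape == "disk":
            if float(self.size) <= 0:
                raise ValidationError(f"disk radius must be positive: {self.size}")
        else:
            w, h = self.size
            if w <= 0 or h <= 0:
                raise ValidationError(f"rectangle size must be positive: {self.size}")

    def center_at(self, frame_index: int) -> tuple[float, float]:
        traj = np.asarray(self.trajectory, dtype=float)
        if traj.ndim == 1:
            return float(traj[0]), float(traj[1])
        return float(traj[frame_index, 0]), float(traj[frame_index, 1])


@dataclass
class SceneSpec:
    """Full description of a synthetic trial; a pure function of its seed."""

    camera: CameraModel
    objects: list[SceneObject]
    n_frames: int
    fixations: list[Fixation]
    dropout: Mapping[str, float] = field(default_factory=dict)
    gaze_noise_sd_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, rate in self.dropout.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"dropout rate for {label!r} must be in [0, 1]")
        labels = [o.label for o in self.objects]
        if len(labels) != len(set(labels)):
            raise ValidationError(f"duplicate object labels: {labels}")


@dataclass(frozen=True)
class GroundTruthRecord:
    fixation_id: int
    aoi_label: str
    analytic_px: float
    detected: bool
    frame_index: int


@dataclass
class GroundTruth:
    """Analytic fixation x AOI distances (pre-rasterization geometry)."""

    records: list[GroundTruthRecord]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fixation_id": r.fixation_id,
                    "aoi_label": r.aoi_label,
                    "analytic_px": r.analytic_px,
                    "detected": r.detected,
                    "frame_index": r.frame_index,
                }
                for r in self.records
            ]
        )


#: Half-pixel dilation applied when rasterizing (see module docstring).
_DILATION_RADIAL = math.sqrt(2.0) / 2.0
_DILATION_AXIAL = 0.5


def _rasterize(obj: SceneObject, frame_index: int, camera: CameraModel) -> np.ndarray:
    cx, cy = obj.center_at(frame_index)
    h, w = camera.height_px, camera.width_px
    yy, xx = np.mgrid[0:h, 0:w]
    if obj.shape == "disk":
        r = float(obj.size) + _DILATION_RADIAL
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    bw, bh = obj.size
    return (np.abs(xx - cx) <= bw / 2.0 + _DILATION_AXIAL) & (
        np.abs(yy - cy) <= bh / 2.0 + _DILATION_AXIAL
    )


def _analytic_distance(obj: SceneObject, frame_index: int, gx: float, gy: float) -> float:
    cx, cy = obj.center_at(frame_index)
    if obj.shape == "disk":
        return max(0.0, math.hypot(gx - cx, gy - cy) - float(obj.size))
    bw, bh = obj.size
    dx = max(abs(gx - cx) - bw / 2.0, 0.0)
    dy = max(abs(gy - cy) - bh / 2.0, 0.0)
    return math.hypot(dx, dy)


def _midpoint_frame(fixation: Fixation, fps: float) -> int:
    return int(round((fixation.start_s + fixation.duration_s / 2.0) * fps))


def generate_scene(spec: SceneSpec) -> tuple[TrialBundle, GroundTruth]:
    """Rasterize a synthetic trial and compute its analytic ground truth.

    Random streams are split per purpose (dropout draws vs gaze noise) so that
    changing one setting never perturbs the other.  The ground truth evaluates
    each fixation at its temporal-midpoint frame, with ``detected = False``
    where the dropout draw removed the object.
    """
    camera = spec.camera
    drop_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    dropped: dict[str, np.ndarray] = {}
    for obj in spec.objects:
        rate = float(spec.dropout.get(obj.label, 0.0))
        dropped[obj.label] = drop_rng.random(spec.n_frames) < rate

    frames: list[FrameSegmentation] = []
    any_pixels = {obj.label: False for obj in spec.objects}
    for idx in range(spec.n_frames):
        masks: dict[str, list[np.ndarray]] = {}
        for obj in spec.objects:
            if dropped[obj.label][idx]:
                continue
            m = _rasterize(obj, idx, camera)
            if m.any():
                any_pixels[obj.label] = True
                masks.setdefault(obj.label, []).append(m)
        frames.append(FrameSegmentation(frame_index=idx, masks=masks))
    for label, seen in any_pixels.items():
        if not seen:
            warnings.warn(
                f"object {label!r} never rasterizes inside the frame; "
                "its records will all be sentinel"
            )

    fixations: list[Fixation] = []
    for f in spec.fixations:
        gx, gy = f.gaze_x, f.gaze_y
        if spec.gaze_noise_sd_px > 0:
            gx += float(noise_rng.normal(0.0, spec.gaze_noise_sd_px))
            gy += float(noise_rng.normal(0.0, spec.gaze_noise_sd_px))
        fixations.append(
            Fixation(f.fixation_id, f.start_s, f.duration_s, gx, gy)
        )

    gt_records: list[GroundTruthRecord] = []
    for f in fixations:
        idx = _midpoint_frame(f, camera.fps)
        for obj in sorted(spec.objects, key=lambda o: o.label):
            detected = not dropped[obj.label][idx]
            gt_records.append(
                GroundTruthRecord(
                    fixation_id=f.fixation_id,
                    aoi_label=obj.label,
                    analytic_px=_analytic_distance(obj, idx, f.gaze_x, f.gaze_y),
                    detected=detected,
                    frame_index=idx,
                )
            )

    bundle = TrialBundle(
        camera=camera,
        fixations=fixations,
        frames=frames,
        aoi_labels=frozenset(o.label for o in spec.objects),
    )
    return bundle, GroundTruth(records=gt_records)


def random_fixation_track(
    n: int, camera: CameraModel, seed: int, duration_s: float | None = None
) -> list[Fixation]:
    """Sequential non-overlapping fixations with uniform random gaze points.

    One fixation starts at each frame boundary and, by default, lasts 80 % of
    the frame period — the remaining 20 % stands in for the saccade between
    fixations and keeps each fixation's temporal midpoint safely inside one
    frame (a midpoint exactly on a frame boundary would make the frame choice
    sensitive to float round-off).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    period = 1.0 / camera.fps
    if duration_s is None:
        duration_s = 0.8 * period
    if duration_s > period:
        raise ValidationError(
            f"duration_s {duration_s} exceeds the frame period {period}"
        )
    return [
        Fixation(
            fixation_id=i,
            start_s=i * period,
            duration_s=duration_s,
            gaze_x=float(rng.uniform(0, camera.width_px - 1)),
            gaze_y=float(rng.uniform(0, camera.height_px - 1)),
        )
        for i in range(n)
    ]


def embed_pattern_series(
    pattern: str,
    params: PatternParams | None = None,
    length: int = 10,
    position: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a noise-free pair of OGD series containing exactly one pattern.

    The pattern's rule-defining fixations sit around ``position`` (default:
    the series midpoint); everywhere else both series are flat at in-band
    baselines (below the perifoveal threshold), which guarantees no other
    pattern can fire.  Concatenating embeds adds events one-for-one.
    """
    params = params or PatternParams()
    spec = params.field_spec
    fov, peri, near = spec.foveal_px, spec.perifoveal_px, spec.near_peripheral_px
    tol = params.tolerance_px
    base_a = 0.55 * peri
    base_b = 0.83 * peri
    a = np.full(length, base_a)
    b = np.full(length, base_b)

    if pattern == "glance":
        p = length // 2 if position is None else position
        if not 1 <= p <= length - 2:
            raise ValidationError(
                f"glance needs 1 <= position <= length-2, got {p} in {length}"
            )
        a[p] = 0.0
        b[p] = base_b + max(10 * tol, 0.3 * peri)
    elif pattern == "convergence":
        k = max(2, params.min_len)  # number of decreasing steps
        p = length // 2 if position is None else position  # index of the Hit
        if not k <= p <= length - 1:
            raise ValidationError(
                f"convergence needs {k} <= position <= length-1, got {p}"
            )
        a[p - k : p + 1] = np.linspace(1.2 * base_a, 0.0, k + 1)
        b[p - k : p + 1] = np.linspace(base_b, fov / 2.0, k + 1)
    elif pattern == "joint_excursion":
        p = length // 2 if position is None else position
        if not 1 <= p <= length - 2:
            raise ValidationError(
                f"joint_excursion needs 1 <= position <= length-2, got {p}"
            )
        a[p] = (peri + near) / 2.0 - 0.1 * peri
        b[p] = (peri + near) / 2.0 + 0.1 * peri
    elif pattern == "disappearance":
        p = length // 2 if position is None else position
        if not 1 <= p <= length - 2:
            raise ValidationError(
                f"disappearance needs 1 <= position <= length-2, got {p}"
            )
        a[p : p + 2] = near + 0.1 * near
    else:
        raise ValidationError(
            f"unknown pattern {pattern!r}; expected one of "
            "glance/convergence/joint_excursion/disappearance"
        )
    return a, b


def inject_dropout(
    frames: Sequence[FrameSegmentation], label: str, rate: float, seed: int
) -> list[FrameSegmentation]:
    """Remove one AOI's masks from a seeded Bernoulli subset of frames."""
    if not 0.0 <= rate <= 1.0:
        raise ValidationError(f"dropout rate must be in [0, 1], got {rate}")
    known = {lbl for fr in frames for lbl in fr.masks}
    if label not in known:
        raise ValidationError(f"unknown label {label!r}; present labels: {sorted(known)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    drop = rng.random(len(frames)) < rate
    out: list[FrameSegmentation] = []
    for fr, d in zip(frames, drop):
        masks = {k: list(v) for k, v in fr.masks.items() if not (d and k == label)}
        out.append(FrameSegmentation(frame_index=fr.frame_index, masks=masks))
    return out
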