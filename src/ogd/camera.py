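"""Scene-camera geometry and visual-field classification.

The scene camera of a head-mounted eye tracker defines the coordinate frame in
which both gaze points and object masks live.  Two derived quantities matter
downstream:

* the pixel-per-degree scale, which converts the angular diameters of the human
  fields of vision (foveal < 2°, parafoveal < 9°, perifoveal < 18°,
  near-peripheral < 60°) into pixel distance thresholds around the gaze point;
* the frame diagonal, which caps every object-gaze distance and doubles as the
  sentinel value assigned when an AOI is not detected in a frame.

The reference device is a 1280 x 960 px scene camera with a 60° horizontal and
46° vertical viewing angle at 60 Hz, for which the diagonal is exactly 1600 px
and the near-peripheral threshold exactly 640 px.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from ._errors import ValidationError

__all__ = [
    "CameraModel",
    "VisionFieldSpec",
    "VisionBand",
    "REFERENCE_CAMERA",
    "pixels_per_degree",
    "deg_diameter_to_px",
    "frame_diagonal_px",
    "default_field_spec",
    "classify_vision_field",
]

#: Angular diameters (degrees) of the concentric fields of vision.
FIELD_DIAMETERS_DEG = {
    "foveal": 2.0,
    "parafoveal": 9.0,
    "perifoveal": 18.0,
    "near_peripheral": 60.0,
}

#: Rounded pixel thresholds as printed for the reference camera.
TABLE_DEFAULT_THRESHOLDS_PX = (20.0, 90.0, 180.0, 640.0)


@dataclass(frozen=True)
class CameraModel:
    """Scene-camera geometry: resolution, field of view and frame rate.

    Parameters
    ----------
    width_px, height_px
        Scene resolution in pixels.
    hfov_deg, vfov_deg
        Horizontal and vertical viewing angle in degrees.
    fps
        Scene-video frame rate in frames per second.
    """

    width_px: int
    height_px: int
    hfov_deg: float
    vfov_deg: float
    fps: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError(
                f"camera resolution must be positive, got "
                f"{self.width_px}x{self.height_px}"
            )
        if self.hfov_deg <= 0 or self.vfov_deg <= 0:
            raise ValidationError(
                f"camera field of view must be positive, got "
                f"{self.hfov_deg}°x{self.vfov_deg}°"
            )
        if self.fps <= 0:
            raise ValidationError(f"frame rate must be positive, got {self.fps}")

    @property
    def diagonal_px(self) -> float:
        return frame_diagonal_px(self)


#: The reference eye-tracker scene camera (1280x960, 60°x46°, 60 Hz).
REFERENCE_CAMERA = CameraModel(1280, 960, 60.0, 46.0, 60.0)


class VisionBand(str, enum.Enum):
    """Concentric visual-field band of an object relative to the gaze point."""

    FOVEAL = "foveal"
    PARAFOVEAL = "parafoveal"
    PERIFOVEAL = "perifoveal"
    NEAR_PERIPHERAL = "near_peripheral"
    OUTSIDE = "outside"
    UNDETECTED = "undetected"


@dataclass(frozen=True)
class VisionFieldSpec:
    """Pixel thresholds (radii around the gaze point) for the vision bands.

    ``source`` records whether the thresholds are the rounded table values for
    the reference camera or were derived from the camera's px/deg scale.
    """

    foveal_px: float
    parafoveal_px: float
    perifoveal_px: float
    near_peripheral_px: float
    source: str = "derived_from_camera"

    def __post_init__(self) -> None:
        t = (
            self.foveal_px,
            self.parafoveal_px,
            self.perifoveal_px,
            self.near_peripheral_px,
        )
        if not (0 < t[0] < t[1] < t[2] < t[3]):
            raise ValidationError(
                f"vision-field thresholds must be strictly increasing and "
                f"positive, got {t}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (
            self.foveal_px,
            self.parafoveal_px,
            self.perifoveal_px,
            self.near_peripheral_px,
        )


def pixels_per_degree(camera: CameraModel) -> float:
    """Pixel-per-degree scale of the scene camera.

    The horizontal axis is the reference scale: a single isotropic threshold
    table is used, and the horizontal ratio reproduces the printed
    near-peripheral threshold (640 px at 1280 px / 60°) exactly.
    """
    return camera.width_px / camera.hfov_deg


def deg_diameter_to_px(camera: CameraModel, diameter_deg: float) -> float:
    """Convert an angular *diameter* into a pixel threshold (a radius).

    Distances are measured from the gaze point outward, so a field of vision
    with angular diameter ``d`` corresponds to a threshold of ``d/2`` degrees
    of visual angle, converted at the camera's horizontal px/deg scale.
    """
    if diameter_deg < 0:
        raise ValidationError(f"diameter must be non-negative, got {diameter_deg}")
    return (diameter_deg / 2.0) * pixels_per_degree(camera)


def frame_diagonal_px(camera: CameraModel) -> float:
    """Length of the frame diagonal in pixels.

    This is both the upper bound of any object-gaze distance and the sentinel
    value assigned when an AOI is undetected in a frame (1600 px for the
    reference 1280x960 camera).
    """
    return math.hypot(camera.width_px, camera.height_px)


def _is_reference_geometry(camera: CameraModel) -> bool:
    return (
        camera.width_px == REFERENCE_CAMERA.width_px
        and camera.height_px == REFERENCE_CAMERA.height_px
        and camera.hfov_deg == REFERENCE_CAMERA.hfov_deg
    )


def default_field_spec(
    camera: CameraModel, mode: str = "derived_from_camera"
) -> VisionFieldSpec:
    """Build the default vision-field thresholds for a camera.

    ``table_defaults`` returns the published rounded thresholds
    (20 / 90 / 180 / 640 px) and is only valid for the reference 1280x960 / 60°
    geometry.  ``derived_from_camera`` converts the angular diameters
    (2 / 9 / 18 / 60°) exactly, with no rounding, and works for any camera.
    """
    if mode == "table_defaults":
        if not _is_reference_geometry(camera):
            raise ValidationError(
                "table_defaults thresholds are only defined for the reference "
                "1280x960 / 60° camera; use mode='derived_from_camera' for "
                f"{camera.width_px}x{camera.height_px} / {camera.hfov_deg}°"
            )
        return VisionFieldSpec(*TABLE_DEFAULT_THRESHOLDS_PX, source="table_defaults")
    if mode == "derived_from_camera":
        return VisionFieldSpec(
            *(deg_diameter_to_px(camera, d) for d in FIELD_DIAMETERS_DEG.values()),
            source="derived_from_camera",
        )
    raise ValidationError(
        f"unknown field-spec mode {mode!r}; expected 'table_defaults' or "
        "'derived_from_camera'"
    )


def classify_vision_field(
    distance_px: float, spec: VisionFieldSpec, *, sentinel: bool = False
) -> VisionBand:
    """Classify an object-gaze distance into a visual-field band.

    Bands are half-open ``[lo, hi)`` so every distance maps to exactly one
    band; a 0 px distance (an AOI Hit) is foveal.  Records flagged as sentinel
    (AOI undetected) are classified ``undetected`` regardless of their value.
    """
    if sentinel:
        return VisionBand.UNDETECTED
    if distance_px < 0:
        raise ValidationError(f"distance must be non-negative, got {distance_px}")
    if distance_px < spec.foveal_px:
        return VisionBand.FOVEAL
    if distance_px < spec.parafoveal_px:
        return VisionBand.PARAFOVEAL
    if distance_px < spec.perifoveal_px:
        return VisionBand.PERIFOVEAL
    if distance_px < spec.near_peripheral_px:
        return VisionBand.NEAR_PERIPHERAL
    return VisionBand.OUTSIDE
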