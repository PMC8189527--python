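import numpy as np
import pytest
from hypothesis import settings

from ogd.camera import CameraModel, REFERENCE_CAMERA, default_field_spec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from ogd.synth import SceneObject, SceneSpec, generate_scene, random_fixation_track


@pytest.fixture(scope="session")
def ref_camera():
    return REFERENCE_CAMERA


@pytest.fixture(scope="session")
def small_camera():
    """A compact camera with the reference 60° optics, cheap to rasterize."""
    return CameraModel(320, 240, 60.0, 46.0, 30.0)


@pytest.fixture(scope="session")
def table_spec(ref_camera):
    return default_field_spec(ref_camera, "table_defaults")


def make_scene(camera, n_fixations=60, dropout=0.0, seed=11, gaze_noise_sd_px=0.0):
    """A two-object scene: moving disk (left half) + static rectangle (right),
    spatially disjoint so the scene survives label-image encoding, with
    sub-pixel sizes and positions."""
    n_frames = n_fixations + 1
    traj = np.column_stack(
        [
            np.linspace(0.15 * camera.width_px, 0.4 * camera.width_px, n_frames),
            0.5 * camera.height_px
            + 0.15 * camera.height_px * np.sin(np.linspace(0, 5, n_frames)),
        ]
    )
    spec = SceneSpec(
        camera=camera,
        objects=[
            SceneObject("screw", "disk", 0.08 * camera.height_px + 0.3, traj),
            SceneObject(
                "screwdriver",
                "rectangle",
                (0.13 * camera.width_px + 0.4, 0.1 * camera.height_px + 0.7),
                np.array([0.78 * camera.width_px + 0.2, 0.4 * camera.height_px + 0.6]),
            ),
        ],
        n_frames=n_frames,
        fixations=random_fixation_track(n_fixations, camera, seed),
        dropout={"screw": dropout},
        seed=seed,
        gaze_noise_sd_px=gaze_noise_sd_px,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def small_scene(small_camera):
    return make_scene(small_camera, n_fixations=60, dropout=0.2, seed=11)
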