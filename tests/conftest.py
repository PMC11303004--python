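import numpy as np
import pytest

from rastr.align import AlignConfig, align_stack
from rastr.azimuthal import reconstruct, smooth_z
from rastr.formats import ImageStack, empty_metadata
from rastr.subtraction import subtract_stack
from rastr.synthtube import (ParticleModel, TubeProfile, render_tube_projection,
                             simulate_segments)

PIXEL_SIZE = 4.32  # A/px (3x-binned 1.44 A detector pixel)


@pytest.fixture(scope="session")
def small_profile():
    """Tube small enough to fit a 64-voxel reconstruction box."""
    return TubeProfile(outer_radius=60.0, bilayer_separation=35.0, shell_sigma=7.0)


@pytest.fixture(scope="session")
def default_profile():
    return TubeProfile()


@pytest.fixture(scope="session")
def blob_particle():
    return ParticleModel.gaussian_blob(sigma=45.0, voxel_size=PIXEL_SIZE,
                                       amplitude=1.0, attachment_offset=20.0)


@pytest.fixture(scope="session")
def cylinder_stack(small_profile):
    """360 noiseless aligned projections of the small tube at uniform phi."""
    img = render_tube_projection(small_profile, 64, PIXEL_SIZE)
    data = np.repeat(img.pixels[None], 360, axis=0)
    meta = empty_metadata(360)
    meta["psi_deg"] = 0.0
    meta["shift_x_px"] = 0.0
    meta["shift_y_px"] = 0.0
    meta["phi_deg"] = np.arange(360.0)
    meta["theta_deg"] = 90.0
    return ImageStack(data, PIXEL_SIZE, meta)


@pytest.fixture(scope="session")
def cylinder_average(cylinder_stack):
    return smooth_z(reconstruct(cylinder_stack, 64, wiener_frac=1e-4), 0.8)


@pytest.fixture(scope="session")
def bare_tube_run(default_profile):
    """Noiseless particle-free segments through align + average + subtract."""
    stack, truths = simulate_segments(30, 128, PIXEL_SIZE,
                                      profile=default_profile, seed=5)
    aligned = align_stack(stack, AlignConfig(seed=7))
    avg = smooth_z(reconstruct(aligned, 128, ring_average=True), 0.8)
    subtracted = subtract_stack(aligned, avg, refine=True,
                                remove_axial_residual=True)
    return {"stack": stack, "truths": truths, "aligned": aligned,
            "avg": avg, "subtracted": subtracted}


@pytest.fixture(scope="session")
def decorated_run(default_profile, blob_particle):
    """Noiseless decorated segments through align + average + subtract —
    the clean oracle for what subtraction does to particle signal."""
    stack, truths = simulate_segments(
        20, 192, PIXEL_SIZE, profile=default_profile, particle=blob_particle,
        particles_per_segment=1, seed=21)
    aligned = align_stack(stack, AlignConfig(seed=4))
    avg = smooth_z(reconstruct(aligned, 128, wiener_frac=1e-4,
                               ring_average=True), 0.8)
    subtracted = subtract_stack(aligned, avg, refine=True,
                                remove_axial_residual=True)
    return {"stack": stack, "truths": truths, "aligned": aligned,
            "avg": avg, "subtracted": subtracted}
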