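import numpy as np
import pytest

from rastr.azimuthal import (AzimuthalAverage, cylindricity, project,
                             radial_density_profile, reconstruct,
                             refine_against_average, smooth_z)
from rastr.formats import ImageStack, Volume3D, empty_metadata
from rastr.geometry import euler_matrix, image_center, rotate_image, shift_image
from rastr.synthtube import (abel_transform, inverse_abel, radial_profile,
                             render_tube_projection)

PS = 4.32


def _ncc(a, b, mask=None):
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))


def _analytic_cylinder(profile, n, pixel_size):
    c = image_center(n)
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
    r = np.hypot(xx - c, yy - c) * pixel_size
    return radial_profile(profile, r)


class TestReconstruct:
    def test_matches_analytic_body_of_revolution(self, cylinder_average,
                                                 small_profile):
        n = 64
        ref = _analytic_cylinder(small_profile, n, PS)
        c = image_center(n)
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        mask = (np.hypot(xx - c, yy - c) <= 0.4 * n) & (np.abs(zz - c) <= 0.4 * n)
        assert _ncc(cylinder_average.volume.voxels, ref, mask) >= 0.99

    def test_zero_images_give_zero_volume(self, cylinder_stack):
        zero = cylinder_stack.copy_with(data=np.zeros_like(cylinder_stack.data))
        avg = reconstruct(zero, 64)
        assert np.abs(avg.volume.voxels).max() == 0.0

    def test_linearity(self, cylinder_stack):
        sub = cylinder_stack.copy_with(
            data=cylinder_stack.data[:40].copy(),
            metadata=cylinder_stack.metadata.iloc[:40])
        a1 = reconstruct(sub, 64).volume.voxels
        scaled = sub.copy_with(data=3.0 * sub.data)
        a3 = reconstruct(scaled, 64).volume.voxels
        np.testing.assert_allclose(a3, 3.0 * a1, atol=1e-8 * np.abs(a1).max())

    def test_missing_angles_rejected(self, cylinder_stack):
        meta = cylinder_stack.metadata.drop(columns=["phi_deg"])
        broken = cylinder_stack.copy_with(metadata=meta)
        with pytest.raises(ValueError):
            reconstruct(broken, 64)

    def test_fourier_slice_consistency(self, cylinder_average, cylinder_stack):
        """The reconstruction's central section at a segment's orientation
        reproduces that segment's Fourier transform (noiseless, many
        views)."""
        vol = cylinder_average.volume.voxels
        img = cylinder_stack.data[0]
        proj = project(cylinder_average, 0.0, 90.0, 0.0).pixels
        # equality of projections implies equality of the central slices
        assert _ncc(proj, img) > 0.99


class TestSmoothZ:
    def test_z_invariant_fixed_point(self):
        vol = np.tile(np.random.default_rng(0).normal(size=(1, 16, 16)), (16, 1, 1))
        avg = AzimuthalAverage(Volume3D(vol, 1.0))
        out = smooth_z(avg, 0.8)
        np.testing.assert_allclose(out.volume.voxels, vol, atol=1e-12)

    def test_single_slice_spreads_as_mean(self):
        n = 10
        vol = np.zeros((n, n, n))
        vol[n // 2] = 5.0
        out = smooth_z(AzimuthalAverage(Volume3D(vol, 1.0)), 1.0)
        np.testing.assert_allclose(out.volume.voxels, 0.5, atol=1e-12)

    def test_linear_ramp_becomes_constant_mean(self):
        n = 16
        ramp = np.arange(n, dtype=float)[:, None, None] * np.ones((n, n, n))
        out = smooth_z(AzimuthalAverage(Volume3D(ramp, 1.0)), 1.0)
        np.testing.assert_allclose(out.volume.voxels, (n - 1) / 2, atol=1e-9)

    def test_invalid_fraction_rejected(self):
        avg = AzimuthalAverage(Volume3D(np.zeros((4, 4, 4)), 1.0))
        with pytest.raises(ValueError):
            smooth_z(avg, 0.0)


class TestCylindricity:
    def test_analytic_cylinder_is_nearly_perfect(self, small_profile):
        vol = _analytic_cylinder(small_profile, 64, PS)
        avg = AzimuthalAverage(Volume3D(vol, PS))
        assert cylindricity(avg) > 0.999

    def test_off_axis_blob_lowers_score(self, small_profile):
        vol = _analytic_cylinder(small_profile, 64, PS)
        c = image_center(64)
        zz, yy, xx = np.mgrid[0:64, 0:64, 0:64].astype(float)
        blob = vol.max() * np.exp(-((xx - c - 14) ** 2 + (yy - c) ** 2
                                    + (zz - c) ** 2) / (2 * 3.0**2))
        dirty = AzimuthalAverage(Volume3D(vol + blob, PS))
        clean = AzimuthalAverage(Volume3D(vol, PS))
        assert cylindricity(dirty) < cylindricity(clean) - 1e-4

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            cylindricity(AzimuthalAverage(Volume3D(np.zeros((8, 8, 8)), 1.0)))


class TestProject:
    def test_zero_volume_projects_to_zero(self):
        avg = AzimuthalAverage(Volume3D(np.zeros((32, 32, 32)), 1.0))
        assert np.abs(project(avg).pixels).max() == 0.0

    def test_phi_invariance_for_symmetric_volume(self, small_profile):
        """For an exactly z-invariant body of revolution, projections at
        any two azimuths agree to 0.1% RMS."""
        avg = AzimuthalAverage(Volume3D(_analytic_cylinder(small_profile, 64, PS), PS))
        a = project(avg, 0.0, 90.0, 0.0).pixels
        b = project(avg, 137.0, 90.0, 0.0).pixels
        assert np.sqrt(np.mean((a - b) ** 2)) / np.abs(a).max() < 1e-3

    def test_matches_rendered_tube(self, cylinder_average, small_profile):
        """Projection of the reconstructed cylinder at theta=90 equals the
        simulator's analytic tube image (NCC > 0.999 on the inscribed
        disc)."""
        n = 64
        c = image_center(n)
        yy, xx = np.mgrid[0:n, 0:n]
        disc = np.hypot(xx - c, yy - c) <= n / 2 - 1
        for psi in (0.0, 37.0):
            proj = project(cylinder_average, 0.0, 90.0, psi).pixels
            ref = render_tube_projection(small_profile, n, PS, psi).pixels
            assert _ncc(proj, ref, disc) > 0.999

    def test_shift_moves_projection_to_original_frame(self, cylinder_average):
        shifted = project(cylinder_average, 0.0, 90.0, 0.0, shift_x_px=5.0)
        unshifted = project(cylinder_average, 0.0, 90.0, 0.0)
        # shift_x is the alignment correction, so overlaying the original
        # means translating by -shift_x
        back = shift_image(unshifted.pixels, -5.0, 0.0)
        assert _ncc(shifted.pixels[:, 8:-8], back[:, 8:-8]) > 0.999


class TestInverseAbelConsistency:
    def test_volume_profile_matches_inverse_abel_of_projection(
            self, cylinder_average, cylinder_stack):
        """Radial profile of the reconstruction vs the inverse Abel
        transform of the mean aligned projection: < 2% RMS over the
        shells."""
        n = 64
        c = image_center(n)
        mean_proj = cylinder_stack.data.mean(axis=0).mean(axis=0)
        x = (np.arange(n) - c) * PS
        half = x >= 0
        P = 0.5 * (mean_proj[half] + mean_proj[::-1][half])
        r_test = np.arange(4.0, 80.0, 2.0)
        g_img = inverse_abel(P, x[half], r_test)
        _, g_vol = radial_density_profile(cylinder_average.volume, r_test / PS)
        scale = np.dot(g_vol, g_img) / np.dot(g_vol, g_vol)
        rms = np.sqrt(np.mean((scale * g_vol - g_img) ** 2)) / np.abs(g_img).max()
        assert rms < 0.02


class TestRefineAgainstAverage:
    def test_fixed_point_on_converged_stack(self, cylinder_stack, cylinder_average):
        sub = cylinder_stack.copy_with(
            data=cylinder_stack.data[:20].copy(),
            metadata=cylinder_stack.metadata.iloc[:20])
        _, rep = refine_against_average(sub, cylinder_average)
        assert rep["mean_abs_dpsi_deg"] < 0.1
        assert rep["mean_abs_dshift_px"] < 0.25

    def test_recovers_perturbed_psi(self, cylinder_stack, cylinder_average):
        n = 10
        rng = np.random.default_rng(0)
        pert = rng.uniform(-2.0, 2.0, n)
        data = np.stack([rotate_image(cylinder_stack.data[i], pert[i])
                         for i in range(n)])
        meta = cylinder_stack.metadata.iloc[:n].copy()
        stack = ImageStack(data, PS, meta)
        refined, _ = refine_against_average(stack, cylinder_average)
        err = np.abs(((refined.metadata["psi_deg"].to_numpy() - pert + 90) % 180) - 90)
        assert err.max() < 0.3

    def test_idempotent_after_convergence(self, cylinder_stack, cylinder_average):
        sub = cylinder_stack.copy_with(
            data=cylinder_stack.data[:10].copy(),
            metadata=cylinder_stack.metadata.iloc[:10])
        once, _ = refine_against_average(sub, cylinder_average)
        twice, rep = refine_against_average(once, cylinder_average)
        assert rep["mean_abs_dpsi_deg"] < 0.1
        np.testing.assert_allclose(twice.metadata["psi_deg"],
                                   once.metadata["psi_deg"], atol=0.2)
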