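import numpy as np
import pytest
from scipy.integrate import quad

from rastr.formats import Image2D
from rastr.geometry import image_center
from rastr.synthtube import (ParticleModel, ParticlePlacement, TubeProfile,
                             abel_transform, add_noise, apply_ctf, ctf_1d,
                             electron_wavelength, inverse_abel, radial_profile,
                             render_decorated_segment, render_tube_projection,
                             simulate_micrograph, simulate_segments)

PS = 4.32


class TestRadialProfile:
    def test_closed_form_at_outer_shell(self, small_profile):
        p = small_profile
        expected = p.amplitude * (1 + np.exp(-p.bilayer_separation**2
                                             / (2 * p.shell_sigma**2)))
        assert radial_profile(p, np.array([p.outer_radius]))[0] == \
            pytest.approx(expected, rel=1e-12)

    def test_vanishes_far_from_shells(self, small_profile):
        assert radial_profile(small_profile, np.array([1e4]))[0] < 1e-30

    def test_mass_integral_matches_quadrature(self, small_profile):
        """2*pi*r*g(r) integrated numerically on a fine grid agrees with
        adaptive quadrature to 0.1%."""
        r = np.linspace(0, 200, 20001)
        trapz = np.trapezoid(2 * np.pi * r * radial_profile(small_profile, r), r)
        exact, _ = quad(lambda x: 2 * np.pi * x
                        * float(radial_profile(small_profile, np.array([x]))[0]),
                        0, 200, limit=200)
        assert trapz == pytest.approx(exact, rel=1e-3)


class TestTubeProjection:
    def test_vertical_tube_is_column_constant_and_symmetric(self, small_profile):
        img = render_tube_projection(small_profile, 64, PS).pixels
        assert np.ptp(img, axis=0).max() < 1e-9 * img.max()
        np.testing.assert_allclose(img, img[:, ::-1], rtol=1e-9)

    def test_matches_voxel_raysum_oracle(self, small_profile):
        """Projection equals the brute-force ray sum through a voxelized
        3D cylinder (NCC > 0.999)."""
        n = 64
        c = image_center(n)
        # cylinder with axis along y; integrate along the viewing axis d
        d, yy, xx = np.mgrid[0:4 * n, 0:n, 0:n].astype(float)
        r = np.hypot((xx - c), (d / 4.0 - 2 * n / 4.0)) * PS  # d sampled at 1/4 px
        oracle = radial_profile(small_profile, r).sum(axis=0) * (PS / 4)
        img = render_tube_projection(small_profile, n, PS).pixels
        a, b = img.ravel() - img.mean(), oracle.ravel() - oracle.mean()
        assert (a @ b) / np.sqrt((a @ a) * (b @ b)) > 0.999

    def test_psi90_is_transpose_of_psi0(self, small_profile):
        img0 = render_tube_projection(small_profile, 65, PS, psi_deg=0).pixels
        img90 = render_tube_projection(small_profile, 65, PS, psi_deg=90).pixels
        np.testing.assert_allclose(img90, img0.T, atol=1e-9 * img0.max())

    def test_tube_wider_than_field_rejected(self, default_profile):
        with pytest.raises(ValueError):
            render_tube_projection(default_profile, 32, PS)

    def test_mean_profile_matches_abel_transform(self, small_profile):
        """The column-mean of the noiseless projection equals the analytic
        Abel transform of the radial profile (0.5% RMS)."""
        n = 64
        img = render_tube_projection(small_profile, n, PS).pixels
        x = np.abs(np.arange(n) - image_center(n)) * PS
        P = abel_transform(small_profile, x)
        rms = np.sqrt(np.mean((img.mean(axis=0) - P) ** 2)) / P.max()
        assert rms < 0.005


class TestInverseAbel:
    def test_recovers_radial_profile(self, small_profile):
        x = np.arange(0, 140, 1.0)
        P = abel_transform(small_profile, x)
        r = np.arange(4, 90, 2.0)
        g = inverse_abel(P, x, r)
        gt = radial_profile(small_profile, r)
        assert np.sqrt(np.mean((g - gt) ** 2)) / gt.max() < 0.01


class TestDecoratedSegment:
    def test_no_particles_reduces_to_tube(self, small_profile):
        img, truth = render_decorated_segment(small_profile, None, [], 64, PS)
        tube = render_tube_projection(small_profile, 64, PS)
        np.testing.assert_array_equal(img.pixels, tube.pixels)
        assert truth.particles == []

    def test_front_particle_projects_onto_axis(self, default_profile, blob_particle):
        _, truth = render_decorated_segment(
            default_profile, blob_particle, [ParticlePlacement(10.0, 0.0)], 192, PS)
        x, y = truth.particle_xy_px[0]
        c = image_center(192)
        assert x == pytest.approx(c, abs=1e-9)
        assert y == pytest.approx(c + 10.0, abs=1e-9)

    def test_side_particle_offset_is_decoration_radius(self, default_profile,
                                                       blob_particle):
        _, truth = render_decorated_segment(
            default_profile, blob_particle, [ParticlePlacement(0.0, 90.0)], 192, PS)
        x, _ = truth.particle_xy_px[0]
        expected = (default_profile.outer_radius
                    + blob_particle.attachment_offset) / PS
        assert x - image_center(192) == pytest.approx(expected, abs=1e-6)

    def test_out_of_field_particle_rejected(self, default_profile, blob_particle):
        with pytest.raises(ValueError):
            render_decorated_segment(default_profile, blob_particle,
                                     [ParticlePlacement(90.0, 90.0)], 192, PS)

    def test_every_particle_recorded_once(self, default_profile, blob_particle):
        placements = [ParticlePlacement(-50.0, 10.0), ParticlePlacement(0.0, 200.0),
                      ParticlePlacement(50.0, 355.0)]
        _, truth = render_decorated_segment(default_profile, blob_particle,
                                            placements, 192, PS)
        assert truth.particles == placements
        assert len(truth.particle_xy_px) == 3


class TestNoise:
    def test_zero_sigma_is_identity(self):
        img = Image2D(np.ones((32, 32)), 1.0)
        np.testing.assert_array_equal(add_noise(img, 0.0, 1).pixels, img.pixels)

    def test_seed_determinism(self):
        img = Image2D(np.zeros((64, 64)), 1.0)
        a = add_noise(img, 1.0, 42).pixels
        b = add_noise(img, 1.0, 42).pixels
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, add_noise(img, 1.0, 43).pixels)

    def test_realized_sigma_matches_request(self):
        img = Image2D(np.zeros((256, 256)), 1.0)
        out = add_noise(img, 3.0, 7)
        assert out.pixels.std() == pytest.approx(3.0, rel=0.02)


class TestCtf:
    def test_unit_ctf_preserves_image(self, small_profile):
        """With amplitude contrast 1 and tiny defocus the CTF is ~cos(chi)~1
        at all represented frequencies of a smooth image."""
        img = render_tube_projection(small_profile, 64, PS)
        out = apply_ctf(img, defocus=1.0, amplitude_contrast=1.0)
        assert np.corrcoef(out.pixels.ravel(), img.pixels.ravel())[0, 1] > 0.9999

    def test_power_never_amplified(self, small_profile):
        img = render_tube_projection(small_profile, 64, PS)
        out = apply_ctf(img, defocus=15000.0)
        assert np.sum(out.pixels**2) <= np.sum(img.pixels**2) + 1e-9

    @pytest.mark.parametrize("defocus", [8000.0, 15000.0, 30000.0])
    def test_first_zero_scaling(self, defocus):
        """First zero crossing follows k0 = sqrt(1/(lambda*defocus)) (2%)."""
        k = np.linspace(1e-4, 0.2, 200001)
        c = ctf_1d(k, defocus, amplitude_contrast=0.0)
        k0 = k[np.flatnonzero(np.diff(np.sign(c)))[0]]
        lam = electron_wavelength(300.0)
        assert k0 == pytest.approx(np.sqrt(1 / (lam * defocus)), rel=0.02)


class TestSimulators:
    def test_seed_reproducibility(self, small_profile):
        a, _ = simulate_segments(3, 64, PS, profile=small_profile, snr=0.5, seed=9)
        b, _ = simulate_segments(3, 64, PS, profile=small_profile, snr=0.5, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_metadata_and_pixel_size(self, small_profile):
        stack, truths = simulate_segments(10, 128, 1.44,
                                          profile=small_profile, seed=3)
        assert len(stack.metadata) == 10
        assert stack.pixel_size == 1.44
        assert len(truths) == 10

    def test_micrograph_segments_share_pixels(self, default_profile):
        mic, stack, _ = simulate_micrograph((300, 600), 128, 64, PS,
                                            profile=default_profile, seed=1)
        meta = stack.metadata
        x0 = int(meta["origin_x"][0] - image_center(128))
        y0 = int(meta["origin_y"][0] - image_center(128))
        np.testing.assert_array_equal(stack.data[0],
                                      mic.pixels[y0:y0 + 128, x0:x0 + 128])
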