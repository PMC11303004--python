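"""Synthetic decorated-nanotube simulator.

Generates 2D projections of a lipid-bilayer nanotube sparsely decorated
with globular particles, with known ground truth for every image, so each
downstream stage (alignment, azimuthal averaging, subtraction, picking) can
be validated without real data.

The tube is modelled as a body of revolution: two concentric Gaussian
density shells (the bilayer leaflets) whose radial profile is

    g(r) = A * [exp(-(r - r_out)^2 / 2 sigma^2) + exp(-(r - r_in)^2 / 2 sigma^2)]

with ``r_in = r_out - bilayer_separation``.  Its 2D projection perpendicular
to the tube axis is the Abel transform ``P(x) = 2 * integral g(sqrt(x^2+s^2)) ds``,
constant along the axis.  Particles are small 3D density grids attached a
fixed gap above the tube surface at random axial/azimuthal positions and
rendered by rotating and ray-summing the grid.

Default dimensions follow the experimental system: tubes ~27.5 nm wide
imaged at 1.44 A/pixel, decorated with a ~465 kDa globular particle.  Tests
use explicitly smaller geometries (binned pixel sizes) for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .formats import Image2D, ImageStack, Volume3D, empty_metadata
from .geometry import image_center, rotate_image

__all__ = [
    "TubeProfile",
    "ParticleModel",
    "ParticlePlacement",
    "TubeGroundTruth",
    "radial_profile",
    "abel_transform",
    "inverse_abel",
    "render_tube_projection",
    "render_decorated_segment",
    "add_noise",
    "apply_ctf",
    "noise_sigma_for_snr",
    "simulate_segments",
    "simulate_micrograph",
]


@dataclass(frozen=True)
class TubeProfile:
    """Radial density model of the bilayer tube (all lengths in Angstrom)."""

    outer_radius: float = 137.5
    bilayer_separation: float = 35.0
    shell_sigma: float = 7.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not (self.outer_radius > self.bilayer_separation > 0):
            raise ValueError("require outer_radius > bilayer_separation > 0")
        if self.shell_sigma <= 0:
            raise ValueError("shell_sigma must be positive")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.bilayer_separation


@dataclass(frozen=True)
class ParticleModel:
    """Globular decoration density plus its gap above the tube surface."""

    density: Volume3D
    attachment_offset: float = 20.0  # Angstrom between tube surface and particle center

    def __post_init__(self) -> None:
        vox = self.density.voxels
        if vox.min() < 0:
            raise ValueError("particle density must be non-negative")
        n = self.density.size
        margin = np.zeros_like(vox, dtype=bool)
        margin[2:n - 2, 2:n - 2, 2:n - 2] = True
        if vox[~margin].max() > 1e-6 * max(vox.max(), 1e-300):
            raise ValueError("particle density must fit its grid with a 2-voxel margin")

    @classmethod
    def gaussian_blob(cls, sigma: float = 45.0, voxel_size: float = 1.44,
                      amplitude: float = 1.0, attachment_offset: float = 20.0,
                      n: int | None = None) -> "ParticleModel":
        """Spherical Gaussian blob of the given sigma (Angstrom)."""
        if n is None:
            n = int(np.ceil(6 * sigma / voxel_size)) | 1
        c = image_center(n)
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
        vox = amplitude * np.exp(-r2 * voxel_size**2 / (2 * sigma**2))
        vox[r2 > ((n - 1) / 2 - 2.5) ** 2] = 0.0  # compact support inside the grid
        return cls(Volume3D(vox, voxel_size), attachment_offset)

    @classmethod
    def two_lobe(cls, sigma: float = 30.0, lobe_separation: float = 80.0,
                 voxel_size: float = 1.44, amplitude: float = 1.0,
                 attachment_offset: float = 20.0) -> "ParticleModel":
        """Dumbbell test shape: two Gaussian lobes along the grid x axis."""
        n = int(np.ceil((lobe_separation + 7 * sigma) / voxel_size)) | 1
        c = image_center(n)
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
        half = lobe_separation / (2 * voxel_size)
        vox = np.zeros((n, n, n))
        for s in (-half, half):
            r2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c - s) ** 2
            vox += amplitude * np.exp(-r2 * voxel_size**2 / (2 * sigma**2))
        rc2 = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2
        vox[rc2 > ((n - 1) / 2 - 2.5) ** 2] = 0.0  # compact support inside the grid
        return cls(Volume3D(vox, voxel_size), attachment_offset)


@dataclass(frozen=True)
class ParticlePlacement:
    """One particle on the tube: axial position (px from image center along
    the axis), azimuth (deg around the tube axis; 0 = toward the viewer,
    90 = toward +x after the psi rotation), and in-plane rotation (deg)."""

    axial_pos_px: float
    azimuth_deg: float
    in_plane_rot_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "azimuth_deg", float(self.azimuth_deg) % 360.0)


@dataclass
class TubeGroundTruth:
    """Everything the simulator knows about one rendered segment."""

    psi_true_deg: float
    center_offset_px: float
    particles: list[ParticlePlacement] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int | None = None
    particle_xy_px: list[tuple[float, float]] = field(default_factory=list)
    #: noiseless particle-only layer (decoration minus tube), for oracles
    particle_layer: np.ndarray | None = None


def radial_profile(profile: TubeProfile, r: np.ndarray) -> np.ndarray:
    """Analytic two-shell radial density g(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radii must be non-negative")
    s2 = 2 * profile.shell_sigma**2
    return profile.amplitude * (
        np.exp(-((r - profile.outer_radius) ** 2) / s2)
        + np.exp(-((r - profile.inner_radius) ** 2) / s2)
    )


def abel_transform(profile: TubeProfile, x: np.ndarray, ds: float = 0.5) -> np.ndarray:
    """Perpendicular projection P(x) = 2 * integral_0^inf g(sqrt(x^2+s^2)) ds.

    ``x`` and the quadrature step ``ds`` are in Angstrom.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    s_max = profile.outer_radius + 8 * profile.shell_sigma
    s = np.arange(0.0, s_max, ds)
    r = np.sqrt(x[:, None] ** 2 + s[None, :] ** 2)
    g = radial_profile(profile, r)
    return 2.0 * np.trapezoid(g, dx=ds, axis=1)


def inverse_abel(P: np.ndarray, x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Recover g(r) from a sampled symmetric projection P(|x|).

    Uses g(r) = -(1/pi) * integral_0^inf P'(sqrt(r^2+t^2)) / sqrt(r^2+t^2) dt
    (the substitution t = sqrt(x^2-r^2) removes the endpoint singularity).
    """
    from scipy.interpolate import CubicSpline

    x = np.asarray(x, dtype=float)
    P = np.asarray(P, dtype=float)
    dP = CubicSpline(x, P).derivative()
    t = np.arange(0.0, x.max(), 0.1)
    out = np.empty(len(np.atleast_1d(r)))
    for i, ri in enumerate(np.atleast_1d(r)):
        xi = np.sqrt(ri**2 + t**2)
        integrand = np.where(xi <= x.max(), dP(np.clip(xi, x.min(), x.max()))
                             / np.maximum(xi, 1e-12), 0.0)
        out[i] = -np.trapezoid(integrand, t) / np.pi
    return out


def _axis_vectors(psi_deg: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.deg2rad(psi_deg)
    u = np.array([np.sin(t), np.cos(t)])    # along-axis direction, (x, y)
    nv = np.array([np.cos(t), -np.sin(t)])  # perpendicular direction
    return u, nv


def render_tube_projection(profile: TubeProfile, image_size: int, pixel_size: float,
                           psi_deg: float = 0.0, center_offset_px: float = 0.0) -> Image2D:
    """Noiseless projection of the tube at in-plane angle psi.

    The image value at each pixel is the analytic Abel transform evaluated
    at that pixel's perpendicular distance from the tube axis, which makes
    the projection exact for arbitrary psi (no interpolation).
    """
    if 2 * profile.outer_radius / pixel_size > image_size:
        raise ValueError("tube diameter exceeds the field of view")
    if abs(center_offset_px) >= image_size / 2:
        raise ValueError("center offset places the tube outside the field")
    c = image_center(image_size)
    u, nv = _axis_vectors(psi_deg)
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    d_px = (xx - c - center_offset_px * nv[0]) * nv[0] + (yy - c - center_offset_px * nv[1]) * nv[1]
    d = np.abs(d_px) * pixel_size
    grid = np.arange(0.0, d.max() + 2 * pixel_size, min(pixel_size, 2.0) / 4)
    P = abel_transform(profile, grid)
    return Image2D(np.interp(d, grid, P), pixel_size)


def _particle_stamp(particle: ParticleModel, pixel_size: float,
                    azimuth_deg: float, rot2d_deg: float) -> np.ndarray:
    """Projected particle image: rotate the density grid about the tube-axis
    (y) direction by the azimuth, ray-sum along the viewing axis, then apply
    the in-plane rotation."""
    vox = particle.density.voxels
    if abs(particle.density.voxel_size - pixel_size) > 1e-9:
        zoom = particle.density.voxel_size / pixel_size
        vox = ndimage.zoom(vox, zoom, order=1)
    if azimuth_deg % 360.0 != 0.0:
        vox = ndimage.rotate(vox, azimuth_deg, axes=(0, 2), reshape=False, order=1)
    stamp = vox.sum(axis=0) * pixel_size  # integral along the viewing ray
    if rot2d_deg % 360.0 != 0.0:
        stamp = rotate_image(stamp, rot2d_deg, order=1)
    return stamp


def render_decorated_segment(
    profile: TubeProfile,
    particle: ParticleModel | None,
    placements: list[ParticlePlacement],
    image_size: int,
    pixel_size: float,
    psi_deg: float = 0.0,
    center_offset_px: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    min_axial_spacing_px: float = 0.0,
    invert_contrast: bool = False,
) -> tuple[Image2D, TubeGroundTruth]:
    """Render one tube segment with particles; returns image + ground truth.

    Particle centers sit at radial distance ``outer_radius +
    attachment_offset`` from the axis, so a particle at azimuth ``a``
    projects at perpendicular offset ``R * sin(a)`` pixels from the axis
    line and retains its axial position along the axis.
    """
    if placements and particle is None:
        raise ValueError("placements given without a particle model")
    axial = sorted(p.axial_pos_px for p in placements)
    for a, b in zip(axial, axial[1:]):
        if b - a < min_axial_spacing_px:
            raise ValueError("particle placements violate the minimum axial spacing")
    img = render_tube_projection(profile, image_size, pixel_size, psi_deg, center_offset_px)
    pixels = img.pixels
    c = image_center(image_size)
    u, nv = _axis_vectors(psi_deg)
    truth = TubeGroundTruth(psi_true_deg=psi_deg % 180.0, center_offset_px=center_offset_px,
                            noise_sigma=noise_sigma, seed=seed)
    layer = np.zeros_like(pixels)
    r_px = (profile.outer_radius + particle.attachment_offset) / pixel_size if particle else 0.0
    for pl in placements:
        perp = center_offset_px + r_px * np.sin(np.deg2rad(pl.azimuth_deg))
        pos = np.array([c, c]) + pl.axial_pos_px * u + perp * nv  # (x, y)
        stamp = _particle_stamp(particle, pixel_size, pl.azimuth_deg,
                                pl.in_plane_rot_deg + psi_deg)
        _add_stamp(layer, stamp, pos[0], pos[1])
        truth.particles.append(pl)
        truth.particle_xy_px.append((float(pos[0]), float(pos[1])))
    pixels = pixels + layer
    if invert_contrast:
        pixels = -pixels
        layer = -layer
    truth.particle_layer = layer
    out = Image2D(pixels, pixel_size)
    if noise_sigma > 0:
        out = add_noise(out, noise_sigma, seed)
    return out, truth


def _add_stamp(pixels: np.ndarray, stamp: np.ndarray, x: float, y: float) -> None:
    """Add a small image into ``pixels`` centered at (x, y) with subpixel
    placement; raises if the stamp support would be clipped."""
    m = stamp.shape[0]
    cs = image_center(m)
    fx, fy = x - np.floor(x), y - np.floor(y)
    if fx or fy:
        stamp = ndimage.shift(stamp, (fy, fx), order=1, mode="constant")
    x0 = int(np.floor(x) - np.floor(cs))
    y0 = int(np.floor(y) - np.floor(cs))
    ny, nx = pixels.shape
    if x0 < 0 or y0 < 0 or x0 + m > nx or y0 + m > ny:
        raise ValueError("particle projects outside the field of view")
    pixels[y0:y0 + m, x0:x0 + m] += stamp


def add_noise(img: Image2D, sigma: float, seed: int | None = None) -> Image2D:
    """Additive white Gaussian noise, deterministic under ``seed``."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return Image2D(img.pixels.copy(), img.pixel_size)
    rng = np.random.default_rng(seed)
    return Image2D(img.pixels + rng.normal(0.0, sigma, img.pixels.shape), img.pixel_size)


def noise_sigma_for_snr(signal: np.ndarray, snr: float,
                        support: np.ndarray | None = None) -> float:
    """Noise sigma giving SNR = var(signal) / var(noise).

    With ``support`` (boolean mask), the signal variance is measured over
    the signal's own support — the conventional definition for simulated
    particles, where the relevant contrast is that of the object to be
    detected, not of the whole field."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    values = signal[support] if support is not None else signal
    return float(np.sqrt(np.var(values) / snr))


def electron_wavelength(voltage_kV: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kV * 1e3
    return 12.2643 / np.sqrt(v * (1 + v * 0.978466e-6))


def ctf_1d(k: np.ndarray, defocus: float, voltage_kV: float = 300.0,
           amplitude_contrast: float = 0.07, cs_mm: float = 0.0) -> np.ndarray:
    """Contrast transfer function over spatial frequency k (1/Angstrom)."""
    lam = electron_wavelength(voltage_kV)
    chi = np.pi * lam * defocus * k**2 - 0.5 * np.pi * (cs_mm * 1e7) * lam**3 * k**4
    a = amplitude_contrast
    return np.sqrt(1 - a**2) * np.sin(chi) + a * np.cos(chi)


def apply_ctf(img: Image2D, defocus: float, voltage_kV: float = 300.0,
              amplitude_contrast: float = 0.07, cs_mm: float = 0.0) -> Image2D:
    """Multiply the image by the CTF in Fourier space (phase-flipping model
    of the microscope's frequency response; positive defocus = underfocus)."""
    if defocus <= 0:
        raise ValueError("defocus must be positive")
    ny, nx = img.pixels.shape
    ky = np.fft.fftfreq(ny, d=img.pixel_size)
    kx = np.fft.fftfreq(nx, d=img.pixel_size)
    k = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    ctf = ctf_1d(k, defocus, voltage_kV, amplitude_contrast, cs_mm)
    out = np.fft.ifft2(np.fft.fft2(img.pixels) * ctf).real
    return Image2D(out, img.pixel_size)


def _random_placements(rng: np.random.Generator, n: int, half_axial_px: float,
                       min_spacing_px: float) -> list[ParticlePlacement]:
    """Axial positions uniform on the ordered set with a minimum spacing
    (spacing plus sorted slack offsets); azimuth and in-plane rotation
    uniform."""
    half = half_axial_px
    axial = _spaced_uniform(rng, n, -half, half, min_spacing_px)
    return [
        ParticlePlacement(a, rng.uniform(0, 360), rng.uniform(0, 360))
        for a in axial
    ]


def _spaced_uniform(rng: np.random.Generator, n: int, lo: float, hi: float,
                    min_spacing: float) -> np.ndarray:
    """n sorted positions uniform on {lo <= x_1 < ... < x_n <= hi,
    x_{i+1} - x_i >= min_spacing}."""
    if n == 0:
        return np.empty(0)
    slack = (hi - lo) - (n - 1) * min_spacing
    if slack < 0:
        raise ValueError("could not place particles with the requested spacing")
    u = np.sort(rng.uniform(0.0, slack, n))
    return lo + np.arange(n) * min_spacing + u


def simulate_segments(
    n_segments: int,
    image_size: int,
    pixel_size: float,
    profile: TubeProfile | None = None,
    particle: ParticleModel | None = None,
    particles_per_segment: int = 0,
    snr: float | None = None,
    noise_sigma: float | None = None,
    psi_range: tuple[float, float] = (0.0, 180.0),
    max_center_offset_px: float = 5.0,
    min_axial_spacing_px: float = 30.0,
    defocus: float | None = None,
    seed: int = 0,
) -> tuple[ImageStack, list[TubeGroundTruth]]:
    """Independent decorated segments with random psi/offset/decoration.

    ``snr`` sets the noise level as var(noiseless signal)/var(noise) per
    segment; ``noise_sigma`` overrides it with an absolute level.
    """
    if n_segments <= 0:
        raise ValueError("n_segments must be positive")
    profile = profile or TubeProfile()
    rng = np.random.default_rng(seed)
    stamp_half = 0.0
    perp_max = 0.0
    if particle is not None and particles_per_segment > 0:
        stamp_half = ((particle.density.size - 1) / 2
                      * particle.density.voxel_size / pixel_size)
        perp_max = ((profile.outer_radius + particle.attachment_offset) / pixel_size
                    + max_center_offset_px)
    data = np.empty((n_segments, image_size, image_size))
    truths: list[TubeGroundTruth] = []
    for i in range(n_segments):
        psi = rng.uniform(*psi_range)
        offset = rng.uniform(-max_center_offset_px, max_center_offset_px)
        if particles_per_segment:
            # keep every particle stamp inside the frame for any azimuth:
            # |t*sin(psi)| + perp*|cos(psi)| and the y analogue must stay
            # within half the box minus the stamp radius
            b = image_size / 2 - stamp_half - 2
            s, c_ = abs(np.sin(np.deg2rad(psi))), abs(np.cos(np.deg2rad(psi)))
            half_ax = min((b - perp_max * c_) / max(s, 1e-6),
                          (b - perp_max * s) / max(c_, 1e-6))
            if half_ax <= 0:
                raise ValueError("segment too small for the decoration geometry")
            placements = _random_placements(rng, particles_per_segment, half_ax,
                                            min_axial_spacing_px)
        else:
            placements = []
        img, truth = render_decorated_segment(
            profile, particle, placements, image_size, pixel_size,
            psi_deg=psi, center_offset_px=offset,
            min_axial_spacing_px=0.0,
        )
        truth.psi_true_deg = psi % 180.0
        if defocus is not None:
            img = apply_ctf(img, defocus)
        sigma = noise_sigma
        if sigma is None and snr is not None:
            layer = truth.particle_layer
            if layer is not None and np.any(layer):
                support = np.abs(layer) > 0.02 * np.abs(layer).max()
                sigma = noise_sigma_for_snr(layer, snr, support)
            else:
                sigma = noise_sigma_for_snr(img.pixels, snr)
        if sigma:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            img = add_noise(img, sigma, sub_seed)
            truth.noise_sigma = sigma
            truth.seed = sub_seed
        data[i] = img.pixels
        truths.append(truth)
    meta = empty_metadata(n_segments)
    meta["micrograph_id"] = [f"synth_{i:05d}" for i in range(n_segments)]
    meta["origin_x"] = image_center(image_size)
    meta["origin_y"] = image_center(image_size)
    return ImageStack(data, pixel_size, meta), truths


def simulate_micrograph(
    micrograph_shape: tuple[int, int],
    segment_size: int,
    segment_step: int,
    pixel_size: float,
    profile: TubeProfile | None = None,
    particle: ParticleModel | None = None,
    n_particles: int = 0,
    psi_deg: float = 90.0,
    snr: float | None = None,
    min_axial_spacing_px: float = 30.0,
    seed: int = 0,
    micrograph_id: str = "synth_micrograph",
) -> tuple[Image2D, ImageStack, pd.DataFrame]:
    """One straight tube across a rectangular micrograph, cut into
    overlapping square segments along the axis.

    The same physical particle therefore appears in several segments —
    exactly the situation duplicate elimination must resolve.  Returns the
    micrograph, the segment stack (with segment-center origins recorded in
    the metadata), and a table of true global particle coordinates.
    """
    profile = profile or TubeProfile()
    ny, nx = micrograph_shape
    rng = np.random.default_rng(seed)
    # Render the tube on the full rectangular field: axis through the
    # micrograph center at angle psi (measured from vertical).
    u, nv = _axis_vectors(psi_deg)
    cx, cy = image_center(nx), image_center(ny)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    d_px = (xx - cx) * nv[0] + (yy - cy) * nv[1]
    grid = np.arange(0.0, np.abs(d_px).max() * pixel_size + 2 * pixel_size, 0.5)
    P = abel_transform(profile, grid)
    pixels = np.interp(np.abs(d_px) * pixel_size, grid, P)
    # Particles along the axis.
    half_len = 0.5 * np.hypot(nx * u[0], ny * u[1])
    margin = segment_size / 2.0
    if particle is not None:
        margin = max(margin, particle.density.size / 2 + 4)
    truth_rows = []
    r_px = (profile.outer_radius + particle.attachment_offset) / pixel_size if particle else 0.0
    axial = _spaced_uniform(rng, n_particles, -(half_len - margin),
                            half_len - margin, min_axial_spacing_px)
    layer = np.zeros_like(pixels)
    for a in axial:
        az = rng.uniform(0, 360)
        rot = rng.uniform(0, 360)
        perp = r_px * np.sin(np.deg2rad(az))
        pos = np.array([cx, cy]) + a * u + perp * nv
        stamp = _particle_stamp(particle, pixel_size, az, rot + psi_deg)
        _add_stamp(layer, stamp, pos[0], pos[1])
        truth_rows.append({"micrograph_id": micrograph_id, "axial_pos_px": a,
                           "azimuth_deg": az, "global_x": pos[0], "global_y": pos[1]})
    pixels = pixels + layer
    if snr is not None:
        if np.any(layer):
            support = np.abs(layer) > 0.02 * np.abs(layer).max()
            sigma = noise_sigma_for_snr(layer, snr, support)
        else:
            sigma = noise_sigma_for_snr(pixels, snr)
        pixels = pixels + rng.normal(0.0, sigma, pixels.shape)
    micrograph = Image2D(pixels, pixel_size)
    # Cut square segments centered on the axis at a fixed stride.
    half_seg = segment_size / 2.0
    centers = []
    t = -(half_len - half_seg)
    while t <= half_len - half_seg + 1e-9:
        pos = np.array([cx, cy]) + t * u
        x0, y0 = int(round(pos[0] - (segment_size - 1) / 2)), int(round(pos[1] - (segment_size - 1) / 2))
        if 0 <= x0 and 0 <= y0 and x0 + segment_size <= nx and y0 + segment_size <= ny:
            centers.append((x0, y0))
        t += segment_step
    if not centers:
        raise ValueError("no segment window fits the micrograph")
    data = np.stack([pixels[y0:y0 + segment_size, x0:x0 + segment_size]
                     for x0, y0 in centers])
    meta = empty_metadata(len(centers))
    meta["micrograph_id"] = micrograph_id
    meta["origin_x"] = [x0 + image_center(segment_size) for x0, _ in centers]
    meta["origin_y"] = [y0 + image_center(segment_size) for _, y0 in centers]
    stack = ImageStack(data, pixel_size, meta)
    return micrograph, stack, pd.DataFrame(truth_rows)
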