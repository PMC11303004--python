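"""Tube-signal subtraction.

For each segment the azimuthal average is projected back at that segment's
orientation and subtracted from the original image with a per-segment
least-squares intensity scale: alpha = argmin ||img - alpha * proj||^2,
fitted only over the tube mask (pixels where the projection carries
signal) so off-tube particles do not bias the fit, but applied to the
whole frame.  What remains is the decoration — plus noise — with the
membrane erased; the subtracted stack is then treated as a set of small
micrographs by the picking stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .azimuthal import AzimuthalAverage, project
from .formats import Image2D, ImageStack
from .geometry import image_center, rotate_image


def _remove_axial_profile(pixels: np.ndarray, psi_deg: float) -> np.ndarray:
    """Subtract the axially invariant component of a subtracted segment:
    the per-column median in the aligned (axis-vertical) frame, mapped
    back through the perpendicular-distance coordinate."""
    n = pixels.shape[0]
    c = image_center(n)
    rot = rotate_image(pixels, -psi_deg, order=1)
    prof = np.median(rot, axis=0)
    t = np.deg2rad(psi_deg)
    nv = (np.cos(t), -np.sin(t))
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    d = (xx - c) * nv[0] + (yy - c) * nv[1]
    return pixels - np.interp(d + c, np.arange(n), prof)

__all__ = ["SubtractionResult", "subtract_segment", "subtract_stack"]


@dataclass
class SubtractionResult:
    subtracted: Image2D
    scale_alpha: float
    residual_rms_in_mask: float


def tube_mask(proj: np.ndarray, mask_frac: float = 0.1) -> np.ndarray:
    """Pixels where the projection magnitude exceeds ``mask_frac`` of its
    maximum magnitude — the region used to fit alpha."""
    peak = np.abs(proj).max()
    return np.abs(proj) > mask_frac * peak


def subtract_segment(img: Image2D, proj: Image2D,
                     mask_frac: float = 0.1,
                     robust: bool = True) -> SubtractionResult:
    """Least-squares scaled subtraction of one projected tube model.

    With ``robust=True`` (default) the scale fit is repeated after
    clipping strong outliers from the fit region, so bright particles
    sitting on the tube do not inflate alpha.
    """
    if img.pixels.shape != proj.pixels.shape:
        raise ValueError("image and projection shapes differ")
    p = proj.pixels
    peak = np.abs(p).max()
    if peak <= 0 or not np.any(np.abs(p) > 1e-12 * max(peak, 1e-300)):
        raise ValueError("projection is (near) zero: nothing to subtract")
    mask = tube_mask(p, mask_frac)
    pm = p[mask]
    im = img.pixels[mask]
    alpha = float(np.dot(im, pm) / np.dot(pm, pm))
    if robust:
        for _ in range(2):
            r = im - alpha * pm
            keep = np.abs(r) <= 2.5 * max(r.std(), 1e-30)
            if keep.sum() < 16 or keep.all():
                break
            alpha = float(np.dot(im[keep], pm[keep]) / np.dot(pm[keep], pm[keep]))
    out = img.pixels - alpha * p
    rms = float(np.sqrt(np.mean(out[mask] ** 2)))
    return SubtractionResult(Image2D(out, img.pixel_size), alpha, rms)


def subtract_stack(stack: ImageStack, avg: AzimuthalAverage,
                   mask_frac: float = 0.1, log=None,
                   refine: bool = False,
                   refine_psi_range: float = 0.75, refine_psi_step: float = 0.25,
                   refine_shift_range: float = 1.0, refine_shift_step: float = 0.25,
                   remove_axial_residual: bool = False,
                   ) -> ImageStack:
    """Project-and-subtract every aligned segment.

    With ``refine=True`` each segment's psi and perpendicular shift are
    locally re-optimized against the projected average (small grid search
    minimizing the masked residual) before subtracting — the same
    reference-based final alignment pass the method prescribes before
    subtraction, robust to decorations because the tube dominates the
    masked residual.

    With ``remove_axial_residual=True`` any axially invariant structure
    left after subtraction (per-column median in the aligned frame —
    e.g. the faint ring the dispersed decorations leave in the average)
    is removed as a 1D profile; localized particles are untouched because
    the median along the axis ignores them.

    Output images keep the original (unaligned) frame; metadata gains
    ``scale_alpha``, ``residual_rms`` and ``subtract_ok`` columns.  Fails
    only if no segment can be subtracted.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    meta = stack.metadata.copy()
    if "psi_deg" not in meta.columns:
        raise ValueError("stack is not aligned")
    data = stack.data.copy()
    alphas = np.full(len(stack), np.nan)
    resid = np.full(len(stack), np.nan)
    ok = np.zeros(len(stack), dtype=bool)
    aligned = meta["align_ok"].to_numpy().astype(bool) if "align_ok" in meta.columns \
        else np.ones(len(stack), dtype=bool)
    d_psi = np.arange(-refine_psi_range, refine_psi_range + 1e-9,
                      refine_psi_step) if refine else np.array([0.0])
    d_sx = np.arange(-refine_shift_range, refine_shift_range + 1e-9,
                     refine_shift_step) if refine else np.array([0.0])
    for i in range(len(stack)):
        if not aligned[i] or not np.isfinite(meta["psi_deg"].iloc[i]):
            continue
        row = meta.iloc[i]
        best: SubtractionResult | None = None
        best_off = (0.0, 0.0)
        try:
            for dp in d_psi:
                for ds in d_sx:
                    proj = project(avg, float(row["phi_deg"]), float(row["theta_deg"]),
                                   float(row["psi_deg"]) + dp,
                                   float(row["shift_x_px"]) + ds,
                                   float(row.get("shift_y_px", 0.0)),
                                   out_size=stack.data.shape[1])
                    res = subtract_segment(stack.image(i), proj, mask_frac)
                    if best is None or res.residual_rms_in_mask < best.residual_rms_in_mask:
                        best = res
                        best_off = (dp, ds)
        except ValueError as exc:
            if log:
                log(f"segment {i}: subtraction failed ({exc})")
            continue
        res = best
        psi_i = float(row["psi_deg"])
        if refine and best_off != (0.0, 0.0):
            psi_i = (psi_i + best_off[0]) % 180.0
            meta.loc[meta.index[i], "psi_deg"] = psi_i
            meta.loc[meta.index[i], "shift_x_px"] = \
                float(row["shift_x_px"]) + best_off[1]
        out_pixels = res.subtracted.pixels
        if remove_axial_residual:
            out_pixels = _remove_axial_profile(out_pixels, psi_i)
        data[i] = out_pixels
        alphas[i] = res.scale_alpha
        resid[i] = res.residual_rms_in_mask
        ok[i] = True
        if log:
            log(f"segment {i}: alpha={res.scale_alpha:.3f} residual_rms={res.residual_rms_in_mask:.4g}")
    if not ok.any():
        raise RuntimeError("subtraction failed for every segment")
    meta["scale_alpha"] = alphas
    meta["residual_rms"] = resid
    meta["subtract_ok"] = ok
    return stack.copy_with(data=data, metadata=meta)
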