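"""Particle recovery from tube-subtracted segments.

Two complementary pickers operate on the subtracted stack, whose images
are treated as small micrographs:

* **Template picking** — normalized cross-correlation against (rotations
  of) a reference projection, with greedy non-maximum suppression.
* **Picking-by-classification** — template-free: each segment is tiled
  into overlapping sub-boxes just larger than the particle, the pooled
  sub-boxes are run through multi-reference 2D classification, classes
  whose references show coherent structure are kept, and each member
  sub-box yields a pick at its center corrected by the in-class alignment
  shift.

Because neighbouring segments along a tube overlap, the same physical
particle is recovered several times; duplicates are detected by a global
distance gate plus peak cross-correlation of the boxed images and resolved
in favour of the highest-scoring pick.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import match_template, peak_local_max

from .formats import Image2D, ImageStack
from .geometry import image_center, rotate_image, shift_image

__all__ = [
    "SubBoxGrid",
    "ClassSet",
    "pick_by_template",
    "tile_subboxes",
    "classify_2d",
    "select_good_classes",
    "picks_from_classes",
    "eliminate_duplicates",
    "extract_boxes",
    "pick_stack_by_template",
    "pick_stack_by_classification",
    "to_global",
]


@dataclass
class SubBoxGrid:
    divisions: tuple[int, int]
    subbox_size: int
    centers: list[tuple[float, float]]  # (x, y) in segment frame

    @property
    def count(self) -> int:
        return self.divisions[0] * self.divisions[1]


@dataclass
class ClassSet:
    references: np.ndarray            # (k, s, s), zero-mean / unit-variance
    reference_power: np.ndarray       # (k,) std of the raw class average
    assignments: np.ndarray           # (n,)
    rotations_deg: np.ndarray         # (n,)
    shifts: np.ndarray                # (n, 2) = (dx, dy): particle offset from box center
    scores: np.ndarray                # (n,)
    populations: np.ndarray           # (k,)
    history: list[dict] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.references)


def _normalize(img: np.ndarray) -> np.ndarray:
    out = img - img.mean()
    sd = out.std()
    return out / sd if sd > 0 else out


def _subpixel_peak(field: np.ndarray, y: int, x: int) -> tuple[float, float]:
    dy = dx = 0.0
    ny, nx = field.shape
    if 0 < x < nx - 1:
        d = field[y, x - 1] - 2 * field[y, x] + field[y, x + 1]
        if d < 0:
            dx = 0.5 * (field[y, x - 1] - field[y, x + 1]) / d
    if 0 < y < ny - 1:
        d = field[y - 1, x] - 2 * field[y, x] + field[y + 1, x]
        if d < 0:
            dy = 0.5 * (field[y - 1, x] - field[y + 1, x]) / d
    return float(x + dx), float(y + dy)


def pick_by_template(segment: Image2D, template: Image2D, threshold: float = 0.3,
                     min_separation_px: float = 10.0, n_rotations: int = 24,
                     max_picks: int | None = None,
                     edge_margin_px: float | None = None) -> pd.DataFrame:
    """Template picks in one segment by greedy matched filtering with
    explained-signal subtraction.

    At each step the strongest normalized-cross-correlation peak (over a
    set of in-plane template rotations) above ``threshold`` is accepted,
    the least-squares-scaled template is subtracted at that position, and
    the correlation is recomputed — so a bright particle's correlation
    tails cannot displace or mask the picks of its neighbours.  Accepted
    picks carry sub-pixel (parabolic) coordinates and their NCC score.

    Peaks within ``edge_margin_px`` of the segment border (default: half
    the template) are excluded: a clipped particle cannot be localized
    reliably there, and with overlapping segments it is always interior
    to a neighbouring segment.
    """
    if template.pixels.shape[0] >= segment.pixels.shape[0] or \
            template.pixels.shape[1] >= segment.pixels.shape[1]:
        raise ValueError("template must be smaller than the segment")
    work = segment.pixels.astype(np.float64).copy()
    ny, nx = work.shape
    rotations = np.arange(0.0, 360.0, 360.0 / max(1, n_rotations))
    tmpls = [rotate_image(template.pixels, r, order=1) if r else
             template.pixels.astype(np.float64) for r in rotations]
    if max_picks is None:
        max_picks = max(4, int(work.size / max(min_separation_px, 4.0) ** 2))
    m = template.pixels.shape[0]
    half = (m - 1) // 2
    if edge_margin_px is None:
        edge_margin_px = m / 2
    margin = int(round(edge_margin_px))
    rows = []
    accepted: list[tuple[float, float]] = []
    for _ in range(max_picks):
        # NCC is numerically meaningless where the local window has ~zero
        # variance (flat background); mask those regions out
        from scipy.ndimage import uniform_filter
        local_mean = uniform_filter(work, m)
        local_var = np.clip(uniform_filter(work**2, m) - local_mean**2, 0, None)
        dead = local_var < 1e-8 * max(local_var.max(), 1e-300)
        best_map = None
        best_rot = None
        for ti, tmpl in enumerate(tmpls):
            ncc = match_template(work, tmpl, pad_input=True)
            ncc = np.where(np.isfinite(ncc) & ~dead, np.clip(ncc, -1.0, 1.0), 0.0)
            if best_map is None:
                best_map = ncc
                best_rot = np.zeros_like(ncc, dtype=int)
            else:
                upd = ncc > best_map
                best_map[upd] = ncc[upd]
                best_rot[upd] = ti
        masked = best_map.copy()
        if margin > 0:
            masked[:margin, :] = -np.inf
            masked[-margin:, :] = -np.inf
            masked[:, :margin] = -np.inf
            masked[:, -margin:] = -np.inf
        for (px, py) in accepted:
            y0, y1 = max(0, int(py - min_separation_px)), int(py + min_separation_px) + 1
            x0, x1 = max(0, int(px - min_separation_px)), int(px + min_separation_px) + 1
            masked[y0:y1, x0:x1] = -np.inf
        y, x = np.unravel_index(int(np.argmax(masked)), masked.shape)
        score = float(masked[y, x])
        if not np.isfinite(score) or score < threshold:
            break
        sx, sy = _subpixel_peak(best_map, y, x)
        rows.append({"local_x": sx, "local_y": sy, "score": score})
        accepted.append((sx, sy))
        # subtract the least-squares-scaled template at the accepted site
        tm = tmpls[int(best_rot[y, x])]
        ys0, ys1 = max(0, y - half), min(ny, y - half + m)
        xs0, xs1 = max(0, x - half), min(nx, x - half + m)
        patch = work[ys0:ys1, xs0:xs1]
        tpatch = tm[ys0 - (y - half):ys1 - (y - half),
                    xs0 - (x - half):xs1 - (x - half)]
        denom = float(np.sum(tpatch**2))
        if denom > 0:
            a = float(np.sum(patch * tpatch)) / denom
            work[ys0:ys1, xs0:xs1] = patch - max(a, 0.0) * tpatch
    rows.sort(key=lambda r: -r["score"])
    return pd.DataFrame(rows, columns=["local_x", "local_y", "score"])


def tile_subboxes(segment: Image2D, divisions: tuple[int, int], subbox_size: int
                  ) -> tuple[np.ndarray, SubBoxGrid]:
    """Cut ``nx * ny`` overlapping sub-boxes on an even grid spanning the
    segment interior (margin of half a sub-box on every side)."""
    ny_img, nx_img = segment.pixels.shape
    nx, ny = divisions
    if nx < 1 or ny < 1:
        raise ValueError("divisions must be >= 1")
    if subbox_size > min(nx_img, ny_img):
        raise ValueError("sub-box larger than the segment")
    half = (subbox_size - 1) / 2.0
    cx = np.linspace(half, nx_img - 1 - half, nx) if nx > 1 \
        else np.array([(nx_img - 1) / 2.0])
    cy = np.linspace(half, ny_img - 1 - half, ny) if ny > 1 \
        else np.array([(ny_img - 1) / 2.0])
    boxes = np.empty((nx * ny, subbox_size, subbox_size))
    centers = []
    i = 0
    for y in cy:
        for x in cx:
            x0 = int(round(x - half))
            y0 = int(round(y - half))
            boxes[i] = segment.pixels[y0:y0 + subbox_size, x0:x0 + subbox_size]
            centers.append((x0 + half, y0 + half))
            i += 1
    return boxes, SubBoxGrid((nx, ny), subbox_size, centers)


def _shift_window_mask(s: int, max_shift: int) -> np.ndarray:
    lag = np.fft.fftfreq(s, 1.0 / s).astype(int)
    ok = np.abs(lag) <= max_shift
    return ok[:, None] & ok[None, :]


def classify_2d(images: np.ndarray, k: int, n_iter: int = 15, seed: int = 0,
                rot_step_deg: float = 30.0, max_shift_px: int = 4) -> ClassSet:
    """Multi-reference alignment classification.

    Starts from a random partition, then alternates (a) aligning every
    image against every reference over a grid of in-plane rotations and a
    bounded shift search (via FFT cross-correlation) and assigning it to
    the best-correlating class, with (b) re-averaging the aligned members
    into new references.  Deterministic under ``seed``; stops early when
    fewer than 1% of assignments change.
    """
    images = np.asarray(images, dtype=np.float64)
    n, s, _ = images.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} classes but only {n} images")
    rng = np.random.default_rng(seed)
    norm_imgs = np.stack([_normalize(im) for im in images])
    F_imgs = np.fft.fft2(norm_imgs)
    img_norm = np.sqrt((norm_imgs**2).sum(axis=(1, 2)))
    assign = rng.permutation(n) % k
    refs = np.empty((k, s, s))
    power = np.zeros(k)
    for c in range(k):
        raw = norm_imgs[assign == c].mean(axis=0)
        power[c] = raw.std()
        refs[c] = _normalize(raw)
    rotations = np.arange(0.0, 360.0, rot_step_deg)
    window = _shift_window_mask(s, int(max_shift_px))
    lag = np.fft.fftfreq(s, 1.0 / s).astype(int)
    history: list[dict] = []
    best_rot = np.zeros(n)
    best_shift = np.zeros((n, 2))
    scores = np.full(n, -np.inf)
    for it in range(n_iter):
        scores = np.full(n, -np.inf)
        new_assign = np.zeros(n, dtype=int)
        best_rot = np.zeros(n)
        best_shift = np.zeros((n, 2), dtype=float)
        for c in range(k):
            for r in rotations:
                ref_r = _normalize(rotate_image(refs[c], r, order=1))
                ref_norm = np.sqrt((ref_r**2).sum())
                if ref_norm <= 0:
                    continue
                corr = np.fft.ifft2(F_imgs * np.conj(np.fft.fft2(ref_r))).real
                corr = np.where(window, corr, -np.inf)
                flat = corr.reshape(n, -1)
                idx = np.argmax(flat, axis=1)
                val = flat[np.arange(n), idx] / (img_norm * ref_norm)
                better = val > scores
                if np.any(better):
                    dy = lag[idx[better] // s]
                    dx = lag[idx[better] % s]
                    scores[better] = val[better]
                    new_assign[better] = c
                    best_rot[better] = r
                    best_shift[better, 0] = dx
                    best_shift[better, 1] = dy
        changed = float(np.mean(new_assign != assign)) if it > 0 else 1.0
        assign = new_assign
        cgrid = image_center(s)
        yy, xx = np.mgrid[0:s, 0:s].astype(float)
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue  # keep the previous reference for an empty class
            acc = np.zeros((s, s))
            for i in members:
                al = shift_image(norm_imgs[i], -best_shift[i, 0], -best_shift[i, 1], order=1)
                acc += rotate_image(al, -best_rot[i], order=1)
            raw = acc / members.size
            # re-center the reference on its intensity centroid so that
            # class membership translates into a centered pick
            pos = np.clip(raw - raw.mean(), 0.0, None)
            tot = pos.sum()
            if tot > 0:
                cx = float((pos * xx).sum() / tot - cgrid)
                cy = float((pos * yy).sum() / tot - cgrid)
                if 0.5 < max(abs(cx), abs(cy)) < s / 4:
                    raw = shift_image(raw, -cx, -cy, order=1)
            power[c] = raw.std()
            refs[c] = _normalize(raw)
        history.append({"iteration": it, "objective": float(np.mean(scores)),
                        "frac_changed": changed})
        if it > 0 and changed < 0.01:
            break
    # sub-pixel refinement of the winning shift (parabolic on the final
    # correlation peak) so picks inherit better-than-integer centering
    for i in range(n):
        ref_r = _normalize(rotate_image(refs[assign[i]], best_rot[i], order=1))
        corr = np.fft.ifft2(F_imgs[i] * np.conj(np.fft.fft2(ref_r))).real
        xi = int(best_shift[i, 0]) % s
        yi = int(best_shift[i, 1]) % s
        for axis, idx in ((0, xi), (1, yi)):
            if axis == 0:
                y0, y1, y2 = corr[yi, (xi - 1) % s], corr[yi, xi], corr[yi, (xi + 1) % s]
            else:
                y0, y1, y2 = corr[(yi - 1) % s, xi], corr[yi, xi], corr[(yi + 1) % s, xi]
            den = y0 - 2 * y1 + y2
            if den < 0:
                best_shift[i, axis] += 0.5 * (y0 - y2) / den
    populations = np.bincount(assign, minlength=k)
    return ClassSet(refs, power, assign, best_rot, best_shift, scores,
                    populations, history)


def class_central_concentration(classset: ClassSet,
                                radius_frac: float = 0.2) -> np.ndarray:
    """Fraction of each reference's power inside a central disc of radius
    ``radius_frac * box_size``."""
    s = classset.references.shape[1]
    c = image_center(s)
    yy, xx = np.mgrid[0:s, 0:s]
    disc = np.hypot(xx - c, yy - c) < radius_frac * s
    out = np.empty(classset.k)
    for k in range(classset.k):
        p2 = classset.references[k] ** 2
        out[k] = float(p2[disc].sum() / max(p2.sum(), 1e-30))
    return out


def select_good_classes(classset: ClassSet, central_min: float = 0.4,
                        power_frac: float = 0.3,
                        min_population: int = 1) -> list[int]:
    """Automatic good-class heuristic for centered-particle classes.

    A class is kept when its reference concentrates most of its power in
    the box center (sub-boxes are sized just larger than the particle and
    references are re-centered, so real particle classes are compact
    central blobs, while membrane-residual classes are elongated and
    noise-alignment classes spread power across the frame) and its raw
    average is not unusually weak.  This stands in for the manual class
    selection an operator would normally perform.
    """
    central = class_central_concentration(classset)
    pmax = classset.reference_power.max()
    return [c for c in range(classset.k)
            if central[c] >= central_min
            and classset.reference_power[c] >= power_frac * pmax
            and classset.populations[c] >= min_population]


def picks_from_classes(classset: ClassSet, grids: list[SubBoxGrid] | SubBoxGrid,
                       good_classes: list[int],
                       segment_ids: np.ndarray | None = None) -> pd.DataFrame:
    """One pick per sub-box assigned to a good class, at the sub-box center
    corrected by the in-class alignment shift.

    ``grids`` may be a single grid (one segment) or one grid per segment
    with ``segment_ids`` giving each sub-box's segment index into it.
    """
    if not good_classes:
        return pd.DataFrame(columns=["segment_index", "local_x", "local_y", "score"])
    single = isinstance(grids, SubBoxGrid)
    rows = []
    n = len(classset.assignments)
    for i in range(n):
        c = int(classset.assignments[i])
        if c not in good_classes:
            continue
        if single:
            grid, box_idx, seg = grids, i, 0
        else:
            seg = int(segment_ids[i])
            grid = grids[seg]
            box_idx = i - int(np.searchsorted(np.asarray(segment_ids), seg))
        cx, cy = grid.centers[box_idx]
        rows.append({
            "segment_index": seg,
            "local_x": cx + float(classset.shifts[i, 0]),
            "local_y": cy + float(classset.shifts[i, 1]),
            "score": float(classset.scores[i]),
        })
    return pd.DataFrame(rows, columns=["segment_index", "local_x", "local_y", "score"])


def extract_boxes(pixels: np.ndarray, centers: np.ndarray, box_size: int) -> np.ndarray:
    """Boxes centered at (x, y) positions, zero-padded at the borders."""
    half = (box_size - 1) / 2.0
    ny, nx = pixels.shape
    out = np.zeros((len(centers), box_size, box_size))
    for i, (x, y) in enumerate(centers):
        x0 = int(round(x - half))
        y0 = int(round(y - half))
        xs0, ys0 = max(0, x0), max(0, y0)
        xs1, ys1 = min(nx, x0 + box_size), min(ny, y0 + box_size)
        if xs1 <= xs0 or ys1 <= ys0:
            continue
        out[i, ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = pixels[ys0:ys1, xs0:xs1]
    return out


def boxes_for_picks(stack: ImageStack, picks: pd.DataFrame, box_size: int) -> np.ndarray:
    """Extract each pick's boxed image from its own segment.

    Duplicate detection compares these boxes: two picks of the same
    physical particle in overlapping segments see (nearly) the same pixels
    and correlate strongly, while picks of different particles do not.
    """
    out = np.zeros((len(picks), box_size, box_size))
    for row_i, (_, p) in enumerate(picks.iterrows()):
        seg = int(p["segment_index"]) if "segment_index" in picks.columns else 0
        out[row_i] = extract_boxes(stack.data[seg],
                                   np.array([[p["local_x"], p["local_y"]]]),
                                   box_size)[0]
    return out


def _peak_ncc(a: np.ndarray, b: np.ndarray, max_shift: int = 2) -> float:
    """Peak normalized cross-correlation over integer shifts up to
    ``max_shift`` pixels."""
    best = -1.0
    s = a.shape[0]
    for dy in range(-max_shift, max_shift + 1):
        for dx in range(-max_shift, max_shift + 1):
            a0 = a[max(0, dy):s + min(0, dy), max(0, dx):s + min(0, dx)]
            b0 = b[max(0, -dy):s + min(0, -dy), max(0, -dx):s + min(0, -dx)]
            am = a0 - a0.mean()
            bm = b0 - b0.mean()
            den = np.sqrt((am**2).sum() * (bm**2).sum())
            if den > 0:
                best = max(best, float((am * bm).sum() / den))
    return best


def eliminate_duplicates(picks: pd.DataFrame, boxed_images: np.ndarray,
                         dist_px: float, ncc_threshold: float = 0.8,
                         max_shift: int = 4) -> pd.DataFrame:
    """Remove duplicate picks of the same physical particle.

    Two picks are duplicates iff their global distance is below ``dist_px``
    *and* the peak cross-correlation of their boxed images over a small
    shift search exceeds ``ncc_threshold``.  The highest-scoring member of
    each duplicate group is kept; candidates are visited in a
    deterministic score-sorted order, so the result does not depend on the
    input ordering.
    """
    if len(picks) == 0:
        return picks.copy()
    sort_cols = [c for c in ("score", "global_x", "global_y", "segment_id")
                 if c in picks.columns]
    order = picks.reset_index(drop=True).sort_values(
        by=sort_cols, ascending=[c != "score" for c in sort_cols]).index.to_numpy()
    gx = picks["global_x"].to_numpy(dtype=float)
    gy = picks["global_y"].to_numpy(dtype=float)
    mic = picks["micrograph_id"].to_numpy() if "micrograph_id" in picks.columns \
        else np.zeros(len(picks))
    kept: list[int] = []
    for i in order:
        dup = False
        for j in kept:
            if mic[i] != mic[j]:
                continue
            if np.hypot(gx[i] - gx[j], gy[i] - gy[j]) >= dist_px:
                continue
            if _peak_ncc(boxed_images[i], boxed_images[j], max_shift) > ncc_threshold:
                dup = True
                break
        if not dup:
            kept.append(i)
    kept_sorted = sorted(kept)
    return picks.reset_index(drop=True).iloc[kept_sorted].reset_index(drop=True)


def to_global(picks: pd.DataFrame, stack: ImageStack) -> pd.DataFrame:
    """Map segment-local pick coordinates to the parent-micrograph frame:
    global = segment origin + (local - segment center)."""
    meta = stack.metadata
    n_box = stack.data.shape[1]
    c = image_center(n_box)
    out = picks.copy()
    seg = out["segment_index"].to_numpy(dtype=int)
    out["segment_id"] = meta["segment_id"].to_numpy()[seg]
    if "micrograph_id" in meta.columns:
        out["micrograph_id"] = meta["micrograph_id"].to_numpy()[seg]
    else:
        out["micrograph_id"] = "unknown"
    ox = meta["origin_x"].to_numpy(dtype=float)[seg] if "origin_x" in meta.columns else c
    oy = meta["origin_y"].to_numpy(dtype=float)[seg] if "origin_y" in meta.columns else c
    out["global_x"] = ox + (out["local_x"].to_numpy(dtype=float) - c)
    out["global_y"] = oy + (out["local_y"].to_numpy(dtype=float) - c)
    return out


def pick_stack_by_template(stack: ImageStack, template: Image2D,
                           threshold: float = 0.3, min_separation_px: float = 10.0,
                           n_rotations: int = 24,
                           edge_margin_px: float | None = None) -> pd.DataFrame:
    """Template-pick every segment of a (subtracted) stack; returns picks
    with both local and global coordinates."""
    frames = []
    for i in range(len(stack)):
        p = pick_by_template(stack.image(i), template, threshold,
                             min_separation_px, n_rotations,
                             edge_margin_px=edge_margin_px)
        if len(p) == 0:
            continue
        p["segment_index"] = i
        frames.append(p)
    picks = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        {"local_x": pd.Series(dtype=float), "local_y": pd.Series(dtype=float),
         "score": pd.Series(dtype=float), "segment_index": pd.Series(dtype=int)})
    return to_global(picks, stack)


def pick_stack_by_classification(stack: ImageStack, divisions: tuple[int, int] = (4, 4),
                                 subbox_size: int = 64, k: int = 8, n_iter: int = 15,
                                 seed: int = 0, rot_step_deg: float = 45.0,
                                 max_shift_px: int = 14, lowpass_px: float = 2.0,
                                 central_min: float = 0.4,
                                 junk_central_max: float = 0.15,
                                 good_classes: list[int] | None = None,
                                 n_rounds: int = 4,
                                 rescue: bool = True,
                                 rescue_quantile: float = 25.0
                                 ) -> tuple[pd.DataFrame, ClassSet]:
    """Template-free picking: tile every segment into overlapping
    sub-boxes and run rounds of 2D classification over the pooled boxes.

    Boxes are light low-pass filtered before classification (the filter
    scale is far below the particle size, so centering is unaffected, but
    it lets weak references lock onto real structure instead of noise).
    Each round emits picks from classes whose references concentrate
    their power centrally (``central_min``), discards members of clearly
    incoherent classes (``junk_central_max``), and re-classifies the
    ambiguous remainder — up to ``n_rounds`` rounds or until nothing new
    is resolved.  Passing ``good_classes`` switches to manual mode: one
    round, picks from exactly those classes.

    With ``rescue=True`` a final pass re-aligns every box that was never
    emitted against the most compact emitted reference and accepts those
    whose correlation reaches the ``rescue_quantile``-th percentile of
    the emitted boxes' own scores — recovering particles whose boxes
    co-classified with partial neighbours into rejected classes, using a
    reference that the classification itself discovered (no external
    template involved).

    Returns the picks (local + global coordinates) and the first round's
    :class:`ClassSet` (whose references cover the complete data).
    """
    all_boxes = []
    centers = []
    seg_ids = []
    for i in range(len(stack)):
        boxes, grid = tile_subboxes(stack.image(i), divisions, subbox_size)
        all_boxes.append(boxes)
        centers.extend(grid.centers)
        seg_ids.extend([i] * len(boxes))
    boxes = np.concatenate(all_boxes)
    seg_ids = np.asarray(seg_ids)
    centers = np.asarray(centers)
    if lowpass_px > 0:
        from scipy.ndimage import gaussian_filter
        filtered = np.stack([gaussian_filter(b, lowpass_px) for b in boxes])
    else:
        filtered = boxes
    rows = []
    first_classset = None
    active = np.arange(len(boxes))
    emitted: list[int] = []
    best_ref = None
    best_central = -np.inf
    for rnd in range(1 if good_classes is not None else n_rounds):
        if len(active) < max(2 * k, 20):
            break
        classset = classify_2d(filtered[active], k, n_iter, seed + rnd,
                               rot_step_deg, max_shift_px)
        if first_classset is None:
            first_classset = classset
        if good_classes is not None:
            emit = list(good_classes)
            junk: list[int] = []
        else:
            central = class_central_concentration(classset)
            emit = [c for c in range(classset.k) if central[c] >= central_min]
            junk = [c for c in range(classset.k) if central[c] < junk_central_max]
            for c in emit:
                if central[c] > best_central:
                    best_central = central[c]
                    best_ref = classset.references[c]
        for li in np.flatnonzero(np.isin(classset.assignments, emit)):
            gi = int(active[li])
            emitted.append(gi)
            rows.append({"segment_index": int(seg_ids[gi]),
                         "local_x": float(centers[gi, 0] + classset.shifts[li, 0]),
                         "local_y": float(centers[gi, 1] + classset.shifts[li, 1]),
                         "score": float(classset.scores[li])})
        resolved = np.isin(classset.assignments, emit + junk)
        if not resolved.any():
            break
        active = active[~resolved]
    if rescue and best_ref is not None and emitted:
        s = filtered.shape[1]
        refn = _normalize(best_ref)
        Fr = np.conj(np.fft.fft2(refn))
        lag = np.fft.fftfreq(s, 1.0 / s).astype(int)
        win = np.abs(lag) <= max_shift_px
        wmask = win[:, None] & win[None, :]
        norm = np.stack([_normalize(b) for b in filtered])
        corr = np.where(wmask, np.fft.ifft2(np.fft.fft2(norm) * Fr).real, -np.inf)
        flat = corr.reshape(len(boxes), -1)
        idx = np.argmax(flat, axis=1)
        nrm = np.sqrt((norm**2).sum(axis=(1, 2))) * np.sqrt((refn**2).sum())
        score = flat[np.arange(len(boxes)), idx] / np.maximum(nrm, 1e-30)
        dyi = lag[idx // s]
        dxi = lag[idx % s]
        thr = float(np.percentile(score[np.asarray(emitted)], rescue_quantile))
        emitted_set = set(emitted)
        for gi in np.flatnonzero(score >= thr):
            if int(gi) in emitted_set:
                continue
            cmap = corr[gi]
            sx, sy = float(dxi[gi]), float(dyi[gi])
            xi, yi = int(sx) % s, int(sy) % s
            d = cmap[yi, (xi - 1) % s] - 2 * cmap[yi, xi] + cmap[yi, (xi + 1) % s]
            if np.isfinite(d) and d < 0:
                sx += 0.5 * (cmap[yi, (xi - 1) % s] - cmap[yi, (xi + 1) % s]) / d
            d = cmap[(yi - 1) % s, xi] - 2 * cmap[yi, xi] + cmap[(yi + 1) % s, xi]
            if np.isfinite(d) and d < 0:
                sy += 0.5 * (cmap[(yi - 1) % s, xi] - cmap[(yi + 1) % s, xi]) / d
            rows.append({"segment_index": int(seg_ids[gi]),
                         "local_x": float(centers[gi, 0] + sx),
                         "local_y": float(centers[gi, 1] + sy),
                         "score": float(score[gi])})
    picks = pd.DataFrame(rows, columns=["segment_index", "local_x", "local_y", "score"])
    return to_global(picks, stack), first_classset
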