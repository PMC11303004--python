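import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rastr.formats import Image2D, ImageStack
from rastr.geometry import shift_image
from rastr.picking import (boxes_for_picks, classify_2d, eliminate_duplicates,
                           pick_by_template, picks_from_classes,
                           select_good_classes, tile_subboxes, to_global)

PS = 4.32


def _blob(n, sigma, cx, cy, amp=1.0):
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestPickByTemplate:
    def test_recovers_inserted_template(self):
        tmpl = _blob(31, 4.0, 15, 15)
        frame = np.zeros((128, 128))
        frame[50:81, 70:101] += tmpl
        picks = pick_by_template(Image2D(frame, PS), Image2D(tmpl, PS),
                                 threshold=0.5, min_separation_px=10,
                                 n_rotations=1)
        assert len(picks) == 1
        assert picks.local_x[0] == pytest.approx(85.0, abs=1.0)
        assert picks.local_y[0] == pytest.approx(65.0, abs=1.0)
        assert picks.score[0] > 0.95

    def test_blank_noise_gives_no_picks(self):
        tmpl = _blob(31, 4.0, 15, 15)
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frame = rng.normal(size=(128, 128))
            picks = pick_by_template(Image2D(frame, PS), Image2D(tmpl, PS),
                                     threshold=0.3, min_separation_px=10,
                                     n_rotations=1)
            hits += len(picks) > 0
        assert hits <= 1  # no picks on >= 90% of pure-noise frames

    def test_neighbouring_particles_resolved(self):
        """Greedy pick-and-subtract separates two particles one diameter
        apart without displacement."""
        tmpl = _blob(31, 4.0, 15, 15)
        frame = np.zeros((128, 128))
        for cx, cy, amp in ((50, 64, 1.0), (66, 64, 0.6)):
            frame += _blob(128, 4.0, cx, cy, amp)
        picks = pick_by_template(Image2D(frame, PS), Image2D(tmpl, PS),
                                 threshold=0.3, min_separation_px=10,
                                 n_rotations=1)
        got = sorted((p.local_x, p.local_y) for _, p in picks.iterrows())
        assert len(got) == 2
        assert got[0] == pytest.approx((50.0, 64.0), abs=1.0)
        assert got[1] == pytest.approx((66.0, 64.0), abs=1.0)

    def test_template_must_be_smaller(self):
        img = Image2D(np.zeros((32, 32)), PS)
        with pytest.raises(ValueError):
            pick_by_template(img, Image2D(np.zeros((64, 64)), PS))


class TestTileSubboxes:
    def test_4x4_yields_16(self):
        segment = Image2D(np.zeros((384, 384)), 1.44)
        boxes, grid = tile_subboxes(segment, (4, 4), 96)
        assert len(boxes) == 16
        assert grid.count == 16

    def test_1x1_centered(self):
        segment = Image2D(np.arange(64.0 * 64).reshape(64, 64), PS)
        boxes, grid = tile_subboxes(segment, (1, 1), 32)
        assert len(boxes) == 1
        assert grid.centers[0] == (31.5, 31.5)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(2, 6), st.integers(2, 6))
    def test_count_law_and_coverage(self, nx, ny):
        """Count is always nx*ny; when the boxes are at least as large as
        the grid spacing, every interior pixel is covered."""
        n = 120
        subbox = 40
        segment = Image2D(np.zeros((n, n)), PS)
        boxes, grid = tile_subboxes(segment, (nx, ny), subbox)
        assert len(boxes) == nx * ny
        spacing_x = (n - subbox) / max(nx - 1, 1)
        spacing_y = (n - subbox) / max(ny - 1, 1)
        if subbox >= max(spacing_x, spacing_y):
            covered = np.zeros((n, n), dtype=int)
            half = (subbox - 1) / 2
            for cx, cy in grid.centers:
                x0, y0 = int(round(cx - half)), int(round(cy - half))
                covered[y0:y0 + subbox, x0:x0 + subbox] += 1
            assert covered.min() >= 1

    def test_oversized_subbox_rejected(self):
        with pytest.raises(ValueError):
            tile_subboxes(Image2D(np.zeros((64, 64)), PS), (2, 2), 65)


class TestClassify2d:
    def test_k1_gives_global_mean(self):
        rng = np.random.default_rng(0)
        imgs = rng.normal(size=(20, 32, 32))
        cs = classify_2d(imgs, 1, n_iter=3, seed=1, rot_step_deg=360,
                         max_shift_px=0)
        assert set(cs.assignments) == {0}
        assert cs.populations[0] == 20

    def test_two_distinct_views_perfectly_separated(self):
        """Two noiseless views, k=2: purity 1.0 and recovered shifts."""
        rng = np.random.default_rng(3)
        blob = _blob(48, 5.0, 23.5, 23.5)
        yy, xx = np.mgrid[0:48, 0:48].astype(float)
        ring = np.exp(-((np.hypot(xx - 23.5, yy - 23.5) - 12) ** 2) / (2 * 3.0**2))
        imgs, labels = [], []
        for base, lab in ((blob, 0), (ring, 1)):
            for _ in range(100):
                dx, dy = rng.integers(-3, 4, 2)
                imgs.append(shift_image(base, dx, dy))
                labels.append(lab)
        cs = classify_2d(np.array(imgs), 2, n_iter=10, seed=1,
                         rot_step_deg=90, max_shift_px=4)
        labels = np.array(labels)
        a = cs.assignments
        purity = max(np.mean(a[labels == 0] == 0), np.mean(a[labels == 0] == 1))
        purity2 = max(np.mean(a[labels == 1] == 0), np.mean(a[labels == 1] == 1))
        assert purity == 1.0 and purity2 == 1.0

    def test_objective_non_decreasing(self):
        rng = np.random.default_rng(5)
        blob = _blob(32, 4.0, 15.5, 15.5)
        imgs = np.stack([shift_image(blob, *rng.integers(-3, 4, 2))
                         + rng.normal(0, 0.3, (32, 32)) for _ in range(60)])
        cs = classify_2d(imgs, 3, n_iter=8, seed=2, rot_step_deg=90,
                         max_shift_px=4)
        obj = [h["objective"] for h in cs.history]
        assert all(b >= a - 1e-3 for a, b in zip(obj, obj[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            classify_2d(np.zeros((3, 16, 16)), 5, 2, 0)


class TestPicksFromClasses:
    def _classified_single_box(self, shift=(0.0, 0.0)):
        from rastr.picking import ClassSet
        return ClassSet(
            references=np.zeros((2, 32, 32)),
            reference_power=np.array([1.0, 0.1]),
            assignments=np.array([0]),
            rotations_deg=np.array([0.0]),
            shifts=np.array([list(shift)]),
            scores=np.array([0.9]),
            populations=np.array([1, 0]),
        )

    def test_centered_particle_pick(self):
        from rastr.picking import SubBoxGrid
        grid = SubBoxGrid((1, 1), 32, [(40.0, 40.0)])
        picks = picks_from_classes(self._classified_single_box(), grid, [0])
        assert picks.local_x[0] == pytest.approx(40.0)
        assert picks.local_y[0] == pytest.approx(40.0)

    def test_shift_corrects_pick(self):
        from rastr.picking import SubBoxGrid
        grid = SubBoxGrid((1, 1), 32, [(40.0, 40.0)])
        picks = picks_from_classes(self._classified_single_box((6.0, -2.0)),
                                   grid, [0])
        assert (picks.local_x[0], picks.local_y[0]) == (46.0, 38.0)

    def test_no_good_classes_gives_empty(self):
        from rastr.picking import SubBoxGrid
        grid = SubBoxGrid((1, 1), 32, [(40.0, 40.0)])
        picks = picks_from_classes(self._classified_single_box(), grid, [])
        assert len(picks) == 0


class TestGlobalCoordinates:
    def test_local_to_global_mapping(self):
        stack = ImageStack(np.zeros((2, 64, 64)), PS,
                           pd.DataFrame({"segment_id": [7, 8],
                                         "micrograph_id": ["m1", "m1"],
                                         "origin_x": [100.0, 150.0],
                                         "origin_y": [80.0, 80.0]}))
        picks = pd.DataFrame({"segment_index": [1], "local_x": [40.0],
                              "local_y": [30.0], "score": [1.0]})
        out = to_global(picks, stack)
        # global = origin + (local - center), center = 31.5
        assert out.global_x[0] == pytest.approx(150.0 + 8.5)
        assert out.global_y[0] == pytest.approx(80.0 - 1.5)


class TestEliminateDuplicates:
    def _picks(self, coords, scores, seg=None):
        return pd.DataFrame({
            "segment_index": seg if seg is not None else range(len(coords)),
            "segment_id": seg if seg is not None else range(len(coords)),
            "micrograph_id": "m",
            "local_x": [c[0] for c in coords], "local_y": [c[1] for c in coords],
            "global_x": [c[0] for c in coords], "global_y": [c[1] for c in coords],
            "score": scores})

    def test_disjoint_picks_all_kept(self):
        rng = np.random.default_rng(0)
        picks = self._picks([(10, 10), (100, 100), (200, 10)], [0.9, 0.8, 0.7])
        boxes = rng.normal(size=(3, 16, 16))
        out = eliminate_duplicates(picks, boxes, dist_px=20.0)
        assert len(out) == 3

    def test_empty_input(self):
        out = eliminate_duplicates(self._picks([], []), np.zeros((0, 8, 8)), 10.0)
        assert len(out) == 0

    def test_threefold_overlap_keeps_one(self):
        """The same particle seen from three overlapping segments collapses
        to the single highest-scoring pick."""
        rng = np.random.default_rng(1)
        content = rng.normal(size=(24, 24))
        jitter = [(0, 0), (1, -1), (-1, 2)]
        coords = [(50 + dx, 60 + dy) for dx, dy in jitter]
        picks = self._picks(coords, [0.7, 0.9, 0.8])
        boxes = np.stack([shift_image(content, dx, dy) for dx, dy in jitter])
        out = eliminate_duplicates(picks, boxes, dist_px=20.0, ncc_threshold=0.8)
        assert len(out) == 1
        assert out.score[0] == 0.9

    def test_order_independence(self):
        rng = np.random.default_rng(2)
        content = [rng.normal(size=(24, 24)) for _ in range(3)]
        coords = [(50, 60), (51, 61), (200, 200)]
        picks = self._picks(coords, [0.5, 0.9, 0.7])
        boxes = np.stack([shift_image(content[0], 0, 0),
                          shift_image(content[0], 1, 1), content[1]])
        out1 = eliminate_duplicates(picks, boxes, 20.0)
        perm = [2, 0, 1]
        out2 = eliminate_duplicates(picks.iloc[perm].reset_index(drop=True),
                                    boxes[perm], 20.0)
        assert sorted(out1.score) == sorted(out2.score)

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        coords = [(50, 60), (52, 61), (120, 40), (123, 43)]
        picks = self._picks(coords, [0.9, 0.6, 0.8, 0.75])
        base = rng.normal(size=(24, 24))
        other = rng.normal(size=(24, 24))
        boxes = np.stack([base, shift_image(base, 2, 1), other,
                          shift_image(other, 3, 3)])
        once = eliminate_duplicates(picks, boxes, 20.0)
        keep_idx = [i for i, c in enumerate(coords)
                    if (c[0], c[1]) in set(zip(once.global_x, once.global_y))]
        twice = eliminate_duplicates(once, boxes[keep_idx], 20.0)
        pd.testing.assert_frame_equal(once, twice)
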