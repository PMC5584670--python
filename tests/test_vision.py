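"""Segmentation chain: channels, background, Otsu, morphology, CFS."""
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchrig import scene as scn
from patchrig import vision


def _frame(red, green):
    return scn.Frame(red=red.astype(np.uint16), green=green.astype(np.uint16),
                     focal_z=0.0, timestamp=0.0)


def brute_force_otsu(image):
    """Independent exact oracle: exhaustive between-class variance
    maximization with Fraction arithmetic, lowest threshold on ties."""
    vals = np.asarray(image).ravel()
    n = vals.size
    best_t, best_var = None, None
    for t in range(int(vals.min()), int(vals.max())):
        c0 = vals[vals <= t]
        c1 = vals[vals > t]
        if c0.size == 0 or c1.size == 0:
            continue
        w0 = Fraction(int(c0.size), n)
        w1 = Fraction(int(c1.size), n)
        mu0 = Fraction(int(c0.sum()), int(c0.size))
        mu1 = Fraction(int(c1.sum()), int(c1.size))
        var = w0 * w1 * (mu0 - mu1) ** 2
        if best_var is None or var > best_var:
            best_var, best_t = var, t
    return best_t


class TestChannels:
    def test_red_identity(self):
        r = np.arange(16, dtype=np.uint16).reshape(4, 4)
        f = _frame(r, np.zeros((4, 4)))
        assert np.array_equal(vision.split_channels(f, "red"), r)

    def test_green_identity(self):
        g = np.arange(16, dtype=np.uint16).reshape(4, 4)
        f = _frame(np.zeros((4, 4)), g)
        assert np.array_equal(vision.split_channels(f, "green"), g)

    def test_sum_saturates(self):
        a = np.full((2, 2), 40000)
        f = _frame(a, a)
        s = vision.split_channels(f, "sum")
        assert s.dtype == np.uint16
        assert np.all(s == 65535)


class TestBackgroundCorrect:
    def test_constant_maps_to_zero(self):
        img = np.full((64, 64), 500, dtype=np.uint16)
        assert vision.background_correct(img, 48).max() == 0

    def test_ramp_removed(self):
        rng = np.random.default_rng(0)
        blob = np.zeros((96, 96))
        blob[40:50, 40:50] = 8000
        ramp = np.linspace(0, 2000, 96)[None, :] * np.ones((96, 96))
        a = vision.background_correct(blob.astype(np.uint16), 48)
        b = vision.background_correct((blob + ramp).astype(np.uint16), 48)
        interior = (slice(20, 76), slice(20, 76))
        assert np.abs(a[interior].astype(int) - b[interior].astype(int)).max() < 400

    def test_blob_preserved(self):
        img = np.zeros((96, 96), dtype=np.uint16)
        img[45:52, 45:52] = 10000
        out = vision.background_correct(img, 48)
        assert out.max() >= 0.9 * 10000


class TestOtsu:
    def test_two_class_separation(self):
        img = np.concatenate([np.full(50, 10), np.full(50, 200)])
        img = img.reshape(10, 10).astype(np.uint16)
        thr, mask = vision.otsu_threshold(img)
        assert 10 <= thr < 200
        assert mask.sum() == 50

    def test_constant_image_degenerate(self):
        thr, mask = vision.otsu_threshold(np.full((8, 8), 7, dtype=np.uint16))
        assert thr is None and not mask.any()

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = (rng.integers(4, 20), rng.integers(4, 20))
        if seed % 3 == 0:
            img = rng.integers(0, 256, shape).astype(np.uint16)
        elif seed % 3 == 1:
            img = (rng.choice([5, 30, 200, 220], size=shape,
                              p=[0.4, 0.2, 0.2, 0.2])).astype(np.uint16)
        else:
            img = np.clip(rng.normal(100, 40, shape), 0, 400).astype(np.uint16)
        thr, mask = vision.otsu_threshold(img)
        assert thr == brute_force_otsu(img)
        assert np.array_equal(mask, img > thr)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 60), min_size=4, max_size=36))
    def test_oracle_property(self, pixels):
        img = np.asarray(pixels, dtype=np.uint16).reshape(1, -1)
        if np.unique(img).size < 2:
            return
        thr, _ = vision.otsu_threshold(img)
        assert thr == brute_force_otsu(img)

    def test_symmetric_swap_same_threshold(self):
        img = np.concatenate([np.full(30, 10), np.full(70, 200)])
        swapped = np.concatenate([np.full(70, 10), np.full(30, 200)])
        t1, _ = vision.otsu_threshold(img.reshape(10, 10).astype(np.uint16))
        t2, _ = vision.otsu_threshold(swapped.reshape(10, 10).astype(np.uint16))
        assert t1 == t2


class TestMorphology:
    def _disk_mask(self, radius, shape=(40, 40), center=(20, 20)):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2

    def test_fill_annulus(self):
        mask = self._disk_mask(10) & ~self._disk_mask(5)
        filled = vision.fill_holes(mask)
        assert np.array_equal(filled, self._disk_mask(10))

    def test_fill_idempotent(self):
        mask = self._disk_mask(8)
        once = vision.fill_holes(mask)
        assert np.array_equal(once, vision.fill_holes(once))
        assert np.array_equal(once, mask)

    def test_erode_disk(self):
        eroded = vision.erode(self._disk_mask(5), 2)
        expect = self._disk_mask(3)
        # allow 1 px discretization slack at the boundary
        assert not (eroded & ~self._disk_mask(4)).any()
        assert (self._disk_mask(2) & ~eroded).sum() == 0
        assert abs(int(eroded.sum()) - int(expect.sum())) <= 12

    def test_erode_empty_and_antiextensive(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert not vision.erode(empty, 1).any()
        mask = self._disk_mask(6)
        assert not (vision.erode(mask, 2) & ~mask).any()


class TestParticles:
    def test_two_blobs(self, seg_config):
        mask = np.zeros((60, 60), dtype=bool)
        mask[5:15, 5:15] = True     # 100 px
        mask[40:50, 40:50] = True   # 100 px
        objs = vision.particle_analysis(mask, mask.astype(np.uint16) * 100,
                                        seg_config)
        assert len(objs) == 2
        assert [o.area for o in objs] == [100, 100]
        assert objs[0].label < objs[1].label

    def test_small_blob_excluded(self, seg_config):
        mask = np.zeros((30, 30), dtype=bool)
        mask[4:7, 4] = True  # 3 px < min_particle_area
        assert vision.particle_analysis(mask, mask.astype(np.uint16),
                                        seg_config) == []

    def test_disk_centroid(self, seg_config):
        yy, xx = np.mgrid[:100, :120]
        mask = (yy - 60) ** 2 + (xx - 50) ** 2 <= 81
        obj = vision.particle_analysis(mask, mask.astype(np.uint16),
                                       seg_config)[0]
        assert obj.centroid[0] == pytest.approx(50, abs=0.5)  # x = col
        assert obj.centroid[1] == pytest.approx(60, abs=0.5)  # y = row
        assert obj.internal_mask.any() and obj.external_ring.any()
        assert not (obj.internal_mask & obj.external_ring).any()


class TestCfs:
    def _obj(self, shape=(20, 20)):
        internal = np.zeros(shape, dtype=bool)
        ring = np.zeros(shape, dtype=bool)
        internal[8:12, 8:12] = True
        ring[6:14, 6:14] = True
        ring &= ~internal
        return vision.DetectedObject(label=1, contour=np.zeros((0, 2)),
                                     area=64, centroid=(10, 10),
                                     bbox=(6, 6, 14, 14),
                                     internal_mask=internal,
                                     external_ring=ring)

    def _image(self, interior, ring_val, obj):
        img = np.zeros(obj.internal_mask.shape)
        img[obj.internal_mask] = interior
        img[obj.external_ring] = ring_val
        return img

    @pytest.mark.parametrize("interior,ring,expected",
                             [(1000, 0, 1.0), (1000, 1000, 0.0),
                              (800, 200, 0.75)])
    def test_analytic_values(self, interior, ring, expected):
        obj = self._obj()
        cfs = vision.compute_cfs(self._image(interior, ring, obj), obj)
        assert cfs == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_scale_invariance(self, k):
        obj = self._obj()
        img = self._image(800, 200, obj)
        assert vision.compute_cfs(img * k, obj) == pytest.approx(
            vision.compute_cfs(img, obj), abs=1e-12)

    def test_zero_interior_sentinel(self):
        obj = self._obj()
        cfs = vision.compute_cfs(self._image(0, 100, obj), obj)
        assert np.isnan(cfs) and not obj.cfs_usable


class TestSegmentFrame:
    def test_three_cells_found(self, seg_config):
        cfg = {"cells": [
            {"id": 0, "center": [-25, -20, -120], "diameter": 10,
             "channel": "green", "peak_intensity": 15000},
            {"id": 1, "center": [20, -15, -120], "diameter": 8,
             "channel": "green", "peak_intensity": 12000},
            {"id": 2, "center": [0, 25, -120], "diameter": 12,
             "channel": "green", "peak_intensity": 14000}],
            "motion": {"breathing_amplitude": 0, "heartbeat_amplitude": 0}}
        s = scn.make_scene(cfg, seed=3)
        f = scn.render_frame(s, -120.0, 0.0, noise=True, include_pipette=False)
        objs = vision.segment_frame(f, seg_config)
        assert len(objs) == 3

    def test_noise_only_frame_empty(self, seg_config):
        rng = np.random.default_rng(0)
        img = np.clip(rng.normal(5000, 60, (128, 128)), 0,
                      65535).astype(np.uint16)
        f = _frame(img.copy(), img)
        assert vision.segment_frame(f, seg_config) == []

    def test_deterministic(self, single_cell_scene, seg_config):
        f = scn.render_frame(single_cell_scene, -120.0, 0.0, noise=False)
        a = vision.segment_frame(f, seg_config)
        b = vision.segment_frame(f, seg_config)
        assert [o.label for o in a] == [o.label for o in b]
        assert [o.centroid for o in a] == [o.centroid for o in b]
        assert [o.cfs for o in a] == [o.cfs for o in b]

    def test_cfs_peaks_at_cell_plane(self, single_cell_scene, seg_config):
        """Focus metric link to the optics: CFS maximal at the cell's z."""
        scores = {}
        for dz in (-6, -4, -2, 0, 2, 4, 6):
            f = scn.render_frame(single_cell_scene, -120.0 + dz, 0.0,
                                 noise=False, include_pipette=False)
            objs = vision.segment_frame(f, seg_config)
            scores[dz] = max((o.cfs for o in objs), default=0.0)
        assert all(scores[0] > scores[dz] for dz in scores if dz != 0)
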