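"""Histology classification rules, droplet statistics, collagen fraction,
segmentation, and 3D morphometry."""

import numpy as np
import pytest

from adipoclock import histoquant, synthdata
from adipoclock.histoquant import SegmentedObject


def disk_object(object_id, image, center, radius, margin=20):
    yy, xx = np.mgrid[0 : image.shape[0], 0 : image.shape[1]]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    rows, cols = np.nonzero(mask)
    return SegmentedObject.from_pixels(object_id, rows, cols, image, margin)


def blank_image(h=400, w=400, color=(230, 180, 190)):
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = color
    return img


def paint(img, center, radius, color):
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = color


class TestClassifyDroplets:
    def test_qualifying_droplet_kept(self):
        img = blank_image()
        paint(img, (200, 200), 60, (200, 200, 200))  # area ~11,310 > 10,000
        obj = disk_object(1, img, (200, 200), 60)
        kept = histoquant.classify_droplets([obj], img.shape[:2])
        assert len(kept) == 1

    def test_area_not_exceeding_threshold_rejected(self):
        img = blank_image()
        paint(img, (200, 200), 60, (200, 200, 200))
        obj = disk_object(1, img, (200, 200), 60)
        obj.area = 10_000  # exactly at the threshold: 'exceeding' is strict
        assert len(histoquant.classify_droplets([obj], img.shape[:2])) == 0
        obj.area = 10_001
        assert len(histoquant.classify_droplets([obj], img.shape[:2])) == 1

    def test_dark_object_rejected(self):
        img = blank_image()
        paint(img, (200, 200), 60, (189, 200, 200))  # R channel below 190
        obj = disk_object(1, img, (200, 200), 60)
        assert len(histoquant.classify_droplets([obj], img.shape[:2])) == 0

    def test_border_proximity_rejected(self):
        img = blank_image()
        paint(img, (200, 70), 60, (220, 220, 220))  # leftmost pixel at col 10 < 20
        obj = disk_object(1, img, (200, 70), 60)
        assert obj.border
        assert len(histoquant.classify_droplets([obj], img.shape[:2])) == 0

    def test_overlap_keeps_largest(self):
        img = blank_image(500, 500)
        paint(img, (250, 220), 70, (220, 220, 220))
        paint(img, (250, 300), 63, (220, 220, 220))
        a = disk_object(1, img, (250, 220), 70)  # area ~15,390
        b = disk_object(2, img, (250, 300), 63)  # area ~12,470, overlaps a
        kept = histoquant.classify_droplets([a, b], img.shape[:2])
        assert kept["object_id"].tolist() == [1]

    def test_out_of_image_pixels_rejected(self):
        img = blank_image(50, 50)
        with pytest.raises(ValueError, match="outside"):
            SegmentedObject.from_pixels(1, [10, 60], [10, 10], img)

    def test_area_threshold_monotonicity(self):
        img = blank_image(900, 900)
        objs = [
            disk_object(i, img, (150 + 220 * (i // 3), 150 + 220 * (i % 3)), 58 + 4 * i)
            for i in range(9)
        ]
        for o in objs:
            img[o.rows, o.cols] = (250, 250, 250)
            o.mean_rgb = (250.0, 250.0, 250.0)
        counts = [
            len(histoquant.classify_droplets(objs, img.shape[:2], area_min=t))
            for t in (8_000, 10_000, 12_000, 14_000, 16_000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestClassifyNuclei:
    def _obj(self, rgb, area):
        img = blank_image(300, 300)
        paint(img, (150, 150), 30, rgb)
        o = disk_object(1, img, (150, 150), 30)
        o.area = area
        return o

    def test_purple_small_object_is_nucleus(self):
        o = self._obj((120, 120, 180), 3000)
        assert len(histoquant.classify_nuclei([o])) == 1

    def test_area_at_limit_rejected(self):
        assert len(histoquant.classify_nuclei([self._obj((120, 120, 180), 5000)])) == 0
        assert len(histoquant.classify_nuclei([self._obj((120, 120, 180), 4999)])) == 1

    def test_red_channel_over_limit_rejected(self):
        assert len(histoquant.classify_nuclei([self._obj((160, 120, 180), 3000)])) == 0


class TestDropletSummary:
    def test_equal_areas_zero_sd(self):
        s = histoquant.droplet_summary([50.0] * 10)
        assert s.sd_log_area == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_values(self):
        s = histoquant.droplet_summary([np.e**2, np.e**4])
        assert s.mean_log_area == pytest.approx(3.0)
        assert s.sd_log_area == pytest.approx(np.sqrt(2.0))
        assert s.sem_mean == pytest.approx(np.sqrt(2.0) / np.sqrt(2))
        assert s.sem_sd == pytest.approx(np.sqrt(2.0 / 2.0))

    def test_subsample_reproducible(self, rng):
        areas = rng.uniform(1e4, 5e4, size=500)
        a = histoquant.droplet_summary(areas, subsample=200, seed=3)
        b = histoquant.droplet_summary(areas, subsample=200, seed=3)
        assert a == b and a.n == 200

    def test_too_few_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            histoquant.droplet_summary([100.0])


class TestCollagenFraction:
    def test_uniform_collagen_image(self):
        img = blank_image(color=(200, 220, 230))
        assert histoquant.collagen_fraction(img) == 1.0

    def test_no_collagen(self):
        assert histoquant.collagen_fraction(blank_image()) == 0.0

    def test_counting_oracle_on_known_mix(self):
        img = blank_image(100, 100)
        img[:20] = (245, 245, 245)  # white: 2000 px
        img[20:50] = (200, 220, 230)  # collagen: 3000 px
        assert histoquant.collagen_fraction(img) == pytest.approx(3000 / 8000)

    def test_all_white_rejected(self):
        with pytest.raises(ValueError, match="tissue area"):
            histoquant.collagen_fraction(blank_image(color=(245, 245, 245)))


class TestBruteForceOracleEquivalence:
    """The vectorized droplet/nucleus/collagen rules must agree exactly with
    a dumb per-pixel re-implementation on rendered images."""

    @staticmethod
    def brute_force_collagen(img):
        collagen = tissue = 0
        for r in range(img.shape[0]):
            for c in range(img.shape[1]):
                R, G, B = (int(v) for v in img[r, c])
                if min(R, G, B) >= 235:
                    continue
                tissue += 1
                if 170 <= R <= 220 and 190 <= G <= 240 and 210 <= B <= 255:
                    collagen += 1
        return collagen / tissue

    @staticmethod
    def brute_force_droplet_rule(obj, img):
        sr = sg = sb = 0
        border = False
        h, w = img.shape[:2]
        for r, c in zip(obj.rows, obj.cols):
            R, G, B = (int(v) for v in img[r, c])
            sr, sg, sb = sr + R, sg + G, sb + B
            if r < 20 or c < 20 or r >= h - 20 or c >= w - 20:
                border = True
        n = len(obj.rows)
        return min(sr / n, sg / n, sb / n) >= 190 and n > 10_000 and not border

    @pytest.mark.parametrize("seed", range(5))
    def test_rules_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img, _ = synthdata.render_adipose_image(
            n_droplets=int(rng.integers(1, 3)),
            n_nuclei=int(rng.integers(0, 8)),
            collagen_fraction_target=float(rng.uniform(0, 0.3)),
            size=(384, 384),
            radius_lognormal=(4.10, 0.01),
            seed=seed + 100,
        )
        assert histoquant.collagen_fraction(img) == pytest.approx(
            self.brute_force_collagen(img), abs=1e-12
        )
        objects = histoquant.segment_droplets_classical(img)
        kept = histoquant.classify_droplets(objects, img.shape[:2])
        brute = [o.object_id for o in objects if self.brute_force_droplet_rule(o, img)]
        assert sorted(kept["object_id"]) == sorted(brute)


class TestSegmentDropletsClassical:
    def test_disjoint_truth_droplets_recovered_with_iou(self):
        img, truth = synthdata.render_adipose_image(
            n_droplets=4, n_nuclei=5, size=(640, 640), seed=2
        )
        objects = histoquant.segment_droplets_classical(img)
        droplets = truth[truth["class"] == "droplet"]
        assert len(objects) == len(droplets)
        yy, xx = np.mgrid[0:640, 0:640]
        for _, row in droplets.iterrows():
            tmask = (yy - row["center_row"]) ** 2 + (xx - row["center_col"]) ** 2 <= row["radius"] ** 2
            best = 0.0
            for o in objects:
                omask = np.zeros((640, 640), bool)
                omask[o.rows, o.cols] = True
                inter = (tmask & omask).sum()
                union = (tmask | omask).sum()
                best = max(best, inter / union)
            assert best >= 0.9

    def test_blank_image_empty(self):
        assert histoquant.segment_droplets_classical(blank_image()) == []
        assert histoquant.segment_nuclei_classical(blank_image()) == []

    def test_nucleus_segmenter_finds_rendered_nuclei(self):
        img, truth = synthdata.render_adipose_image(
            n_droplets=1, n_nuclei=6, size=(384, 384), seed=11
        )
        nuclei = histoquant.classify_nuclei(histoquant.segment_nuclei_classical(img))
        assert len(nuclei) == (truth["class"] == "nucleus").sum()

    def test_touching_droplets_split_by_watershed(self):
        img = blank_image(400, 400)
        paint(img, (200, 140), 62, (245, 245, 245))
        paint(img, (200, 260), 62, (245, 245, 245))  # gap 120 < 124: touching
        objects = histoquant.segment_droplets_classical(img)
        assert len(objects) == 2


class TestMitoMorphology:
    def test_single_voxel_volume_definition(self):
        vol = np.zeros((5, 5, 5), dtype=np.uint16)
        vol[2, 2, 2] = 1
        m = histoquant.mito_morphology(vol, (0.3, 0.1, 0.1), allow_anisotropy=True)
        assert m.objects[0].volume_um3 == pytest.approx(0.003)

    def test_ball_sphericity_near_unity(self):
        zz, yy, xx = np.mgrid[0:25, 0:25, 0:25]
        ball = (((zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2) <= 100).astype(np.uint16)
        m = histoquant.mito_morphology(ball, (1.0, 1.0, 1.0))
        assert 0.95 <= m.objects[0].sphericity <= 1.05

    def test_sphericity_scale_invariant(self):
        psi = []
        for r, n in ((6, 17), (12, 29)):
            zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
            c = n // 2
            ball = (((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r * r).astype(np.uint16)
            m = histoquant.mito_morphology(ball, (1.0, 1.0, 1.0))
            psi.append(m.objects[0].sphericity)
        assert psi[1] == pytest.approx(psi[0], rel=0.05)

    def test_rod_scores_below_equal_volume_ball(self):
        # capsule and ball of equal analytic volume
        zz, yy, xx = np.mgrid[0:20, 0:60, 0:20]
        axis_dist = np.sqrt((zz - 10) ** 2 + (xx - 10) ** 2)
        proj = np.clip(yy - 30, -15, 15)
        rod = (np.sqrt(axis_dist**2 + (yy - 30 - proj) ** 2) <= 5).astype(np.uint16)
        m_rod = histoquant.mito_morphology(rod, (1.0, 1.0, 1.0))
        v_rod = m_rod.objects[0].volume_um3
        r_ball = (3 * v_rod / (4 * np.pi)) ** (1 / 3)
        n = int(2 * r_ball + 9)
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
        c = n // 2
        ball = (((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= r_ball**2).astype(np.uint16)
        m_ball = histoquant.mito_morphology(ball, (1.0, 1.0, 1.0))
        assert m_rod.objects[0].sphericity < m_ball.objects[0].sphericity

    def test_density_uses_cytoplasm_mask(self):
        vol = np.zeros((4, 4, 4), dtype=np.uint16)
        vol[1, 1, 1] = 1
        vol[2, 2, 2] = 2
        cyto = np.ones_like(vol, dtype=bool)
        m = histoquant.mito_morphology(vol, (1.0, 1.0, 1.0), cytoplasm_mask=cyto)
        assert m.density_per_um3 == pytest.approx(2 / 64)

    def test_anisotropy_warning_recorded(self):
        vol = np.zeros((4, 4, 4), dtype=np.uint16)
        vol[1:3, 1:3, 1:3] = 1
        m = histoquant.mito_morphology(vol, (0.3, 0.1, 0.1))
        assert any("anisotropic" in w for w in m.warnings)
        m2 = histoquant.mito_morphology(vol, (0.3, 0.1, 0.1), allow_anisotropy=True)
        assert m2.warnings == []


class TestStackDepth:
    def test_instrument_pairing(self):
        assert histoquant.stack_depth(41, 0.3) == pytest.approx(12.3)

    def test_single_slice(self):
        assert histoquant.stack_depth(1, 0.7) == pytest.approx(0.7)

    def test_fifty_slices(self):
        assert histoquant.stack_depth(50, 0.3) == pytest.approx(15.0)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            histoquant.stack_depth(0, 0.3)
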