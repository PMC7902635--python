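"""Color conversion, segmentation and polar sampling."""

import numpy as np
import pytest

from polypfeat import imaging
from polypfeat.errors import InvalidInputError, SegmentationError
from polypfeat.imaging import BinaryMask

from conftest import ellipse_mask


class TestYCbCr:
    def test_achromatic_input_has_constant_chroma(self):
        for c in (0, 64, 200, 255):
            img = np.full((32, 32, 3), c, dtype=np.uint8)
            ycc = imaging.rgb_to_ycbcr(img)
            assert np.allclose(ycc.cb, 128.0)
            assert np.allclose(ycc.cr, 128.0)
        lows = imaging.rgb_to_ycbcr(np.full((32, 32, 3), 10, np.uint8)).y
        highs = imaging.rgb_to_ycbcr(np.full((32, 32, 3), 200, np.uint8)).y
        assert highs.mean() > lows.mean()

    def test_pure_red_matches_bt601_hand_computation(self):
        img = np.zeros((32, 32, 3), dtype=np.uint8)
        img[0, 0] = (255, 0, 0)
        ycc = imaging.rgb_to_ycbcr(img)
        assert ycc.y[0, 0] == pytest.approx(0.299 * 255, abs=1e-9)
        assert ycc.cb[0, 0] == pytest.approx(128 - 0.168735892 * 255, abs=1e-6)
        assert ycc.cr[0, 0] == pytest.approx(128 + 0.5 * 255, abs=1e-9)

    def test_round_trip_within_one_intensity_step(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (40, 40, 3), dtype=np.uint8)
        back = imaging.ycbcr_to_rgb(imaging.rgb_to_ycbcr(img))
        assert np.abs(back.astype(int) - img.astype(int)).max() <= 1

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(InvalidInputError):
            imaging.rgb_to_ycbcr(np.zeros((32, 32, 4), dtype=np.uint8))
        with pytest.raises(InvalidInputError):
            imaging.rgb_to_ycbcr(np.zeros((32, 32), dtype=np.uint8))


class TestSegmentPolyp:
    @staticmethod
    def _disk_image(noise_sigma=0.0, seed=0):
        disk = ellipse_mask((96, 96), (48, 48), (22, 22))
        img = np.where(disk, 200.0, 30.0)
        if noise_sigma:
            img = img + np.random.default_rng(seed).normal(0, noise_sigma, img.shape)
        return np.clip(img, 0, 255).astype(np.uint8)[..., None].repeat(3, axis=2), disk

    def test_noiseless_disk_matches_threshold_oracle(self):
        img, disk = self._disk_image()
        # oracle: threshold at the midpoint of the two intensities
        oracle = img[:, :, 0] > (200 + 30) / 2
        got = imaging.segment_polyp(img).mask
        # agreement up to a 1-pixel boundary band
        from scipy import ndimage
        band = ndimage.binary_dilation(disk) & ~ndimage.binary_erosion(disk)
        assert np.array_equal(got[~band], oracle[~band])

    def test_noisy_disk_area_within_five_percent(self):
        _, disk = self._disk_image()
        true_area = disk.sum()
        for seed in range(20):
            img, _ = self._disk_image(noise_sigma=10.0, seed=seed)
            got = imaging.segment_polyp(img)
            assert abs(got.area - true_area) / true_area < 0.05

    def test_constant_image_raises(self):
        img = np.full((64, 64, 3), 90, dtype=np.uint8)
        with pytest.raises(SegmentationError):
            imaging.segment_polyp(img)

    def test_invariant_to_affine_intensity_rescaling(self):
        img, _ = self._disk_image(noise_sigma=8.0, seed=3)
        rescaled = np.clip(img.astype(float) * 0.5 + 40, 0, 255).astype(np.uint8)
        a = imaging.segment_polyp(img).mask
        b = imaging.segment_polyp(rescaled).mask
        assert np.array_equal(a, b)


class TestPolarResample:
    def test_centered_disk_rings_inside_are_one(self, disk_mask):
        ps = imaging.polar_resample(disk_mask, R=32, T=48)
        disk_r = 20.0
        radii = np.linspace(0, ps.ring_radius, 32)
        inside = radii < disk_r - 1.5
        outside = radii > disk_r + 1.5
        assert np.all(ps.values[inside] > 0.99)
        assert np.all(ps.values[outside] < 0.01)
        assert ps.values[0].std() == 0  # ring 0 is the centroid value

    def test_translation_invariance_is_exact(self):
        m = ellipse_mask((128, 128), (50, 44), (18, 11))
        shifted = np.roll(np.roll(m, 13, axis=0), -7, axis=1)
        a = imaging.polar_resample(BinaryMask.from_array(m), 32, 64)
        b = imaging.polar_resample(BinaryMask.from_array(shifted), 32, 64)
        assert np.abs(a.values - b.values).max() < 1e-12
        assert a.ring_radius == pytest.approx(b.ring_radius, abs=1e-12)

    def test_rotation_by_quarter_turn_permutes_angles(self):
        rows, cols = np.meshgrid(np.arange(65), np.arange(65), indexing="ij")
        m = (((rows - 32) / 14) ** 2 + ((cols - 30) / 8) ** 2 <= 1) | (
            ((rows - 32) / 5) ** 2 + ((cols - 44) / 7) ** 2 <= 1
        )
        T = 64
        a = imaging.polar_resample(BinaryMask.from_array(m), 32, T)
        b = imaging.polar_resample(BinaryMask.from_array(np.rot90(m)), 32, T)
        assert np.abs(np.roll(a.values, -T // 4, axis=1) - b.values).max() < 1e-6

    def test_half_plane_matches_geometric_oracle(self):
        H = W = 64
        rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
        m = cols >= W // 2
        bm = BinaryMask.from_array(m)
        R, T = 24, 32
        ps = imaging.polar_resample(bm, R, T)
        cy, cx = bm.centroid
        radii = np.linspace(0, ps.ring_radius, R)
        theta = 2 * np.pi * np.arange(T) / T
        pr = cy + radii[:, None] * np.sin(theta)[None, :]
        pc = cx + radii[:, None] * np.cos(theta)[None, :]
        inside_img = (pr >= 0) & (pr <= H - 1) & (pc >= 0) & (pc <= W - 1)
        clear = inside_img & (np.abs(pc - (W // 2 - 0.5)) > 1.0)  # off the edge
        oracle = (pc >= W // 2 - 0.5).astype(float)
        assert np.array_equal(ps.values[clear] > 0.5, oracle[clear] > 0.5)

    def test_invalid_resolutions_rejected(self, disk_mask):
        with pytest.raises(InvalidInputError):
            imaging.polar_resample(disk_mask, 0, 8)
        with pytest.raises(InvalidInputError):
            imaging.polar_resample(disk_mask, 8, 0)


class TestMaskTypes:
    def test_centroid_and_area_match_definition(self):
        m = ellipse_mask((64, 64), (30, 35), (10, 6))
        bm = BinaryMask.from_array(m)
        rows, cols = np.nonzero(m)
        assert bm.area == rows.size
        assert bm.centroid == (rows.mean(), cols.mean())

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidInputError):
            BinaryMask.from_array(np.zeros((16, 16), bool))

    def test_rle_round_trip(self, tmp_path):
        m = ellipse_mask((40, 40), (20, 20), (8, 5))
        flat = m.ravel()
        runs = []
        i = 0
        while i < flat.size:
            if flat[i]:
                j = i
                while j < flat.size and flat[j]:
                    j += 1
                runs.append((i, j - i))
                i = j
            else:
                i += 1
        text = "40 40\n" + "\n".join(f"{s} {l}" for s, l in runs)
        p = tmp_path / "mask.rle"
        p.write_text(text)
        loaded = imaging.load_mask(p)
        assert np.array_equal(loaded.mask, m)
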