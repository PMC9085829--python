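"""Clearing-performance metrics: identities, oracles, and recovery checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

from glomorph.metrics import (
    OutlinePair,
    align_rigid,
    area_change_ratio,
    extract_outline_area,
    linear_expansion,
    normalized_fluorescence,
    relative_transmittance_grid,
    snr_profile,
    spectral_transmittance,
    ssim_binary,
    tortuosity,
)
from glomorph.synthetic import generate_dendrite_stack


class TestOutlineArea:
    def test_disc_area_within_1pct(self):
        yy, xx = np.mgrid[0:256, 0:256]
        img = np.where((yy - 128) ** 2 + (xx - 128) ** 2 <= 100**2, 220.0, 15.0)
        area, polygon = extract_outline_area(img)
        assert area == pytest.approx(math.pi * 100**2, rel=0.01)
        assert len(polygon) > 100

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64)) * 50
        img[20:40, 20:40] = 200
        a1, _ = extract_outline_area(img)
        a2, _ = extract_outline_area(img)
        assert a1 == a2

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            extract_outline_area(np.full((32, 32), 5.0))


class TestExpansionRatios:
    def test_trivial_values(self):
        assert linear_expansion(OutlinePair(100.0, 100.0)) == pytest.approx(1.0)
        assert linear_expansion(OutlinePair(100.0, 400.0)) == pytest.approx(2.0)
        assert area_change_ratio(OutlinePair(100.0, 200.0)) == pytest.approx(2.0)

    def test_sub_percent_shrinkage_regime(self):
        # a 0.981 area ratio corresponds to ~0.95% linear shrinkage
        val = linear_expansion(OutlinePair(1.0, 0.981))
        assert val == pytest.approx(0.99045, abs=1e-4)

    def test_square_consistency(self):
        pair = OutlinePair(123.0, 456.0)
        assert linear_expansion(pair) ** 2 == pytest.approx(area_change_ratio(pair), abs=1e-9)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_law(self, a, b, c):
        lhs = linear_expansion(OutlinePair(a, b)) * linear_expansion(OutlinePair(b, c))
        rhs = linear_expansion(OutlinePair(a, c))
        assert lhs == pytest.approx(rhs, abs=1e-9, rel=1e-9)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            OutlinePair(0.0, 1.0)


class TestTransmittance:
    def test_grid_identities(self):
        img = np.full((32, 32), 50.0)
        inner = np.zeros((32, 32), bool)
        outer = np.zeros((32, 32), bool)
        inner[10:12, :] = True
        outer[20:22, :] = True
        assert relative_transmittance_grid(img, inner, outer) == pytest.approx(100.0)
        img2 = img.copy()
        img2[inner] = 0.0
        assert relative_transmittance_grid(img2, inner, outer) == pytest.approx(0.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(10, 200, size=(40, 40))
        inner = np.zeros((40, 40), bool)
        outer = np.zeros((40, 40), bool)
        inner[5:10, 5:10] = True
        outer[25:30, 25:30] = True
        t1 = relative_transmittance_grid(img, inner, outer)
        t2 = relative_transmittance_grid(3.7 * img, inner, outer)
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_masks_must_be_disjoint(self):
        img = np.ones((8, 8))
        m = np.ones((8, 8), bool)
        with pytest.raises(ValueError):
            relative_transmittance_grid(img, m, m)

    def test_spectral_identities(self):
        wl = np.arange(400, 801, 50, dtype=float)
        blank = np.full_like(wl, 2.0)
        assert np.allclose(spectral_transmittance(wl, blank, wl, blank), 100.0)
        assert np.allclose(spectral_transmittance(wl, np.zeros_like(wl), wl, blank), 0.0)
        assert np.allclose(spectral_transmittance(wl, blank / 2, wl, blank), 50.0)

    def test_wavelength_mismatch_rejected(self):
        wl = np.arange(400, 500, 10, dtype=float)
        with pytest.raises(ValueError):
            spectral_transmittance(wl, wl, wl + 5, wl)


class TestNormalizedFluorescence:
    def test_example_and_day0(self):
        days = [0, 2]
        vals = normalized_fluorescence(days, [100.0, 60.0], [20.0, 20.0])
        assert vals[0] == 1.0
        assert vals[1] == pytest.approx(0.5)

    def test_constant_net_signal_all_ones(self):
        days = [0, 1, 2, 3]
        vals = normalized_fluorescence(days, [90, 100, 110, 120], [10, 20, 30, 40])
        assert np.allclose(vals, 1.0)

    def test_missing_day0_rejected(self):
        with pytest.raises(ValueError):
            normalized_fluorescence([1, 2], [10, 10], [1, 1])

    def test_nonpositive_day0_net_rejected(self):
        with pytest.raises(ValueError):
            normalized_fluorescence([0, 1], [10, 10], [20, 1])


class TestSNRProfile:
    def test_constructed_contrast_recovered(self):
        stack, recs = generate_dendrite_stack(
            40.0, [(0.0, 4.0), (40.0, 4.0)], path_tortuosity=1.05,
            noise_sigma=0.0, seed=3)
        prof = snr_profile(stack, recs, depths=[0.0, 20.0, 40.0], seed=0)
        for _, snr in prof:
            assert snr == pytest.approx(4.0, rel=0.10)

    def test_uniform_plane_gives_unity(self):
        stack, recs = generate_dendrite_stack(
            20.0, [(0.0, 1.0)], path_tortuosity=1.05, noise_sigma=0.0, seed=3)
        prof = snr_profile(stack, recs, depths=[0.0], seed=0)
        assert prof[0][1] == pytest.approx(1.0, rel=0.02)

    def test_decreasing_schedule_gives_decreasing_profile(self):
        stack, recs = generate_dendrite_stack(
            80.0, [(0.0, 4.0), (80.0, 1.2)], path_tortuosity=1.05,
            noise_sigma=0.5, seed=3)
        prof = snr_profile(stack, recs, depths=[0.0, 20.0, 40.0, 60.0, 80.0],
                          n_dendrites=5, seed=1)
        values = [v for _, v in prof]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_too_few_dendrites_rejected(self):
        stack, recs = generate_dendrite_stack(
            20.0, [(0.0, 4.0)], path_tortuosity=1.05, seed=3)
        with pytest.raises(ValueError, match="at least"):
            snr_profile(stack, recs, depths=[0.0], n_dendrites=10)


class TestTortuosity:
    def test_straight_and_semicircle(self):
        assert tortuosity(np.array([[0, 0, 0], [5, 5, 5]])) == pytest.approx(1.0)
        t = np.linspace(0, math.pi, 400)
        arc = np.stack([np.zeros_like(t), np.sin(t), np.cos(t)], axis=1) * 30.0
        assert tortuosity(arc) == pytest.approx(math.pi / 2, rel=1e-4)

    @given(st.integers(0, 1000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_never_below_one(self, seed):
        rng = np.random.default_rng(seed)
        path = np.cumsum(rng.normal(size=(8, 3)), axis=0)
        if np.linalg.norm(path[-1] - path[0]) < 1e-9:
            return
        assert tortuosity(path) >= 1.0 - 1e-9

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            tortuosity(np.array([[1.0, 2, 3], [4, 5, 6], [1.0, 2, 3]]))


class TestRigidAlignment:
    def _scene(self):
        rng = np.random.default_rng(4)
        img = ndi.gaussian_filter(rng.random((96, 96)), 3)
        img[30:60, 40:55] += 1.0
        return img

    def test_self_alignment_is_identity(self):
        img = self._scene()
        tf, moved = align_rigid(img, img)
        assert tf["angle_deg"] == 0.0
        assert tf["shift"] == (0.0, 0.0)
        assert tf["correlation"] > 0.999

    def test_known_shift_recovered(self):
        img = self._scene()
        shifted = ndi.shift(img, (5, -3), order=1, mode="nearest")
        tf, moved = align_rigid(img, shifted)
        # the reported shift is the one applied to image_b to match image_a
        assert abs(tf["shift"][0] + 5) <= 0.5
        assert abs(tf["shift"][1] - 3) <= 0.5
        assert np.corrcoef(img[8:-8, 8:-8].ravel(), moved[8:-8, 8:-8].ravel())[0, 1] > 0.99

    def test_known_rotation_recovered_within_step(self):
        img = self._scene()
        rot = ndi.rotate(img, -10.0, reshape=False, order=1, mode="nearest")
        tf, moved = align_rigid(img, rot, rotation_range=15.0, rotation_step=1.0)
        assert abs(tf["angle_deg"] - 10.0) <= 1.0


def hand_ssim_window(a: np.ndarray, b: np.ndarray) -> float:
    """Direct evaluation of the SSIM formula on one 11×11 window."""
    from scipy.ndimage import gaussian_filter

    # gaussian weights, sigma 1.5, truncated to the 11x11 window
    k = np.zeros((11, 11))
    k[5, 5] = 1.0
    w = gaussian_filter(k, 1.5, truncate=3.5)
    w /= w.sum()
    mu_a, mu_b = (w * a).sum(), (w * b).sum()
    var_a = (w * (a - mu_a) ** 2).sum()
    var_b = (w * (b - mu_b) ** 2).sum()
    cov = (w * (a - mu_a) * (b - mu_b)).sum()
    C1, C2 = 0.01**2, 0.03**2
    return ((2 * mu_a * mu_b + C1) * (2 * cov + C2)
            / ((mu_a**2 + mu_b**2 + C1) * (var_a + var_b + C2)))


class TestSSIM:
    def test_identical_images_give_one(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64))
        assert ssim_binary(img, img) == pytest.approx(1.0)

    def test_complement_strongly_negative(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        assert ssim_binary(img, 1.0 - img) < 0.0

    def test_single_window_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        a = (rng.random((11, 11)) > 0.5).astype(float)
        b = (rng.random((11, 11)) > 0.5).astype(float)
        # feed pre-binarized images so ssim_binary's Otsu step is a no-op
        assert ssim_binary(a, b) == pytest.approx(hand_ssim_window(a, b), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim_binary(np.zeros((8, 8)), np.zeros((9, 9)))
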