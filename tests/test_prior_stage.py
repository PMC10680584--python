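import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu
from skimage.morphology import disk
from skimage.util import img_as_ubyte

from conftest import make_disk
from oracles import gas_oracle, lmsf_oracle, local_otsu_oracle, multiotsu3_oracle
from unseg.core_io import UnsegParams
from unseg.prior_stage import (
    EmpiricalCDF,
    apriori_probability,
    gas,
    global_mask,
    initial_foreground,
    lmsf,
    local_mask,
    prior_stage_outputs,
)


class TestInitialForeground:
    def test_bright_disks_recovered(self, rng):
        img = np.clip(rng.normal(0.05, 0.01, (96, 96)), 0, 1)
        disks = (make_disk((96, 96), (30, 30), 10)
                 | make_disk((96, 96), (65, 60), 12))
        img[disks] = 0.8
        fg = initial_foreground(img, sigma=3.0)
        eroded = ndi.binary_erosion(disks, iterations=3)
        assert fg[eroded].all()
        far = ~ndi.binary_dilation(disks, iterations=12)
        assert not fg[far].any()

    def test_all_zero_image(self):
        assert not initial_foreground(np.zeros((32, 32)), 3.0).any()

    def test_lower_multiotsu_threshold_matches_oracle(self, rng):
        img = ndi.gaussian_filter(rng.random((40, 40)), 3.0)
        lo, hi = multiotsu3_oracle(img)
        ref = threshold_multiotsu(img, classes=3)
        assert np.allclose(ref, (lo, hi))
        assert np.array_equal(initial_foreground(img, 1e-9), img > lo)


class TestAprioriProbability:
    def test_max_foreground_intensity_maps_to_one(self, rng):
        img = rng.random((16, 16))
        fg = img > 0.5
        Pe = apriori_probability(img, fg)
        peak = np.unravel_index(np.argmax(np.where(fg, img, -1)), img.shape)
        assert Pe[peak] == 1.0

    def test_hand_enumerated_cdf(self):
        cdf = EmpiricalCDF(np.array([0.2, 0.5, 0.9]))
        assert cdf(np.array([0.5]))[0] == pytest.approx(2 / 3)
        assert cdf(np.array([0.1]))[0] == 0.0
        assert cdf(np.array([0.9]))[0] == 1.0

    def test_monotone_in_intensity(self, rng):
        img = rng.random((16, 16))
        Pe = apriori_probability(img, img > 0.3)
        order = np.argsort(img.ravel())
        assert (np.diff(Pe.ravel()[order]) >= 0).all()

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="empty foreground"):
            apriori_probability(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


class TestLmsf:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 0.4)
        out = lmsf(img, t0=0.5, n0=3)
        # interior windows are fully inside: ratio 1 >= t0; borders see
        # zero padding, ratio > 1
        assert np.array_equal(out, img)

    def test_single_bright_pixel_kept(self):
        img = np.zeros((15, 15))
        img[7, 7] = 1.0
        out = lmsf(img, t0=0.5, n0=5)
        assert out[7, 7] == 1.0 and out.sum() == 1.0

    def test_matches_double_loop_oracle(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(lmsf(img, 0.5, 2), lmsf_oracle(img, 0.5, 2))

    def test_never_increases_values(self, rng):
        img = rng.random((20, 20))
        assert (lmsf(img, 0.7, 4) <= img).all()

    def test_all_zero_neighborhood_zeroes_pixel(self):
        assert lmsf(np.zeros((9, 9)), 0.5, 2).sum() == 0.0


class TestGlobalMask:
    def test_valley_removed(self):
        img = np.full((40, 80), 0.02)
        img[:, :37] = 0.8
        img[:, 43:] = 0.8
        params = UnsegParams(n0_list=(5, 10))
        Pe = np.ones_like(img)
        Mg = global_mask(img, Pe, params, 0.01)
        assert not Mg[:, 38:42].any()
        assert Mg[20, 10] and Mg[20, 70]

    def test_uniform_bright_all_kept(self):
        img = np.full((30, 30), 0.8)
        params = UnsegParams(n0_list=(5,))
        assert global_mask(img, np.ones_like(img), params, 0.01).all()

    def test_prior_refinement_removes_low_pe(self):
        img = np.full((30, 30), 0.8)
        params = UnsegParams(n0_list=(5,))
        Pe = np.ones_like(img)
        Pe[10, 10] = 0.005
        Mg = global_mask(img, Pe, params, 0.01)
        assert not Mg[10, 10] and Mg[0, 0]

    def test_any_scale_zeroing_removes_pixel(self):
        # a pixel surviving the small scale but suppressed at the large one
        img = np.full((81, 81), 0.01)
        img[35:46, 35:46] = 0.3  # bright square, dim relative to nothing local
        img[40, 40] = 0.35
        params = UnsegParams(n0_list=(2, 40))
        Mg_small_only = global_mask(img, np.ones_like(img),
                                    UnsegParams(n0_list=(2,)), 0.01)
        Mg_both = global_mask(img, np.ones_like(img), params, 0.01)
        assert (Mg_both <= Mg_small_only).all()


class TestGas:
    def test_constant_unchanged(self):
        img = np.full((12, 12), 0.6)
        assert np.allclose(gas(img, 1.0), img)

    def test_edge_preserved_vs_box_filter(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 1.0
        smoothed = gas(img, 0.2)
        box = ndi.uniform_filter(img, size=3)
        g_gas = np.abs(np.gradient(smoothed, axis=1))[:, 7:9].max()
        g_box = np.abs(np.gradient(box, axis=1))[:, 7:9].max()
        assert g_gas >= g_box

    def test_matches_per_pixel_oracle(self, rng):
        img = rng.random((16, 16))
        assert np.abs(gas(img, 1.0) - gas_oracle(img, 1.0)).max() < 1e-12


class TestLocalMask:
    def test_restricted_to_global_mask(self, rng):
        img = rng.random((20, 20))
        Mg = np.zeros((20, 20), dtype=bool)
        Mg[5:15, 5:15] = True
        Ml = local_mask(img, 3, Mg)
        assert not Ml[~Mg].any()

    def test_matches_sliding_window_oracle(self, rng):
        img = rng.random((9, 9))
        u8 = img_as_ubyte(np.clip(img, 0, 1))
        thr = local_otsu_oracle(u8, disk(2))
        expect = u8 > thr
        Ml = local_mask(img, 2, np.ones((9, 9), dtype=bool))
        assert np.array_equal(Ml, expect)

    def test_bright_disk_inside_halo(self):
        # halo thin enough (4 px) that every halo pixel's r0 = 5 window
        # reaches the bright core and thresholds between core and halo
        img = np.full((40, 40), 0.05)
        halo = make_disk((40, 40), (20, 20), 12)
        core = make_disk((40, 40), (20, 20), 8)
        img[halo] = 0.3
        img[core] = 0.9
        Mg = make_disk((40, 40), (20, 20), 14)
        Ml = local_mask(img, 5, Mg)
        inner = make_disk((40, 40), (20, 20), 6)
        assert Ml[inner].all()
        halo_only = halo & ~make_disk((40, 40), (20, 20), 9.5)
        assert Ml[halo_only].mean() < 0.1


class TestStageOutputs:
    def test_local_subset_of_global(self, rng):
        img = np.clip(rng.normal(0.05, 0.02, (64, 64)), 0, 1)
        img[make_disk((64, 64), (32, 32), 12)] = 0.8
        out = prior_stage_outputs(img, UnsegParams(), 0.01)
        assert not (out["Ml"] & ~out["Mg"]).any()

    def test_deterministic(self, rng):
        img = np.clip(rng.normal(0.05, 0.02, (64, 64)), 0, 1)
        img[make_disk((64, 64), (32, 32), 12)] = 0.8
        a = prior_stage_outputs(img, UnsegParams(), 0.01)
        b = prior_stage_outputs(img, UnsegParams(), 0.01)
        for key in ("Pe", "Mg", "Ml"):
            assert np.array_equal(a[key], b[key])


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3))
def test_lmsf_oracle_property(seed, n0):
    img = np.random.default_rng(seed).random((12, 12))
    assert np.array_equal(lmsf(img, 0.5, n0), lmsf_oracle(img, 0.5, n0))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1),
       st.floats(0.3, 3.0, allow_nan=False))
def test_gas_oracle_property(seed, k0):
    img = np.random.default_rng(seed).random((12, 12))
    assert np.abs(gas(img, k0) - gas_oracle(img, k0)).max() < 1e-12
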