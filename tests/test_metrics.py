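"""Ventilation-metric unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xvlung import (
    CTVolume,
    LungMask,
    PhaseSeries,
    VentilationVolume,
    compute_msv,
    compute_tidal_volume,
    compute_vdp,
    compute_vh,
    compute_vh_scales,
    decompose_scales,
    extract_roi_curve,
    mean_ct_gray,
)
from xvlung.metrics import roi_index_mask

import oracles


def vol_from_flat(flat, shape=(5, 1, 1), spacing=(1.0, 1.0, 1.0)):
    return VentilationVolume(np.asarray(flat, dtype=float).reshape(shape), spacing=spacing)


FULL5 = LungMask(np.ones((5, 1, 1), bool))


class TestMSV:
    def test_uniform_field(self):
        vol = VentilationVolume(np.full((10, 10, 10), 0.15))
        assert compute_msv(vol, LungMask(np.ones((10, 10, 10), bool))) == pytest.approx(0.15)

    def test_hand_enumerated_mean(self):
        vol = vol_from_flat([0.1, 0.2, 0.2, 0.2, 0.3])
        assert compute_msv(vol, FULL5) == pytest.approx(0.2)

    def test_out_of_mask_voxels_ignored(self):
        values = np.full((4, 4, 4), 9.9)
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True
        values[mask] = 0.1
        assert compute_msv(VentilationVolume(values), LungMask(mask)) == pytest.approx(0.1)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty lung mask"):
            compute_msv(VentilationVolume(np.ones((3, 3, 3))), LungMask(np.zeros((3, 3, 3), bool)))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            compute_msv(VentilationVolume(np.ones((3, 3, 3))), LungMask(np.ones((4, 3, 3), bool)))

    def test_series_uses_final_phase(self):
        vols = [
            VentilationVolume(np.full((3, 3, 3), v), phase_index=i)
            for i, v in enumerate([0.0, 0.05, 0.2])
        ]
        series = PhaseSeries(vols, mask=LungMask(np.ones((3, 3, 3), bool)))
        assert compute_msv(series, series.mask) == pytest.approx(0.2)


class TestTidalVolume:
    def test_analytic_value(self):
        # 100 voxels at SV 0.1, voxel volume 0.064 mm^3 -> 0.64 mm^3 = 6.4e-4 ml
        values = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[:1] = True  # 100 voxels
        values[mask] = 0.1
        vol = VentilationVolume(values, spacing=(0.4, 0.4, 0.4))
        assert compute_tidal_volume(vol, LungMask(mask)) == pytest.approx(6.4e-4)

    def test_zero_field_and_linearity(self, small_volume_and_mask):
        vol, mask = small_volume_and_mask
        zero = VentilationVolume(np.zeros(vol.shape), spacing=vol.spacing)
        assert compute_tidal_volume(zero, mask) == 0.0
        doubled = VentilationVolume(2 * vol.values, spacing=vol.spacing)
        assert compute_tidal_volume(doubled, mask) == pytest.approx(
            2 * compute_tidal_volume(vol, mask)
        )


class TestVDP:
    def test_hand_enumerated_count(self):
        vol = vol_from_flat([0.1, 0.2, 0.2, 0.2, 0.3])
        # own MSV 0.2, threshold 0.12 -> exactly one voxel below -> 20%
        assert compute_vdp(vol, FULL5, threshold_fraction=0.6) == pytest.approx(20.0)

    def test_uniform_field_gives_zero(self):
        vol = VentilationVolume(np.full((4, 4, 4), 0.3))
        mask = LungMask(np.ones((4, 4, 4), bool))
        assert compute_vdp(vol, mask, threshold_fraction=0.99) == 0.0

    def test_monotone_in_threshold_and_reference(self, small_volume_and_mask):
        vol, mask = small_volume_and_mask
        fracs = [0.2, 0.4, 0.6, 0.8]
        vdps = [compute_vdp(vol, mask, f, reference_msv=0.2) for f in fracs]
        assert all(a <= b for a, b in zip(vdps, vdps[1:]))
        refs = [0.05, 0.1, 0.2, 0.5]
        nvdps = [compute_vdp(vol, mask, 0.6, reference_msv=r) for r in refs]
        assert all(a <= b for a, b in zip(nvdps, nvdps[1:]))

    def test_non_positive_reference_raises(self, small_volume_and_mask):
        vol, mask = small_volume_and_mask
        with pytest.raises(ValueError, match="non-positive reference MSV"):
            compute_vdp(vol, mask, 0.6, reference_msv=0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_0_100(self, seed):
        rng = np.random.default_rng(seed)
        vol = VentilationVolume(rng.normal(0.2, 0.3, size=(4, 4, 4)))
        mask = LungMask(rng.random((4, 4, 4)) < 0.6)
        if mask.n_voxels == 0:
            return
        vdp = compute_vdp(vol, mask, 0.6, reference_msv=0.2)
        assert 0.0 <= vdp <= 100.0


class TestVH:
    def test_hand_enumerated_iqr_over_mean(self):
        vol = vol_from_flat([1, 2, 3, 4, 5])
        assert compute_vh(vol, FULL5) == pytest.approx(2.0 / 3.0, rel=1e-12)

    def test_uniform_field_gives_zero(self):
        vol = VentilationVolume(np.full((3, 3, 3), 0.4))
        assert compute_vh(vol, LungMask(np.ones((3, 3, 3), bool))) == 0.0

    def test_zero_mean_raises(self):
        vals = np.zeros((4, 1, 1))
        vals[:2, 0, 0], vals[2:, 0, 0] = 1.0, -1.0
        with pytest.raises(ValueError, match="zero-mean"):
            compute_vh(VentilationVolume(vals), LungMask(np.ones((4, 1, 1), bool)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.05, 1.0, size=(4, 4, 4))
        mask = LungMask(np.ones((4, 4, 4), bool))
        vh1 = compute_vh(VentilationVolume(values), mask)
        vh2 = compute_vh(VentilationVolume(c * values), mask)
        assert vh2 == pytest.approx(vh1, rel=1e-9)


class TestScaleDecomposition:
    def test_uniform_field_is_pure_lowpass(self):
        mask = LungMask(np.ones((6, 6, 6), bool))
        vol = VentilationVolume(np.full((6, 6, 6), 0.25), spacing=(1, 1, 1))
        low, high = decompose_scales(vol, mask, cutoff_mm=2.0)
        assert np.allclose(low.values[mask.values], 0.25, atol=1e-12)
        assert np.allclose(high.values[mask.values], 0.0, atol=1e-12)

    def test_complementarity(self, rng):
        for _ in range(5):
            values = rng.uniform(0, 1, size=(6, 5, 7))
            mask = LungMask(rng.random((6, 5, 7)) < 0.7)
            if mask.n_voxels == 0:
                continue
            vol = VentilationVolume(values, spacing=(1, 1, 1))
            low, high = decompose_scales(vol, mask, cutoff_mm=1.5)
            recon = (low.values + high.values)[mask.values]
            assert np.max(np.abs(recon - values[mask.values])) < 1e-10 * np.ptp(values)

    def test_spike_energy_in_highpass(self):
        values = np.full((9, 9, 9), 0.2)
        values[4, 4, 4] = 5.0
        mask = LungMask(np.ones((9, 9, 9), bool))
        vol = VentilationVolume(values, spacing=(1, 1, 1))
        low, high = decompose_scales(vol, mask, cutoff_mm=3.0)
        var_low = np.var(low.values[mask.values])
        var_high = np.var(high.values[mask.values])
        assert var_high > 20 * var_low

    def test_out_of_mask_values_never_leak(self, rng):
        values = rng.uniform(0, 1, size=(6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[1:5, 1:5, 1:5] = True
        vol1 = VentilationVolume(values.copy(), spacing=(1, 1, 1))
        values2 = values.copy()
        values2[~mask] = 1e6
        vol2 = VentilationVolume(values2, spacing=(1, 1, 1))
        lm = LungMask(mask)
        low1, _ = decompose_scales(vol1, lm, 2.0)
        low2, _ = decompose_scales(vol2, lm, 2.0)
        assert np.array_equal(low1.values[mask], low2.values[mask])

    def test_subvoxel_cutoff_raises(self):
        vol = VentilationVolume(np.ones((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="voxel"):
            decompose_scales(vol, LungMask(np.ones((4, 4, 4), bool)), cutoff_mm=0.5)


class TestVHScales:
    def test_uniform_field_gives_zero_pair(self):
        vol = VentilationVolume(np.full((6, 6, 6), 0.3), spacing=(1, 1, 1))
        mask = LungMask(np.ones((6, 6, 6), bool))
        vh_ss, vh_ls = compute_vh_scales(vol, mask, cutoff_mm=2.0)
        assert vh_ss == pytest.approx(0.0, abs=1e-12)
        assert vh_ls == pytest.approx(0.0, abs=1e-12)

    def test_smooth_ramp_is_large_scale(self):
        x = np.linspace(0.1, 1.0, 24)
        values = np.broadcast_to(x[:, None, None], (24, 6, 6)).copy()
        vol = VentilationVolume(values, spacing=(1, 1, 1))
        mask = LungMask(np.ones((24, 6, 6), bool))
        vh = compute_vh(vol, mask)
        vh_ss, vh_ls = compute_vh_scales(vol, mask, cutoff_mm=2.0)
        assert vh_ss < 0.05 * vh_ls
        assert vh_ls == pytest.approx(vh, rel=0.35)

    def test_fine_checkerboard_is_small_scale(self):
        idx = np.indices((12, 12, 12)).sum(axis=0)
        values = 0.2 + 0.1 * (idx % 2)
        vol = VentilationVolume(values.astype(float), spacing=(1, 1, 1))
        mask = LungMask(np.ones((12, 12, 12), bool))
        vh_ss, vh_ls = compute_vh_scales(vol, mask, cutoff_mm=3.0)
        assert vh_ls < 0.05 * vh_ss

    def test_matches_naive_oracle(self, small_volume_and_mask):
        vol, mask = small_volume_and_mask
        got = compute_vh_scales(vol, mask, cutoff_mm=1.0)
        want = oracles.naive_vh_scales(vol.values, mask.values, vol.spacing, 1.0)
        assert got == pytest.approx(want, rel=1e-9)


class TestROICurve:
    def test_whole_volume_roi_equals_whole_lung_curve(self, tumor_phantom):
        series, _ct, _truth = tumor_phantom
        extent = tuple(
            (0.0, s * n) for s, n in zip(series.spacing, series.volumes[0].shape)
        )
        curve = extract_roi_curve(series, extent)
        whole = [np.mean(v.values[series.mask.values]) for v in series.volumes]
        assert curve.phase_means == pytest.approx(whole)

    def test_single_voxel_roi_has_zero_sd(self, tumor_phantom):
        series, _ct, _truth = tumor_phantom
        idx = np.argwhere(series.mask.values)[0]
        lo = idx * np.asarray(series.spacing)
        bounds = tuple((float(lo[a]), float(lo[a] + series.spacing[a])) for a in range(3))
        curve = extract_roi_curve(series, bounds)
        assert np.all(curve.phase_sds == 0.0)

    def test_disjoint_roi_raises(self, tumor_phantom):
        series, _ct, _truth = tumor_phantom
        with pytest.raises(ValueError, match="intersect"):
            extract_roi_curve(series, ((-10.0, -5.0), (-10.0, -5.0), (-10.0, -5.0)))

    def test_voxel_center_half_open_convention(self):
        vol = VentilationVolume(np.ones((4, 4, 4)), spacing=(1.0, 1.0, 1.0))
        # centers at 0.5..3.5; box [0,1) holds only the center 0.5
        sel = roi_index_mask(vol, ((0.0, 1.0), (0.0, 4.0), (0.0, 4.0)))
        assert sel.sum() == 16 and sel[0].all() and not sel[1:].any()


class TestMeanCTGray:
    def test_uniform_and_two_level(self):
        mask = LungMask(np.ones((4, 4, 4), bool))
        assert mean_ct_gray(CTVolume(np.full((4, 4, 4), 500.0)), mask) == 500.0
        vals = np.full((4, 4, 4), 100.0)
        vals[:2] = 300.0
        assert mean_ct_gray(CTVolume(vals), mask) == pytest.approx(200.0)

    def test_denser_tumor_voxels_increase_mean(self, rng):
        vals = np.full((5, 5, 5), 200.0)
        mask = LungMask(np.ones((5, 5, 5), bool))
        before = mean_ct_gray(CTVolume(vals), mask)
        vals2 = vals.copy()
        vals2[2, 2, 2] = 600.0
        assert mean_ct_gray(CTVolume(vals2), mask) > before


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_all_metrics_match_bruteforce_oracle(seed):
    """Vectorized metrics agree with naive per-voxel loops on 5x5x5 fields."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 1.0, size=(5, 5, 5))
    mask = rng.random((5, 5, 5)) < 0.6
    if mask.sum() < 4:
        mask[:2, :2, :2] = True
    vol = VentilationVolume(values, spacing=(1.0, 1.0, 1.0))
    lm = LungMask(mask)
    assert compute_msv(vol, lm) == pytest.approx(oracles.naive_mean(values, mask), rel=1e-12)
    assert compute_tidal_volume(vol, lm) == pytest.approx(
        oracles.naive_tidal_volume_ml(values, mask, vol.spacing), rel=1e-12
    )
    assert compute_vdp(vol, lm, 0.6) == pytest.approx(oracles.naive_vdp(values, mask, 0.6))
    assert compute_vh(vol, lm) == pytest.approx(oracles.naive_vh(values, mask), rel=1e-12)
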