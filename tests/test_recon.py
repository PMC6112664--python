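from dataclasses import replace

import numpy as np
import pytest

from smsepi.encode import AcquisitionParams, caipi_line_phases, collapse_slices, encode_acquisition
from smsepi.fourier import ifft2c
from smsepi.phantom import build_coil_maps, build_phantom, default_phantom_spec
from smsepi.plan import plan
from smsepi.recon import (
    apply_kernel,
    downsample_acs,
    estimate_navigator_phase,
    fit_slice_grappa,
    fit_split_slice_grappa,
    navigator_phase_correct,
    prepare_acs_method1,
    prepare_acs_method2,
    reconstruct_reference,
    reconstruct_series,
    sos_combine,
    unfold,
)

TES = (9.0, 21.5, 34.0)


def _nrmse(a, b):
    return np.linalg.norm(a - b) / np.linalg.norm(b)


# ---------------------------------------------------------------------------
# ACS handling
# ---------------------------------------------------------------------------

class TestDownsample:
    def test_identity(self):
        k = np.arange(64 * 64, dtype=complex).reshape(64, 64)
        assert np.array_equal(downsample_acs(k, (64, 64)), k)

    def test_central_crop_preserves_dc(self):
        rng = np.random.default_rng(0)
        k = rng.standard_normal((3, 128, 68)) + 1j * rng.standard_normal((3, 128, 68))
        out = downsample_acs(k, (64, 64))
        assert out.shape == (3, 64, 64)
        # DC bin (N//2) maps to the new N//2
        assert np.array_equal(out[:, 32, 32], k[:, 64, 34])
        # brute-force index oracle
        assert np.array_equal(out, k[:, 64 - 32 : 64 + 32, 34 - 32 : 34 + 32])
        assert np.sum(np.abs(out) ** 2) <= np.sum(np.abs(k) ** 2)

    def test_impulse_at_dc(self):
        k = np.zeros((9, 9), dtype=complex)
        k[4, 4] = 1.0
        out = downsample_acs(k, (5, 5))
        assert out[2, 2] == 1.0 and np.abs(out).sum() == 1.0

    def test_upsample_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_acs(np.zeros((8, 8), dtype=complex), (16, 16))


class TestAcsPreparation:
    def test_method2_source_is_collapse(self, sb_mb4, plan_mb4):
        acs = prepare_acs_method2(sb_mb4, plan_mb4)
        assert np.allclose(acs.source, acs.target.sum(axis=1))
        assert acs.method == 2

    def test_method1_matches_method2_for_synthetic_sms(self, sb_mb4, sms_mb4, plan_mb4):
        a1 = prepare_acs_method1(sms_mb4, sb_mb4, plan_mb4)
        a2 = prepare_acs_method2(sb_mb4, plan_mb4)
        assert np.abs(a1.source - a2.source).max() < 1e-10
        assert np.abs(a1.target - a2.target).max() < 1e-10

    def test_method1_contrast_mismatch_rejected(self, sb_mb4, sms_mb4, plan_mb4):
        bad = replace(sms_mb4, params=replace(sms_mb4.params, fa=5.0))
        with pytest.raises(ValueError, match="identical"):
            prepare_acs_method1(bad, sb_mb4, plan_mb4)

    def test_mb1_identity(self):
        p = plan(n_pe=32, n_segments=4, n_slices=1, mb=1, f=1, te_list=TES, tr=261.0)
        vol = build_phantom(default_phantom_spec(grid_shape=(1, 32, 32)))
        coils = build_coil_maps(2, (32, 32), seed=5)
        sb = encode_acquisition(vol, coils, p, AcquisitionParams.from_plan(p), sms=False)
        acs = prepare_acs_method2(sb, p, grid=(32, 32))
        assert np.allclose(acs.source[0], sb.data[0, 0])
        assert np.allclose(acs.target[0, 0], sb.data[0, 0])

    def test_method2_missing_slices(self, sb_mb4, plan_mb4):
        short = replace(sb_mb4, data=sb_mb4.data[:, :4])
        with pytest.raises(ValueError, match="missing"):
            prepare_acs_method2(short, plan_mb4)


# ---------------------------------------------------------------------------
# Kernel calibration
# ---------------------------------------------------------------------------

def _dense_lstsq_weights(source, target, kh, kw):
    """Brute-force assembly of the slice-GRAPPA LS problem.

    Independent of the production path: explicit loops building one dense
    system per target coil, solved with ``lstsq``.
    """
    nc, ny, nx = source.shape
    rows = []
    for y in range(kh // 2, ny - kh // 2):
        for x in range(kw // 2, nx - kw // 2):
            row = []
            for c in range(nc):
                for dy in range(-(kh // 2), kh // 2 + 1):
                    for dx in range(-(kw // 2), kw // 2 + 1):
                        row.append(source[c, y + dy, x + dx])
            rows.append(row)
    a = np.array(rows)
    weights = np.empty((target.shape[0], nc, kh, kw), dtype=complex)
    for c in range(target.shape[0]):
        b = np.array([target[c, y, x]
                      for y in range(kh // 2, ny - kh // 2)
                      for x in range(kw // 2, nx - kw // 2)])
        w, *_ = np.linalg.lstsq(a, b, rcond=None)
        weights[c] = w.reshape(nc, kh, kw)
    return weights


class TestSliceGrappa:
    def test_mb1_identity_unfolding(self):
        p = plan(n_pe=32, n_segments=4, n_slices=1, mb=1, f=1, te_list=TES, tr=261.0)
        vol = build_phantom(default_phantom_spec(grid_shape=(1, 32, 32)))
        coils = build_coil_maps(3, (32, 32), seed=5)
        sb = encode_acquisition(vol, coils, p, AcquisitionParams.from_plan(p), sms=False)
        acs = prepare_acs_method2(sb, p, grid=(32, 32))
        k = fit_slice_grappa(acs, lam=0.0)
        pred = apply_kernel(acs.source[0, 0], k.weights[0, 0, 0])
        ref = acs.target[0, 0, 0]
        interior = np.s_[:, 2:-2, 2:-2]
        assert _nrmse(pred[interior], ref[interior]) < 1e-6

    def test_oracle_dense_lstsq_equivalence(self):
        # 16x16, 2 coils, mb = 2 noiseless instance, weights vs brute force
        p = plan(n_pe=16, n_segments=2, n_slices=2, mb=2, f=2, te_list=TES, tr=261.0)
        vol = build_phantom(default_phantom_spec(grid_shape=(2, 16, 16)))
        coils = build_coil_maps(2, (16, 16), seed=9, n_slices=2)
        sb = encode_acquisition(vol, coils, p, AcquisitionParams.from_plan(p), sms=False)
        acs = prepare_acs_method2(sb, p, grid=(16, 16))
        k = fit_slice_grappa(acs, kernel_size=(3, 3), lam=0.0)
        for s in range(2):
            oracle = _dense_lstsq_weights(acs.source[0, 0],
                                          acs.target[0, s, 0], 3, 3)
            assert np.abs(k.weights[0, 0, s] - oracle).max() < 1e-8

    def test_mb2_unfold_ground_truth(self):
        # distinct per-slice coil maps, noiseless, full-data ACS
        p = plan(n_pe=48, n_segments=2, n_slices=2, mb=2, f=2,
                 te_list=TES, tr=261.0)
        vol = build_phantom(default_phantom_spec(grid_shape=(2, 48, 48)))
        coils = build_coil_maps(8, (48, 48), seed=11, n_slices=2)
        sb = encode_acquisition(vol, coils, p, AcquisitionParams.from_plan(p),
                                sms=False)
        sms = collapse_slices(sb)
        acs = prepare_acs_method2(sb, p, grid=(48, 48))
        kern = fit_slice_grappa(acs, lam=1e-6)
        res = reconstruct_series(sms, kern)
        ref = reconstruct_reference(sb)
        for z in range(2):
            assert _nrmse(res.slice_images[0, z, 0], ref.slice_images[0, z, 0]) < 0.02

    def test_lambda_sweep_residual_monotone(self, sb_mb2, plan_mb2):
        acs = prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32))
        res = [fit_slice_grappa(acs, lam=l).residual.sum()
               for l in (0.0, 1e-6, 1e-3)]
        assert res[0] <= res[1] + 1e-12 <= res[2] + 1e-12

    def test_method1_method2_identical_kernels(self, sb_mb4, sms_mb4, plan_mb4):
        a1 = prepare_acs_method1(sms_mb4, sb_mb4, plan_mb4)
        a2 = prepare_acs_method2(sb_mb4, plan_mb4)
        k1 = fit_slice_grappa(a1, lam=1e-6)
        k2 = fit_slice_grappa(a2, lam=1e-6)
        assert np.abs(k1.weights - k2.weights).max() < 1e-8


class TestSplitSliceGrappa:
    def test_single_slice_matches_sg(self):
        p = plan(n_pe=32, n_segments=4, n_slices=1, mb=1, f=1, te_list=TES, tr=261.0)
        vol = build_phantom(default_phantom_spec(grid_shape=(1, 32, 32)))
        coils = build_coil_maps(3, (32, 32), seed=5)
        sb = encode_acquisition(vol, coils, p, AcquisitionParams.from_plan(p), sms=False)
        acs = prepare_acs_method2(sb, p, grid=(32, 32))
        ksg = fit_slice_grappa(acs, lam=1e-6)
        kssg = fit_split_slice_grappa(acs, lam=1e-6)
        assert np.abs(ksg.weights - kssg.weights).max() < 1e-8

    def test_leakage_below_sg(self, sb_mb2, plan_mb2):
        # apply slice-0 kernel to a frame containing only slice 1
        acs = prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32))
        ksg = fit_slice_grappa(acs, lam=1e-6)
        kssg = fit_split_slice_grappa(acs, lam=1e-6)
        only_b = acs.slice_sources[0, 1, 0]  # slice 1 alone
        interior = np.s_[:, 2:-2, 2:-2]  # exclude zero-padding boundary
        leak_sg = np.sum(np.abs(apply_kernel(only_b, ksg.weights[0, 0, 0])[interior]) ** 2)
        leak_ssg = np.sum(np.abs(apply_kernel(only_b, kssg.weights[0, 0, 0])[interior]) ** 2)
        total = np.sum(np.abs(only_b[interior]) ** 2)
        assert leak_ssg < leak_sg
        assert leak_ssg / total < 0.05

    def test_mb4_ground_truth(self, sb_mb4, sms_mb4, plan_mb4):
        acs = prepare_acs_method2(sb_mb4, plan_mb4)
        kern = fit_split_slice_grappa(acs, lam=1e-6)
        res = reconstruct_series(sms_mb4, kern)
        ref = reconstruct_reference(sb_mb4)
        for z in range(plan_mb4.n_slices):
            assert _nrmse(res.slice_images[0, z, 0], ref.slice_images[0, z, 0]) < 0.05

    def test_method1_acs_rejected(self, sb_mb4, sms_mb4, plan_mb4):
        acs = prepare_acs_method1(sms_mb4, sb_mb4, plan_mb4)
        with pytest.raises(ValueError, match="unseparated"):
            fit_split_slice_grappa(acs)


class TestUnfold:
    def test_roundtrip_within_fit_residual(self, sb_mb2, plan_mb2):
        acs = prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32))
        kern = fit_slice_grappa(acs, lam=1e-8)
        pred = apply_kernel(acs.source[0, 0], kern.weights[0, 0, 0])
        ref = acs.target[0, 0, 0]
        interior = np.s_[:, 2:-2, 2:-2]
        rel = np.linalg.norm((pred - ref)[interior]) / np.linalg.norm(ref[interior])
        assert rel <= max(2 * kern.residual[0, 0, 0], 1e-6)

    def test_policy_acs111_vs_acs123(self, sb_mb2, plan_mb2):
        # matched contrast, noiseless: per-echo kernels change little
        sms = collapse_slices(sb_mb2)
        acs = prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32))
        k111 = fit_slice_grappa(acs, lam=1e-6, acs_policy="acs111")
        k123 = fit_slice_grappa(acs, lam=1e-6, acs_policy="acs123")
        r111 = reconstruct_series(sms, k111).slice_images
        r123 = reconstruct_series(sms, k123).slice_images
        ref = reconstruct_reference(sb_mb2).slice_images
        for z in range(2):
            for e in range(3):
                d = abs(_nrmse(r111[0, z, e], ref[0, z, e])
                        - _nrmse(r123[0, z, e], ref[0, z, e]))
                assert d < 0.01

    def test_shift_removed(self, sb_mb4, sms_mb4, plan_mb4):
        # cross-correlation peak with ground truth at lag 0
        acs = prepare_acs_method2(sb_mb4, plan_mb4)
        kern = fit_slice_grappa(acs, lam=1e-6)
        res = reconstruct_series(sms_mb4, kern)
        ref = reconstruct_reference(sb_mb4)
        for z in range(plan_mb4.n_slices):
            a = res.slice_images[0, z, 0]
            b = ref.slice_images[0, z, 0]
            lags = [np.sum(a * np.roll(b, lag, axis=0))
                    for lag in range(plan_mb4.n_pe)]
            assert int(np.argmax(lags)) == 0

    def test_kernel_linearity(self, sb_mb2, plan_mb2):
        acs = prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32))
        kern = fit_slice_grappa(acs, lam=1e-6)
        frame = acs.source[0]
        u1 = unfold(frame, kern, group=0)
        u2 = unfold(3.0 * frame, kern, group=0)
        assert np.allclose(u2, 3.0 * u1)

    def test_coil_mismatch_rejected(self, sb_mb2, plan_mb2):
        acs = prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32))
        kern = fit_slice_grappa(acs)
        with pytest.raises(ValueError, match="coil"):
            unfold(acs.source[0][:, :2], kern)


# ---------------------------------------------------------------------------
# Ghost correction & coil combination
# ---------------------------------------------------------------------------

def _ghosted_single_slice(const, lin, n=64):
    p = plan(n_pe=n, n_segments=2, n_slices=1, mb=1, f=1, te_list=TES, tr=261.0)
    vol = build_phantom(default_phantom_spec(grid_shape=(1, n, n)))
    coils = build_coil_maps(1, (n, n))
    par = AcquisitionParams.from_plan(p, ghost_phase=(const, lin))
    ks = encode_acquisition(vol, coils, p, par, sms=False)
    return p, ks


class TestNavigatorCorrection:
    def test_no_ghost_no_change(self):
        p, ks = _ghosted_single_slice(0.0, 0.0)
        out = navigator_phase_correct(ks.data[0, 0], ks.navigators[0, 0], p)
        assert np.abs(out - ks.data[0, 0]).max() < 1e-12

    def test_constant_phase_ghost_energy_reduced(self):
        # pi/8 on odd lines -> N/(2*n_seg)-spaced ghosts; correction
        # removes > 90% of the ghost-region energy
        p, ks = _ghosted_single_slice(np.pi / 8, 0.0)
        _, clean = _ghosted_single_slice(0.0, 0.0)

        def ghost_energy(ksp):
            img = np.abs(ifft2c(ksp[0, 0]))
            ref = np.abs(ifft2c(clean.data[0, 0, 0, 0]))
            return np.sum((img - ref) ** 2)

        before = ghost_energy(ks.data[0, 0])
        corrected = navigator_phase_correct(ks.data[0, 0], ks.navigators[0, 0], p)
        after = ghost_energy(corrected)
        assert after < 0.1 * before

    def test_linear_slope_recovered(self):
        p, ks = _ghosted_single_slice(0.0, 0.01)
        const, slope = estimate_navigator_phase(ks.navigators[0, 0])
        assert slope == pytest.approx(0.01, rel=0.05)

    def test_missing_navigator_warns(self):
        p, ks = _ghosted_single_slice(0.1, 0.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = navigator_phase_correct(ks.data[0, 0], None, p)
        assert np.array_equal(out, ks.data[0, 0])


class TestSosCombine:
    def test_single_coil(self):
        img = np.array([[1 + 1j, -2.0]])
        assert np.allclose(sos_combine(img[None]), np.abs(img))

    def test_pythagoras(self):
        img = np.ones((4, 4)) * (1 + 2j)
        stack = np.stack([3 * img, 4 * img])
        assert np.allclose(sos_combine(stack), 5 * np.abs(img))

    def test_sos_normalized_maps_recover_signal(self, phantom_mb2, coils_mb2):
        sig = phantom_mb2.pd[0]
        imgs = coils_mb2.for_slice(0) * sig
        combined = sos_combine(imgs)
        sup = sig > 0
        assert np.abs(combined[sup] - sig[sup]).max() / sig.max() < 0.05

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sos_combine(np.empty((0, 4, 4)))


class TestReconstructSeries:
    def test_static_frames_identical(self, plan_mb2, phantom_mb2, coils_mb2):
        p = plan(n_pe=32, n_segments=2, n_slices=2, mb=2, f=2,
                 te_list=TES, tr=261.0, n_frames=3)
        par = AcquisitionParams.from_plan(p)
        sb = encode_acquisition(phantom_mb2, coils_mb2, p, par, sms=False)
        sms = encode_acquisition([phantom_mb2] * 3, coils_mb2, p, par, sms=True)
        kern = fit_slice_grappa(prepare_acs_method2(sb, p, grid=(32, 32)), lam=1e-6)
        res = reconstruct_series(sms, kern)
        assert np.allclose(res.slice_images[0], res.slice_images[1])
        assert np.allclose(res.slice_images[0], res.slice_images[2])

    def test_seeded_rerun_bit_identical(self, plan_mb2, phantom_mb2, coils_mb2):
        par = AcquisitionParams.from_plan(plan_mb2, noise_sd=0.01, seed=3)
        sb = encode_acquisition(phantom_mb2, coils_mb2, plan_mb2,
                                replace(par, noise_sd=0.0), sms=False)
        kern = fit_slice_grappa(prepare_acs_method2(sb, plan_mb2, grid=(32, 32)))
        outs = []
        for _ in range(2):
            sms = encode_acquisition(phantom_mb2, coils_mb2, plan_mb2, par, sms=True)
            outs.append(reconstruct_series(sms, kern).slice_images)
        assert np.array_equal(outs[0], outs[1])

    def test_non_sms_rejected(self, sb_mb2, plan_mb2):
        kern = fit_slice_grappa(prepare_acs_method2(sb_mb2, plan_mb2, grid=(32, 32)))
        with pytest.raises(ValueError, match="SMS"):
            reconstruct_series(sb_mb2, kern)
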