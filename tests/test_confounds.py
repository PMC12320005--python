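import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from strokefc.confounds import (
    acompcor,
    cosine_drift,
    dvars,
    expand_regressors,
    flag_motion_outliers,
    framewise_displacement_jenkinson,
    framewise_displacement_power,
    lesion_ica,
    make_noise_masks,
    mean_signals,
)
from strokefc.io_core import VolumeImage
from strokefc.synthdata import SynthParams, generate_subject
from tests.conftest import make_tiny_ctx

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def motion_frame(arr):
    return pd.DataFrame(np.asarray(arr, dtype=float), columns=MOTION_COLS)


class TestExpandRegressors:
    def test_constant_column(self):
        out = expand_regressors(pd.DataFrame({"c": [3.0, 3.0, 3.0]}))
        np.testing.assert_array_equal(out["c_derivative1"], [0, 0, 0])
        np.testing.assert_array_equal(out["c_power2"], [9, 9, 9])

    def test_backward_difference(self):
        out = expand_regressors(pd.DataFrame({"x": [0.0, 1.0, 3.0]}))
        np.testing.assert_array_equal(out["x_derivative1"], [0, 1, 2])

    def test_motion_expands_to_24(self):
        df = pd.DataFrame(np.random.default_rng(0).standard_normal((10, 6)),
                          columns=MOTION_COLS)
        assert expand_regressors(df).shape == (10, 24)

    def test_too_short(self):
        with pytest.raises(ValueError):
            expand_regressors(pd.DataFrame({"x": [1.0]}))


class TestFDPower:
    def test_constant_motion_zero(self):
        fd = framewise_displacement_power(motion_frame(np.ones((5, 6))))
        np.testing.assert_array_equal(fd, np.zeros(5))

    def test_single_translation_step(self):
        m = np.zeros((3, 6))
        m[1:, 0] = 0.2
        fd = framewise_displacement_power(motion_frame(m))
        np.testing.assert_allclose(fd, [0.0, 0.2, 0.0])

    def test_rotation_scaled_by_head_radius(self):
        m = np.zeros((2, 6))
        m[1, 5] = 0.01
        fd = framewise_displacement_power(motion_frame(m))
        assert fd[1] == pytest.approx(0.5)

    def test_wrong_column_count(self):
        with pytest.raises(ValueError):
            framewise_displacement_power(np.zeros((5, 5)))


class TestFDJenkinson:
    def test_constant_motion_zero(self):
        fd = framewise_displacement_jenkinson(motion_frame(np.ones((4, 6))))
        np.testing.assert_allclose(fd, 0.0, atol=1e-12)

    def test_pure_translation(self):
        m = np.zeros((2, 6))
        m[1, 0] = 0.3
        fd = framewise_displacement_jenkinson(motion_frame(m))
        assert fd[1] == pytest.approx(0.3, abs=1e-12)

    def test_sphere_moment_oracle(self):
        # independent oracle: build the relative affine with scipy Rotation
        # and evaluate E||A x + b||^2 over a solid ball (E[xx^T] = R^2/5 I)
        rng = np.random.default_rng(3)
        radius = 50.0
        m = rng.standard_normal((5, 6)) * np.array([0.5] * 3 + [0.005] * 3)
        fd = framewise_displacement_jenkinson(motion_frame(m), radius)
        for t in range(1, 5):
            affs = []
            for row in (m[t - 1], m[t]):
                rot = (Rotation.from_euler("z", row[5])
                       * Rotation.from_euler("y", row[4])
                       * Rotation.from_euler("x", row[3]))
                aff = np.eye(4)
                aff[:3, :3] = rot.as_matrix()
                aff[:3, 3] = row[:3]
                affs.append(aff)
            rel = affs[1] @ np.linalg.inv(affs[0])
            A = rel[:3, :3] - np.eye(3)
            b = rel[:3, 3]
            expected = np.sqrt(radius ** 2 / 5 * np.sum(A * A) + b @ b)
            assert fd[t] == pytest.approx(expected, abs=1e-6)

    def test_moment_formula_matches_monte_carlo(self):
        # sanity-check the closed-form ball average itself
        rng = np.random.default_rng(4)
        m = np.zeros((2, 6))
        m[1] = [0.2, -0.1, 0.3, 0.004, -0.002, 0.003]
        radius = 50.0
        fd = framewise_displacement_jenkinson(motion_frame(m), radius)[1]
        # sample uniform points in the ball
        pts = rng.standard_normal((200_000, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * rng.random(200_000)[:, None] ** (1 / 3)
        rot = (Rotation.from_euler("z", m[1, 5]) * Rotation.from_euler("y", m[1, 4])
               * Rotation.from_euler("x", m[1, 3]))
        moved = pts @ rot.as_matrix().T + m[1, :3]
        mc = np.sqrt(np.mean(np.sum((moved - pts) ** 2, axis=1)))
        assert fd == pytest.approx(mc, rel=5e-3)


class TestDvars:
    def _vol(self, data):
        return VolumeImage(np.asarray(data, dtype=float), np.eye(4), tr_s=1.0)

    def test_constant_bold_zero(self):
        bold = self._vol(np.ones((2, 2, 2, 5)))
        mask = VolumeImage(np.ones((2, 2, 2), dtype=int), np.eye(4))
        raw, std = dvars(bold, mask)
        np.testing.assert_array_equal(raw, np.zeros(5))
        np.testing.assert_array_equal(std, np.zeros(5))

    def test_single_voxel_arithmetic(self):
        data = np.zeros((1, 1, 1, 3))
        data[0, 0, 0] = [0.0, 3.0, 3.0]
        mask = VolumeImage(np.ones((1, 1, 1), dtype=int), np.eye(4))
        raw, _ = dvars(self._vol(data), mask)
        np.testing.assert_allclose(raw, [0.0, 3.0, 0.0])

    def test_standardized_median_is_one(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 4, 4, 400))
        mask = VolumeImage(np.ones((4, 4, 4), dtype=int), np.eye(4))
        _, std = dvars(self._vol(data), mask)
        assert np.median(std[1:]) == pytest.approx(1.0)

    def test_empty_mask(self):
        mask = VolumeImage(np.zeros((2, 2, 2), dtype=int), np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            dvars(self._vol(np.ones((2, 2, 2, 4))), mask)


class TestOutlierFlags:
    def test_paper_thresholds(self):
        flags = flag_motion_outliers(np.array([0.0, 0.6]), np.array([0.0, 0.0]))
        np.testing.assert_array_equal(flags, [False, True])

    def test_all_below(self):
        flags = flag_motion_outliers(np.array([0.4, 0.1]), np.array([1.0, 1.4]))
        assert not flags.any()

    def test_exactly_at_threshold_not_flagged(self):
        flags = flag_motion_outliers(np.array([0.5]), np.array([1.5]))
        assert not flags.any()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            flag_motion_outliers(np.zeros(3), np.zeros(4))


class TestNoiseMasks:
    def test_lesion_wm_voxel_reassigned(self):
        # lesion voxel deep inside WM (far from GM at x in [2,6))
        lesion_vox = (7, 4, 2)
        ctx = make_tiny_ctx(lesion_voxels=[lesion_vox])
        std = make_noise_masks(ctx, "standard")
        adj = make_noise_masks(ctx, "lesion_adjusted")
        assert std.wm_mask.data[lesion_vox] == 1
        assert std.csf_mask.data[lesion_vox] == 0
        assert adj.wm_mask.data[lesion_vox] == 0
        assert adj.csf_mask.data[lesion_vox] == 1

    def test_prob_below_threshold_excluded(self):
        shape = (8, 8, 4)
        csf = np.zeros(shape)
        csf[:2] = 1.0
        csf[0, 0, 0] = 0.98
        ctx = make_tiny_ctx(csf_prob=csf)
        masks = make_noise_masks(ctx, "standard")
        assert masks.csf_mask.data[0, 0, 0] == 0
        assert masks.csf_mask.data[0, 1, 0] == 1

    def test_gm_dilation_excludes_adjacent_wm(self):
        ctx = make_tiny_ctx()
        masks = make_noise_masks(ctx, "standard", gm_dilation_vox=1)
        # WM at x=6 is adjacent to GM at x=5 -> excluded; x=7 survives
        assert masks.wm_mask.data[6].sum() == 0
        assert masks.wm_mask.data[7].sum() > 0

    def test_combined_is_union(self):
        ctx = make_tiny_ctx()
        masks = make_noise_masks(ctx, "standard")
        union = masks.csf_mask.as_mask() | masks.wm_mask.as_mask()
        np.testing.assert_array_equal(masks.combined_mask.as_mask(), union)

    def test_variants_differ_only_near_lesion(self):
        lesion = [(7, 4, 2), (7, 4, 1)]
        ctx = make_tiny_ctx(lesion_voxels=lesion)
        std = make_noise_masks(ctx, "standard")
        adj = make_noise_masks(ctx, "lesion_adjusted")
        diff = (std.csf_mask.as_mask() != adj.csf_mask.as_mask()) | (
            std.wm_mask.as_mask() != adj.wm_mask.as_mask())
        lesion_mask = ctx.lesion_mask.as_mask()
        # differences confined to lesion voxels and their dilation shadow
        from scipy import ndimage
        near = ndimage.binary_dilation(lesion_mask, iterations=2)
        assert not np.any(diff & ~near)

    def test_empty_mask_errors(self):
        ctx = make_tiny_ctx(csf_prob=np.zeros((8, 8, 4)))
        with pytest.raises(ValueError, match="relax"):
            make_noise_masks(ctx, "standard")


class TestMeanSignals:
    def _uniform_bold(self, ctx, value=5.0, n_t=10):
        shape = ctx.brain_mask.data.shape
        return VolumeImage(np.full(shape + (n_t,), value), np.eye(4), tr_s=2.0)

    def test_uniform_value(self):
        ctx = make_tiny_ctx()
        sig = mean_signals(self._uniform_bold(ctx, 5.0), ctx, "standard")
        for col in ("global_signal", "wm", "csf"):
            np.testing.assert_allclose(sig[col], 5.0)

    def test_lesion_artifact_isolated(self):
        lesion_vox = (7, 4, 2)
        ctx = make_tiny_ctx(lesion_voxels=[lesion_vox])
        shape = ctx.brain_mask.data.shape
        rng = np.random.default_rng(0)
        artifact = rng.standard_normal(12)
        data = np.zeros(shape + (12,))
        data[lesion_vox] = artifact
        bold = VolumeImage(data, np.eye(4), tr_s=2.0)
        sig = mean_signals(bold, ctx, "lesion_adjusted")
        np.testing.assert_allclose(sig["csf_lesion"], artifact)
        np.testing.assert_allclose(sig["csf_excl_lesion"], 0.0)

    def test_including_equals_weighted_average(self):
        lesion_vox = [(7, 4, 2), (7, 4, 1), (6, 3, 2)]
        ctx = make_tiny_ctx(lesion_voxels=lesion_vox)
        shape = ctx.brain_mask.data.shape
        rng = np.random.default_rng(1)
        bold = VolumeImage(rng.standard_normal(shape + (15,)), np.eye(4), tr_s=2.0)
        from strokefc.confounds import make_noise_masks as mnm
        masks = mnm(ctx, "lesion_adjusted")
        sig = mean_signals(bold, ctx, "lesion_adjusted", noise_masks=masks)
        csf = masks.csf_mask.as_mask()
        lesion = ctx.lesion_mask.as_mask()
        n_in = (csf & lesion).sum()
        n_out = (csf & ~lesion).sum()
        combined = (n_in * sig["csf_lesion"] + n_out * sig["csf_excl_lesion"]) / (
            n_in + n_out)
        np.testing.assert_allclose(sig["csf"], combined, atol=1e-12)


class TestACompCor:
    def _bold(self, data):
        return VolumeImage(data, np.eye(4), tr_s=2.0)

    def _mask(self, shape):
        return VolumeImage(np.ones(shape, dtype=int), np.eye(4))

    def test_rank_one_structure(self):
        rng = np.random.default_rng(0)
        n_t, n_vox = 150, 30
        shared = rng.standard_normal(n_t)
        # orthogonalize the planted course against the drift basis so the
        # high-pass step leaves it intact
        drift = np.column_stack([np.ones(n_t),
                                 cosine_drift(n_t, 2.0).to_numpy()])
        shared -= drift @ np.linalg.lstsq(drift, shared, rcond=None)[0]
        data = np.empty((n_vox, 1, 1, n_t))
        for v in range(n_vox):
            data[v, 0, 0] = shared * rng.uniform(0.5, 2.0) \
                + 0.01 * rng.standard_normal(n_t)
        comps = acompcor(self._bold(data), self._mask((n_vox, 1, 1)))
        assert comps.shape[1] == 1
        r = np.corrcoef(comps.iloc[:, 0], shared)[0, 1]
        assert abs(r) > 0.99

    def test_k_matches_svd_oracle_on_noise(self):
        rng = np.random.default_rng(5)
        n_t, n_vox = 100, 40
        data = rng.standard_normal((n_vox, 1, 1, n_t))
        comps = acompcor(self._bold(data), self._mask((n_vox, 1, 1)))
        # independent oracle: same preprocessing spelled out with numpy
        x = data.reshape(n_vox, n_t)
        t = np.arange(n_t)
        order = int(2 * n_t * 2.0 // 128)
        basis = [np.ones(n_t)] + [
            np.cos(np.pi * j * (2 * t + 1) / (2 * n_t)) for j in range(1, order + 1)]
        dm = np.column_stack(basis)
        x = x - (dm @ np.linalg.lstsq(dm, x.T, rcond=None)[0]).T
        x = x / x.std(axis=1, keepdims=True)
        s = np.linalg.svd(x.T, compute_uv=False)
        cum = np.cumsum(s ** 2) / np.sum(s ** 2)
        k_expected = int(np.argmax(cum >= 0.5) + 1)
        assert comps.shape[1] == k_expected

    def test_linear_drift_removed(self):
        rng = np.random.default_rng(2)
        n_t, n_vox = 150, 25
        drift = np.linspace(0, 1, n_t)
        data = np.empty((n_vox, 1, 1, n_t))
        for v in range(n_vox):
            data[v, 0, 0] = 5 * drift + rng.standard_normal(n_t)
        comps = acompcor(self._bold(data), self._mask((n_vox, 1, 1)))
        for c in comps.columns:
            assert abs(np.corrcoef(comps[c], drift)[0, 1]) < 0.1

    def test_invariant_to_voxel_order_and_scaling(self):
        rng = np.random.default_rng(7)
        n_t, n_vox = 80, 20
        data = rng.standard_normal((n_vox, 1, 1, n_t))
        a = acompcor(self._bold(data), self._mask((n_vox, 1, 1)))
        perm = rng.permutation(n_vox)
        b = acompcor(self._bold(data[perm] * 7.3), self._mask((n_vox, 1, 1)))
        assert a.shape == b.shape
        for i in range(a.shape[1]):
            r = np.corrcoef(a.iloc[:, i], b.iloc[:, i])[0, 1]
            assert abs(r) > 1 - 1e-8


class TestLesionICA:
    def test_confined_artifact_flagged_and_recovered(self):
        p = SynthParams(seed=9, lesion_n_voxels=60, artifact_amplitude=2.0,
                        noise_sd=0.5)
        bold, ctx, *_ , truth = generate_subject(p)
        res = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask, seed=0)
        assert res.noise_flags.sum() >= 1
        best = max(
            abs(np.corrcoef(res.flagged_mixing[:, i], truth.artifact)[0, 1])
            for i in range(res.flagged_mixing.shape[1]))
        assert best > 0.95

    def test_artifact_outside_lesion_not_flagged(self):
        p = SynthParams(seed=9, lesion_n_voxels=60, artifact_amplitude=0.0,
                        n_contaminated_regions=3, contamination_amplitude=1.5,
                        noise_sd=0.5)
        bold, ctx, *_ = generate_subject(p)
        res = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask, seed=0)
        assert res.noise_flags.sum() == 0
        assert res.flagged_mixing.shape[1] == 0

    def test_overlap_threshold_inclusive(self):
        p = SynthParams(seed=9, lesion_n_voxels=60, artifact_amplitude=2.0,
                        noise_sd=0.5)
        bold, ctx, *_ = generate_subject(p)
        res = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask, seed=0)
        top = float(res.lesion_overlap.max())
        # re-run with the threshold set exactly at the observed overlap:
        # the >= rule must still flag it
        res2 = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask, seed=0,
                          overlap_threshold=top)
        assert res2.noise_flags[np.argmax(res2.lesion_overlap)]

    def test_deterministic_given_seed(self):
        p = SynthParams(seed=3, lesion_n_voxels=60, artifact_amplitude=2.0,
                        noise_sd=0.5)
        bold, ctx, *_ = generate_subject(p)
        a = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask, seed=1)
        b = lesion_ica(bold, ctx.brain_mask, ctx.lesion_mask, seed=1)
        np.testing.assert_array_equal(a.noise_flags, b.noise_flags)
        np.testing.assert_array_equal(a.mixing, b.mixing)

    def test_empty_lesion_rejected(self):
        p = SynthParams(seed=3)
        bold, ctx, *_ = generate_subject(p)
        empty = VolumeImage(np.zeros_like(ctx.lesion_mask.data),
                            ctx.lesion_mask.affine)
        with pytest.raises(ValueError, match="empty lesion"):
            lesion_ica(bold, ctx.brain_mask, empty, seed=0)


class TestCosineDrift:
    def test_count_formula(self):
        # 150 volumes at TR=2 -> 300 s -> floor(600/128) = 4 columns
        drift = cosine_drift(150, 2.0, 128.0)
        assert drift.shape == (150, 4)

    def test_orthonormal(self):
        drift = cosine_drift(150, 2.0).to_numpy()
        gram = drift.T @ drift
        np.testing.assert_allclose(gram, np.eye(drift.shape[1]), atol=1e-10)

    def test_short_run_empty_with_warning(self):
        with pytest.warns(UserWarning, match="cutoff"):
            drift = cosine_drift(50, 2.0, 128.0)
        assert drift.shape[1] == 0
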