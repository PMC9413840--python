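"""Motion quantification, censoring, nuisance design and filtering."""

import numpy as np
import pytest

from mstconnect.preprocess import (
    MotionTrace,
    bandpass,
    build_design_36p,
    build_spike_regressors,
    compute_fd_jenkinson,
    detrend_linear,
    drop_dummy_volumes,
    flag_spikes,
    friston24,
    regress_nuisance,
    retention_decision,
)


def fd_oracle(params, head_radius=80.0):
    """Independent FD route: explicit homogeneous transforms via scipy Rotation."""
    from scipy.spatial.transform import Rotation

    T = params.shape[0]
    mats = []
    for p in params:
        M = np.eye(4)
        # extrinsic x-then-y-then-z == Rz @ Ry @ Rx
        M[:3, :3] = Rotation.from_euler("xyz", [p[3], p[4], p[5]]).as_matrix()
        M[:3, 3] = p[:3]
        mats.append(M)
    fd = np.zeros(T)
    for t in range(1, T):
        D = mats[t] @ np.linalg.solve(mats[t - 1], np.eye(4)) - np.eye(4)
        A, b = D[:3, :3], D[:3, 3]
        fd[t] = np.sqrt(head_radius**2 / 5 * np.sum(A * A) + b @ b)
    return fd


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        assert np.all(compute_fd_jenkinson(np.zeros((5, 6))) == 0)

    def test_pure_translation(self):
        p = np.zeros((3, 6))
        p[1, 0] = 1.0  # +1 mm in x at volume 1, held at volume 2
        fd = compute_fd_jenkinson(p)
        assert fd[1] == pytest.approx(1.0)
        assert fd[2] == pytest.approx(1.0)  # moves back is also 1 mm

    def test_rotation_closed_form(self):
        # rotation about z by 0.01 rad, R = 80 mm:
        # FD = 80 * sqrt(4 (1 - cos 0.01) / 5) ~ 0.5060 mm
        p = np.zeros((2, 6))
        p[1, 5] = 0.01
        expected = 80 * np.sqrt(4 * (1 - np.cos(0.01)) / 5)
        assert compute_fd_jenkinson(p)[1] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.5060, abs=5e-5)

    def test_matches_bruteforce_matrix_oracle(self, rng):
        params = np.column_stack(
            [rng.normal(0, 0.5, 50) for _ in range(3)]
            + [rng.normal(0, 0.02, 50) for _ in range(3)]
        )
        assert np.allclose(
            compute_fd_jenkinson(params), fd_oracle(params), atol=1e-10
        )

    def test_invariant_to_common_translation_offset(self, rng):
        # exact when rotations are unchanged (only frame-to-frame change matters)
        params = np.zeros((20, 6))
        params[:, :3] = rng.normal(0, 0.1, (20, 3))
        shifted = params.copy()
        shifted[:, :3] += np.array([5.0, -3.0, 2.0])
        assert np.allclose(
            compute_fd_jenkinson(params), compute_fd_jenkinson(shifted), atol=1e-10
        )

    def test_sphere_sampling_interpretation(self, rng):
        # FD^2 is the average squared displacement of points filling the
        # 80 mm sphere; check against Monte-Carlo integration
        params = rng.normal(0, 0.05, (2, 6))
        fd = compute_fd_jenkinson(params)[1]
        from tests.test_preprocess import fd_oracle  # noqa: F401

        from scipy.spatial.transform import Rotation

        def tf(p):
            M = np.eye(4)
            M[:3, :3] = Rotation.from_euler("xyz", [p[3], p[4], p[5]]).as_matrix()
            M[:3, 3] = p[:3]
            return M

        D = tf(params[1]) @ np.linalg.inv(tf(params[0])) - np.eye(4)
        pts = rng.normal(size=(200000, 3))
        pts = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 80 * rng.random(200000)[:, None] ** (1 / 3)
        disp = pts @ D[:3, :3].T + D[:3, 3]
        assert np.sqrt(np.mean(np.sum(disp**2, axis=1))) == pytest.approx(fd, rel=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_fd_jenkinson(np.zeros((1, 6)))
        bad = np.zeros((3, 6))
        bad[2, 1] = np.nan
        with pytest.raises(ValueError, match="volume 2"):
            compute_fd_jenkinson(bad)

    def test_motion_trace_computes_fd(self):
        mt = MotionTrace(params=np.zeros((4, 6)))
        assert mt.fd.shape == (4,)
        assert mt.fd[0] == 0


class TestCensoring:
    def test_flag_spikes_strict_inequality(self):
        fd = np.array([0.0, 0.25, 0.1, 0.2])
        assert flag_spikes(fd).tolist() == [False, True, False, False]
        with pytest.raises(ValueError):
            flag_spikes(fd, threshold=-0.1)

    def test_spike_regressors_shape_and_content(self):
        R = build_spike_regressors(np.array([False, True, False]))
        assert R.shape == (3, 1)
        assert R[:, 0].tolist() == [0.0, 1.0, 0.0]
        assert build_spike_regressors(np.zeros(5, dtype=bool)).shape == (5, 0)

    def test_residuals_vanish_at_censored_volumes(self, rng):
        T = 60
        y = rng.normal(size=T)
        flags = np.zeros(T, dtype=bool)
        flags[[7, 23, 41]] = True
        X = np.column_stack([np.ones(T), build_spike_regressors(flags)])
        resid = regress_nuisance(y, X)
        assert np.allclose(resid[flags], 0, atol=1e-10)

    @pytest.mark.parametrize(
        "n_retained, keep",
        [(310, True), (150, True), (149, False)],  # 4 min at TR 1.6 = 150 volumes
    )
    def test_retention_boundary(self, n_retained, keep):
        assert retention_decision(n_retained, 1.6, 4.0) is keep

    def test_drop_dummy_volumes(self):
        x = np.arange(320.0)
        assert drop_dummy_volumes(x, 10).shape == (310,)
        assert drop_dummy_volumes(x, 10)[0] == 10.0


class TestNuisanceDesign:
    def make_inputs(self, rng, T=60):
        motion = rng.normal(0, 0.1, (T, 6))
        tissue = {k: rng.normal(size=T) for k in ("GM", "WM", "CSF")}
        return motion, tissue

    def test_36_base_columns(self, rng):
        motion, tissue = self.make_inputs(rng)
        d = build_design_36p(motion, tissue)
        assert d.n_base_params == 36
        # 36 base + intercept
        assert d.columns.shape[1] == 37

    def test_friston_block_is_24(self, rng):
        motion, _ = self.make_inputs(rng)
        cols, names = friston24(motion)
        assert cols.shape[1] == 24
        assert len(names) == 24

    def test_constant_tissue_has_zero_difference_column(self, rng):
        motion, tissue = self.make_inputs(rng)
        tissue["WM"] = np.full(60, 3.0)
        d = build_design_36p(motion, tissue)
        j = d.column_names.index("WM_diff")
        assert np.all(d.columns[1:, j] == 0)

    def test_trend_and_spikes_extend_design(self, rng):
        motion, tissue = self.make_inputs(rng)
        flags = np.zeros(60, dtype=bool)
        flags[5] = True
        d = build_design_36p(
            motion, tissue, include_trend=True,
            spike_regressors=build_spike_regressors(flags),
        )
        assert d.columns.shape[1] == 36 + 1 + 1 + 1

    def test_length_mismatch_names_series(self, rng):
        motion, tissue = self.make_inputs(rng)
        tissue["CSF"] = tissue["CSF"][:-1]
        with pytest.raises(ValueError, match="CSF"):
            build_design_36p(motion, tissue)


class TestRegression:
    def test_design_column_regresses_to_zero(self, rng):
        motion = rng.normal(0, 0.1, (50, 6))
        tissue = {k: rng.normal(size=50) for k in ("GM", "WM", "CSF")}
        d = build_design_36p(motion, tissue)
        resid = regress_nuisance(d.columns[:, 3], d)
        assert np.allclose(resid, 0, atol=1e-8)

    def test_intercept_only_demeans(self, rng):
        y = rng.normal(5, 1, 40)
        resid = regress_nuisance(y, np.ones((40, 1)))
        assert np.allclose(resid, y - y.mean())

    def test_residual_orthogonality(self, rng):
        motion = rng.normal(0, 0.1, (80, 6))
        tissue = {k: rng.normal(size=80) for k in ("GM", "WM", "CSF")}
        d = build_design_36p(motion, tissue)
        y = rng.normal(size=(5, 80))
        resid = regress_nuisance(y, d)
        dots = np.abs(resid @ d.columns)
        scale = np.linalg.norm(resid, axis=1, keepdims=True) * np.linalg.norm(
            d.columns, axis=0
        )
        assert np.all(dots <= 1e-8 * np.maximum(scale, 1e-30) + 1e-12)

    def test_degenerate_design_raises(self, rng):
        X = rng.normal(size=(10, 12))
        with pytest.raises(ValueError, match="degenerate"):
            regress_nuisance(rng.normal(size=10), X)


class TestDetrendAndFilter:
    def test_detrend_removes_line(self):
        t = np.arange(100.0)
        assert np.allclose(detrend_linear(2 * t + 5), 0, atol=1e-9)

    def test_detrend_idempotent(self, rng):
        y = detrend_linear(rng.normal(size=200))
        assert np.allclose(detrend_linear(y), y, atol=1e-10)

    def test_detrend_preserves_oscillation(self):
        t = np.arange(310)
        y = np.sin(2 * np.pi * 0.05 * t * 1.6)
        out = detrend_linear(y)
        assert np.std(out) == pytest.approx(np.std(y), rel=0.01)

    def test_bandpass_passband_preserved(self):
        t = np.arange(310) * 1.6
        y = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(y, 1.6)
        core = slice(30, -30)  # avoid edge transients
        assert np.std(out[core]) == pytest.approx(np.std(y[core]), rel=0.05)

    def test_bandpass_stopband_attenuated(self):
        t = np.arange(310) * 1.6
        y = np.sin(2 * np.pi * 0.2 * t)
        core = slice(30, -30)  # steady-state response, past filtfilt edge transients
        assert np.std(bandpass(y, 1.6)[core]) <= 0.10 * np.std(y[core])

    def test_bandpass_kills_constant(self):
        assert np.allclose(bandpass(np.full(310, 7.0), 1.6), 0, atol=1e-6)

    def test_bandpass_invalid_band(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), 1.6, 0.01, 0.4)  # above Nyquist = 0.3125
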