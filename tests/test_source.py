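"""Spherical forward model, DICS filters, source power/ITPC, correlations."""

import numpy as np
import pytest
from scipy.special import lpmv

from tempopred import (HeadModel, build_grid, csd, csd_band_average,
                       dics_filters, grid_adjacency, itpc_behavior_correlation,
                       leadfield_at, leadfield_sphere, source_itpc,
                       source_power)
from tempopred.source import SourceGrid, relative_change, vector_filters


@pytest.fixture(scope="module")
def head():
    return HeadModel()


@pytest.fixture(scope="module")
def sensors(head):
    rng = np.random.default_rng(7)
    s = rng.standard_normal((24, 3))
    s /= np.linalg.norm(s, axis=1, keepdims=True)
    return s * head.radius_mm


def _series_oracle(loc, sens, head, nmax=900):
    """Independent evaluation of the sphere series via scipy.special.lpmv."""
    R = head.radius_mm / 1000
    p = np.asarray(loc, float) / 1000
    b = np.linalg.norm(p)
    rhat = sens / np.linalg.norm(sens, axis=1, keepdims=True)
    scale = 1 / (4 * np.pi * head.conductivity * R**2)
    if b < 1e-12:
        L = 3 * scale * rhat
    else:
        bhat = p / b
        f = b / R
        c = np.clip(rhat @ bhat, -1, 1)
        A = np.zeros(len(sens))
        B = np.zeros(len(sens))
        s = np.sqrt(np.maximum(1 - c**2, 1e-300))
        for n in range(1, nmax):
            Pn = lpmv(0, n, c)
            dPn = -lpmv(1, n, c) / s  # Condon-Shortley: P_n^1 = -(1-c^2)^1/2 P_n'
            A += (2 * n + 1) * f ** (n - 1) * (Pn - c * dPn / n)
            B += ((2 * n + 1) / n) * f ** (n - 1) * dPn
        L = scale * (A[:, None] * bhat[None, :] + B[:, None] * rhat)
    return L - L.mean(axis=0)


class TestGrid:
    def test_spacing_equal_radius_gives_center_voxel(self, head):
        g = build_grid(head, spacing_mm=head.radius_mm)
        assert g.n_voxels == 1
        np.testing.assert_allclose(g.positions_mm[0], head.center_mm)

    def test_count_scales_inversely_with_spacing_cubed(self, head):
        n1 = build_grid(head, spacing_mm=6.0).n_voxels
        n2 = build_grid(head, spacing_mm=12.0).n_voxels
        assert n1 / n2 == pytest.approx(8.0, rel=0.25)

    def test_target_5003(self, head):
        g = build_grid(head, target_count=5003)
        assert 4903 <= g.n_voxels <= 5103  # within 2%

    def test_all_voxels_inside_brain_sphere(self, head):
        g = build_grid(head, spacing_mm=10.0)
        r = np.linalg.norm(g.positions_mm - head.center_mm, axis=1)
        assert r.max() < head.radius_mm * head.brain_fraction

    def test_adjacency_26_connectivity(self, head):
        g = build_grid(head, spacing_mm=20.0)
        A = grid_adjacency(g)
        assert np.array_equal(A, A.T) and not A.diagonal().any()
        # center voxel of a dense-enough grid has 26 neighbors
        center = np.argmin(np.linalg.norm(g.positions_mm - head.center_mm,
                                          axis=1))
        assert A[center].sum() <= 26


class TestLeadfield:
    def test_matches_independent_series(self, head, sensors):
        rng = np.random.default_rng(1)
        r_max = head.radius_mm * head.brain_fraction
        for _ in range(10):
            loc = rng.uniform(-1, 1, 3)
            loc = loc / np.linalg.norm(loc) * rng.uniform(0, r_max * 0.95)
            L1 = leadfield_at(loc, sensors, head)
            L2 = _series_oracle(loc, sensors, head)
            assert np.abs(L1 - L2).max() / np.abs(L2).max() < 1e-10

    def test_central_dipole_closed_form(self, head, sensors):
        L = leadfield_at(np.zeros(3), sensors, head)
        R = head.radius_mm / 1000
        rhat = sensors / np.linalg.norm(sensors, axis=1, keepdims=True)
        expect = 3 * rhat / (4 * np.pi * head.conductivity * R**2)
        expect -= expect.mean(axis=0)
        np.testing.assert_allclose(L, expect, atol=1e-10)

    def test_radial_dipole_peaks_at_nearest_electrode(self, head, sensors):
        loc = np.array([0.0, 0.0, 55.0])
        L = leadfield_at(loc, sensors, head, average_reference=False)
        v = L @ np.array([0.0, 0.0, 1.0])  # radial orientation
        nearest = np.argmin(np.linalg.norm(sensors - loc, axis=1))
        assert v.argmax() == nearest

    def test_depth_attenuation(self, head, layout64):
        """A central dipole is weaker at the scalp montage than a superficial one."""
        sens = layout64.positions * head.radius_mm
        deep = leadfield_at(np.array([0.0, 0, 10.0]), sens, head)
        shallow = leadfield_at(np.array([0.0, 0, 65.0]), sens, head)
        assert np.linalg.norm(deep) < np.linalg.norm(shallow)

    def test_average_reference(self, head, sensors):
        L = leadfield_at(np.array([20.0, -10, 30]), sensors, head)
        np.testing.assert_allclose(L.mean(axis=0), 0.0,
                                   atol=1e-10 * np.abs(L).max())

    def test_outside_sphere_rejected(self, head, sensors):
        with pytest.raises(ValueError):
            leadfield_at(np.array([0.0, 0, 90.0]), sensors, head)


class TestCSD:
    def test_hermitian(self, rng):
        x = rng.standard_normal((5, 4, 3, 40)) + 1j * rng.standard_normal(
            (5, 4, 3, 40))
        C, centers = csd(x, np.arange(40) * 10.0 - 200.0)
        for f in range(3):
            for b in range(C.shape[1]):
                np.testing.assert_allclose(C[f, b], C[f, b].conj().T,
                                           atol=1e-12)
                assert np.all(np.diag(C[f, b]).real >= 0)

    def test_single_channel_is_mean_power(self, rng):
        x = rng.standard_normal((6, 1, 1, 20)) + 1j * rng.standard_normal(
            (6, 1, 1, 20))
        C, _ = csd(x, np.arange(20) * 10.0)
        expect = (np.abs(x[:, 0, 0, :10]) ** 2).mean()
        assert C[0, 0, 0, 0].real == pytest.approx(expect, rel=1e-12)

    def test_duplicated_channel_perfect_coherence(self, rng):
        x1 = rng.standard_normal((4, 1, 1, 20)) + 1j * rng.standard_normal(
            (4, 1, 1, 20))
        x = np.concatenate([x1, x1], axis=1)
        C, _ = csd(x, np.arange(20) * 10.0)
        M = C[0, 0]
        assert abs(M[0, 1]) == pytest.approx(M[0, 0].real, rel=1e-12)


class TestDICS:
    def _world(self, head, n_ch=24, spacing=24.0, seed=0):
        rng = np.random.default_rng(seed)
        sens = rng.standard_normal((n_ch, 3))
        sens /= np.linalg.norm(sens, axis=1, keepdims=True)
        sens *= head.radius_mm

        class _Lay:
            positions = sens / head.radius_mm
        grid = build_grid(head, spacing_mm=spacing)
        lf = leadfield_sphere(grid, _Lay, head)
        return sens, grid, lf, rng

    def test_unit_gain_identity(self, head):
        """W L = I3 at lambda = 0 with a full-rank CSD."""
        sens, grid, lf, rng = self._world(head)
        A = rng.standard_normal((24, 24))
        C = A @ A.T + 24 * np.eye(24)
        W = vector_filters(C, lf, lambda_frac=0.0)
        for v in range(0, grid.n_voxels, max(1, grid.n_voxels // 5)):
            np.testing.assert_allclose(W[v] @ lf.matrix[v], np.eye(3),
                                       atol=1e-6)

    def test_point_source_localization(self, head):
        """A single dipole in noise localizes within one grid spacing."""
        sens, grid, lf, rng = self._world(head, spacing=18.0)
        true_v = grid.n_voxels // 3
        g = lf.matrix[true_v] @ np.array([0.0, 1.0, 0.0])
        n_trials, n_t = 40, 30
        amp = rng.standard_normal((n_trials, n_t)) * 3.0
        noise = rng.standard_normal((n_trials, 24, n_t))
        x = (g[None, :, None] * amp[:, None, :] + noise).astype(complex)
        x = x[:, :, None, :]  # single frequency
        C, centers = csd(x, np.arange(n_t) * 10.0)
        Cavg = C.mean(axis=(0, 1))
        filt = dics_filters(Cavg, lf, lambda_frac=0.05)
        P = source_power(filt, Cavg)
        err = np.linalg.norm(grid.positions_mm[P.argmax()]
                             - grid.positions_mm[true_v])
        assert err <= grid.spacing_mm + 1e-9

    def test_power_linearity(self, head):
        sens, grid, lf, rng = self._world(head)
        A = rng.standard_normal((24, 24))
        C = A @ A.T + np.eye(24)
        filt = dics_filters(C, lf)
        P1 = source_power(filt, C)
        P2 = source_power(filt, 2 * C)
        np.testing.assert_allclose(P2, 2 * P1, rtol=1e-10)

    def test_min_variance_equivalence(self, head):
        """At lambda -> 0, w C w^T equals 1/(l^T C^-1 l) on the fitted orientation."""
        sens, grid, lf, rng = self._world(head, spacing=30.0)
        A = rng.standard_normal((24, 24))
        C = A @ A.T + 24 * np.eye(24)
        filt = dics_filters(C, lf, lambda_frac=0.0)
        P = source_power(filt, C)
        for v in range(grid.n_voxels):
            l = lf.matrix[v] @ filt.orientations[v]
            mv = 1.0 / (l @ np.linalg.solve(C, l))
            assert P[v] == pytest.approx(mv, rel=1e-8)

    def test_common_filter_condition_ratio(self, head):
        """Condition power difference at the source tracks the injected ratio."""
        sens, grid, lf, rng = self._world(head, spacing=20.0)
        true_v = grid.n_voxels // 2
        g = lf.matrix[true_v] @ np.array([0.0, 1.0, 0.0])

        def make_csd(source_var):
            n_trials, n_t = 60, 20
            amp = rng.standard_normal((n_trials, n_t)) * np.sqrt(source_var)
            noise = rng.standard_normal((n_trials, 24, n_t)) * 0.2
            x = (g[None, :, None] * amp[:, None, :] + noise).astype(complex)
            C, _ = csd(x[:, :, None, :], np.arange(n_t) * 10.0)
            return C.mean(axis=(0, 1))

        C1, C2 = make_csd(4.0), make_csd(8.0)
        filt = dics_filters(0.5 * (C1 + C2), lf)
        P1 = source_power(filt, C1)[true_v]
        P2 = source_power(filt, C2)[true_v]
        assert P2 / P1 == pytest.approx(2.0, rel=0.1)

    def test_zscore_normalization(self, head):
        sens, grid, lf, rng = self._world(head)
        A = rng.standard_normal((24, 24))
        C = A @ A.T + np.eye(24)
        filt = dics_filters(C, lf)
        Pz = source_power(filt, C, normalize="zscore")
        assert Pz.mean() == pytest.approx(0.0, abs=1e-12)
        assert Pz.std() == pytest.approx(1.0, abs=1e-12)

    def test_relative_change_guard(self):
        with pytest.raises(ValueError):
            relative_change(np.ones(3), np.zeros(3))


class TestSourceITPC:
    def _filters(self, head, seed=0):
        rng = np.random.default_rng(seed)
        sens = rng.standard_normal((16, 3))
        sens /= np.linalg.norm(sens, axis=1, keepdims=True)
        sens *= head.radius_mm

        class _Lay:
            positions = sens / head.radius_mm
        grid = build_grid(head, spacing_mm=30.0)
        lf = leadfield_sphere(grid, _Lay, head)
        A = rng.standard_normal((16, 16))
        C = A @ A.T + 16 * np.eye(16)
        return dics_filters(C, lf, 0.05), grid, lf, rng

    def test_identical_trials_itpc_one(self, head):
        filt, grid, lf, rng = self._filters(head)
        one = rng.standard_normal((1, 16, 2, 10)) + 1j * rng.standard_normal(
            (1, 16, 2, 10))
        x = np.repeat(one, 12, axis=0)
        R = source_itpc(filt, x, np.arange(10) * 50.0, np.array([1.0, 3.0]),
                        (0.5, 4.0), (0.0, 500.0))
        np.testing.assert_allclose(R, 1.0, atol=1e-12)

    def test_random_phases_near_rayleigh_expectation(self, head):
        filt, grid, lf, rng = self._filters(head)
        n_tr = 470
        phases = rng.uniform(-np.pi, np.pi, (n_tr, 1, 2, 8))
        x = np.exp(1j * phases) * np.ones((n_tr, 16, 2, 8))
        R = source_itpc(filt, x, np.arange(8) * 50.0, np.array([1.0, 3.0]),
                        (0.5, 4.0), (0.0, 400.0))
        expect = np.sqrt(np.pi) / (2 * np.sqrt(n_tr))
        assert abs(R.mean() - expect) < 3 * expect  # loose Monte-Carlo band

    def test_delta_generator_localizes(self, head):
        """Phase-locked dipole: source-ITPC peak within one grid spacing."""
        filt0, grid, lf, rng = self._filters(head, seed=3)
        true_v = int(np.argmin(np.linalg.norm(
            grid.positions_mm - np.array([-40.0, 0, 25.0]), axis=1)))
        g = lf.matrix[true_v] @ np.array([0.0, 1.0, 0.0])
        n_tr, n_t = 60, 12
        theta = rng.vonmises(0.0, 5.0, n_tr)
        carrier = np.exp(1j * (theta[:, None] +
                               2 * np.pi * 2.0 * np.arange(n_t) * 0.05))
        x = g[None, :, None, None] * carrier[:, None, None, :] * 3.0
        x = x + 0.5 * (rng.standard_normal((n_tr, 16, 1, n_t))
                       + 1j * rng.standard_normal((n_tr, 16, 1, n_t)))
        times = np.arange(n_t) * 50.0
        C, centers = csd(x, times)
        Cavg = csd_band_average(C, np.array([2.0]), centers, (0.5, 4.0),
                                (times[0], times[-1]))
        filt = dics_filters(Cavg, lf, 0.05)
        R = source_itpc(filt, x, times, np.array([2.0]), (0.5, 4.0),
                        (times[0], times[-1]))
        err = np.linalg.norm(grid.positions_mm[R.argmax()]
                             - grid.positions_mm[true_v])
        assert err <= grid.spacing_mm + 1e-9


class TestCorrelation:
    def test_constant_steepness_flagged(self, rng):
        maps = rng.uniform(0, 1, (6, 10))
        r, valid = itpc_behavior_correlation(maps, np.full(6, 0.004))
        assert not valid.any()
        assert np.isnan(r).all()

    def test_sign_flip_negates_r(self, rng):
        maps = rng.uniform(0, 1, (8, 12))
        s = rng.normal(0.003, 0.001, 8)
        r1, _ = itpc_behavior_correlation(maps, s)
        r2, _ = itpc_behavior_correlation(maps, -s)
        np.testing.assert_allclose(r1, -r2, atol=1e-12)

    def test_matches_scipy_pearson(self, rng):
        from scipy.stats import pearsonr
        maps = rng.uniform(0, 1, (9, 5))
        s = rng.normal(size=9)
        r, valid = itpc_behavior_correlation(maps, s)
        for v in range(5):
            assert r[v] == pytest.approx(pearsonr(maps[:, v], s).statistic,
                                         abs=1e-12)

    def test_rotation_invariance_of_source_power(self, rng):
        """Rotating sensors and leadfields together leaves source power unchanged."""
        head = HeadModel()
        sens = rng.standard_normal((16, 3))
        sens /= np.linalg.norm(sens, axis=1, keepdims=True)
        sens *= head.radius_mm
        grid = build_grid(head, spacing_mm=35.0)

        class _Lay:
            positions = sens / head.radius_mm
        lf = leadfield_sphere(grid, _Lay, head)
        A = rng.standard_normal((16, 16))
        C = A @ A.T + 16 * np.eye(16)
        P = source_power(dics_filters(C, lf), C)
        # rotating the *sensor space* (permutation = orthogonal on channels)
        perm = rng.permutation(16)
        lf2 = type(lf)(lf.matrix[:, perm, :], grid)
        C2 = C[np.ix_(perm, perm)]
        P2 = source_power(dics_filters(C2, lf2), C2)
        np.testing.assert_allclose(P, P2, rtol=1e-8)
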