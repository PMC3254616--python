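"""Tests of propagator estimation, system conversion and POP extraction."""

import numpy as np
import pytest
import scipy.linalg

from popgex import (
    ExpressionMatrix,
    PopPair,
    amplitude_phase,
    compute_eigensystem,
    estimate_propagator,
    extract_pops,
    propagator_to_system,
)
from popgex.dynamics import Propagator, SystemMatrix
from popgex.eigensystem import EigenSystem

from conftest import planted_linear_system


def rotation(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def eigensystem_from_snapshots(v, tau=7.0, loadings=None, gene_ids=None):
    """Wrap raw snapshot trajectories as an EigenSystem for dynamics tests."""
    r, m = v.shape
    w = np.eye(r) if loadings is None else np.asarray(loadings, float)
    ids = gene_ids or [f"g{i}" for i in range(w.shape[0])]
    return EigenSystem(
        singular_values=np.ones(r),
        eigengenes=np.asarray(v, float),
        loadings=w,
        rank=r,
        covariance_captured=1.0,
        times=np.arange(m) * tau,
        gene_ids=ids,
    )


class TestEstimatePropagator:
    def test_constant_eigengene_gives_identity(self):
        es = eigensystem_from_snapshots(np.ones((1, 10)))
        prop = estimate_propagator(es)
        assert prop.phi == pytest.approx(np.array([[1.0]]))
        assert prop.fit_residual < 1e-12

    def test_planar_rotation_recovered_exactly(self):
        r = rotation(np.pi / 6)
        v0 = np.array([1.0, 0.3])
        v = np.column_stack([np.linalg.matrix_power(r, k) @ v0 for k in range(12)])
        prop = estimate_propagator(eigensystem_from_snapshots(v))
        assert np.max(np.abs(prop.phi - r)) < 1e-10

    def test_too_few_snapshots_rejected(self):
        es = eigensystem_from_snapshots(np.ones((3, 3)))
        with pytest.raises(ValueError, match="time points"):
            estimate_propagator(es)

    def test_rank_deficient_snapshots_warn(self):
        v = np.vstack([np.ones(8), np.ones(8)])  # two identical rows
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            estimate_propagator(eigensystem_from_snapshots(v))


class TestPropagatorToSystem:
    @pytest.mark.parametrize("method", ["matrix-log", "euler"])
    def test_identity_propagator_gives_zero(self, method):
        prop = Propagator(phi=np.eye(3), tau=7.0, fit_residual=0.0)
        b = propagator_to_system(prop, method=method)
        assert np.allclose(b.matrix, 0.0, atol=1e-12)

    def test_rotation_log_gives_skew_matrix(self):
        tau = 7.0
        prop = Propagator(phi=rotation(np.pi / 6), tau=tau, fit_residual=0.0)
        b = propagator_to_system(prop, method="matrix-log")
        omega = (np.pi / 6) / tau
        assert np.allclose(b.matrix, [[0, -omega], [omega, 0]], atol=1e-12)
        ev = np.linalg.eigvals(b.matrix)
        assert sorted(ev.imag) == pytest.approx([-omega, omega], abs=1e-12)

    def test_log_eigenvalues_match_scalar_logs(self):
        rng = np.random.default_rng(0)
        phi = np.eye(3) * 0.9 + 0.05 * rng.normal(size=(3, 3))
        prop = Propagator(phi=phi, tau=7.0, fit_residual=0.0)
        b = propagator_to_system(prop)
        got = np.sort_complex(np.linalg.eigvals(b.matrix))
        want = np.sort_complex(np.log(np.linalg.eigvals(phi).astype(complex)) / 7.0)
        assert np.allclose(got, want, atol=1e-10)

    def test_negative_real_eigenvalue_suggests_euler(self):
        prop = Propagator(phi=np.diag([0.5, -0.2]), tau=7.0, fit_residual=0.0)
        with pytest.raises(ValueError, match="euler"):
            propagator_to_system(prop, method="matrix-log")
        b = propagator_to_system(prop, method="euler")
        assert np.allclose(b.matrix, (prop.phi - np.eye(2)) / 7.0)

    def test_unknown_method_rejected(self):
        prop = Propagator(phi=np.eye(2), tau=7.0, fit_residual=0.0)
        with pytest.raises(ValueError, match="unknown"):
            propagator_to_system(prop, method="exact")


class TestExtractPops:
    def test_all_real_spectrum_yields_only_decay_modes(self):
        b = SystemMatrix(matrix=np.diag([-1.0, -2.0]), tau=7.0, method="matrix-log")
        es = eigensystem_from_snapshots(np.random.default_rng(0).normal(size=(2, 6)))
        dec = extract_pops(b, es)
        assert dec.pairs == []
        assert len(dec.decay_modes) == 2
        # slow decay first
        assert dec.decay_modes[0].eigenvalue == pytest.approx(-1.0)
        assert dec.decay_modes[1].eigenvalue == pytest.approx(-2.0)

    def test_pure_rotation_block_gives_one_pair(self):
        omega = 2 * np.pi / 30
        b = SystemMatrix(
            matrix=np.array([[0.0, -omega], [omega, 0.0]]), tau=7.0, method="matrix-log"
        )
        v = np.column_stack(
            [scipy.linalg.expm(b.matrix * t) @ np.array([1.0, 0.0]) for t in np.arange(8) * 7.0]
        )
        dec = extract_pops(b, eigensystem_from_snapshots(v))
        assert len(dec.pairs) == 1
        pair = dec.pairs[0]
        assert pair.period == pytest.approx(30.0, abs=1e-9)
        # analytic eigenvectors (1, -i)/sqrt(2): p1 and p2 orthogonal, equal norm
        assert abs(pair.p1 @ pair.p2) < 1e-10
        assert np.linalg.norm(pair.p1) == pytest.approx(np.linalg.norm(pair.p2), abs=1e-10)

    def test_conjugate_closure_of_reported_eigenvalues(self, sim_small):
        _, x, _ = sim_small
        es = compute_eigensystem(x, rank=5)
        b = propagator_to_system(estimate_propagator(es))
        dec = extract_pops(b, es)
        ev = dec.ordered_eigenvalues
        assert len(ev) == 5
        for p in dec.pairs:
            assert p.omega > 0
            assert any(abs(e - p.eigenvalue.conjugate()) < 1e-12 for e in ev)

    def test_gene_pops_are_loadings_times_patterns(self, sim_small):
        _, x, _ = sim_small
        es = compute_eigensystem(x, rank=5)
        b = propagator_to_system(estimate_propagator(es))
        pair = extract_pops(b, es).leading
        assert np.array_equal(pair.gene_p1, es.loadings @ pair.p1)
        assert np.array_equal(pair.gene_p2, es.loadings @ pair.p2)

    def test_short_period_flagged_aliased(self):
        omega = 2 * np.pi / 10  # 10-min period at 7-min sampling: unresolvable
        b = SystemMatrix(
            matrix=np.array([[0.0, -omega], [omega, 0.0]]), tau=7.0, method="matrix-log"
        )
        v = np.random.default_rng(1).normal(size=(2, 6))
        with pytest.warns(RuntimeWarning, match="Nyquist"):
            dec = extract_pops(b, eigensystem_from_snapshots(v))
        assert dec.pairs[0].aliased


class TestPlantedSystemOracle:
    """Noiseless X = W exp(B tau k) v0: estimation must be exact."""

    def test_propagator_matches_matrix_exponential(self):
        x, times, w, b, v0 = planted_linear_system(seed=3)
        es = compute_eigensystem(
            ExpressionMatrix([f"g{i}" for i in range(x.shape[0])], times, x), rank=4
        )
        prop = estimate_propagator(es)
        # compare in the original state space via the loading map
        phi_true = scipy.linalg.expm(b * 7.0)
        # eigengene snapshots are a basis change s of the planted state:
        # E = s V  with  s = pinv(loadings) @ w, so phi_true = s^-1 phi s
        s = np.linalg.lstsq(es.loadings, w, rcond=None)[0]
        phi_mapped = np.linalg.inv(s) @ prop.phi @ s
        assert np.linalg.norm(phi_mapped - phi_true) < 1e-8

    def test_period_recovered_to_relative_1e6(self):
        omega = 2 * np.pi / 30
        x, times, w, b, v0 = planted_linear_system(omega=omega, seed=4)
        es = compute_eigensystem(
            ExpressionMatrix([f"g{i}" for i in range(x.shape[0])], times, x), rank=4
        )
        dec = extract_pops(propagator_to_system(estimate_propagator(es)), es)
        assert len(dec.pairs) == 1
        assert abs(dec.pairs[0].period - 30.0) / 30.0 < 1e-6

    def test_all_real_planted_spectrum_gives_no_pairs(self):
        rng = np.random.default_rng(5)
        b = np.diag([-0.01, -0.05, -0.1])
        w = rng.normal(size=(40, 3))
        times = np.arange(10) * 7.0
        v = np.column_stack([scipy.linalg.expm(b * t) @ np.ones(3) for t in times])
        x = ExpressionMatrix([f"g{i}" for i in range(40)], times, w @ v)
        es = compute_eigensystem(x, rank=3)
        dec = extract_pops(propagator_to_system(estimate_propagator(es)), es)
        assert dec.pairs == []
        assert len(dec.decay_modes) == 3


def make_pair(p1, p2, loadings, period=30.0):
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    w = np.asarray(loadings, float)
    return PopPair(
        eigenvalue=complex(0.0, 2 * np.pi / period),
        period=period,
        p1=p1,
        p2=p2,
        gene_p1=w @ p1,
        gene_p2=w @ p2,
        energy=1.0,
        gene_ids=[f"g{i}" for i in range(w.shape[0])],
        loadings=w,
    )


class TestAmplitudePhase:
    def test_axis_cases_of_polar_convention(self):
        w = np.array([[1.0, 0.0], [0.0, 1.0]])
        table = amplitude_phase(make_pair([1.0, 0.0], [0.0, 1.0], w))
        # gene 0: (c1, c2) = (1, 0) -> amplitude 1, phase 0
        # gene 1: (c1, c2) = (0, 1) -> amplitude 1, phase 90
        assert np.allclose(table.amplitude, [1.0, 1.0])
        assert np.allclose(table.phase_deg, [0.0, 90.0])

    def test_zero_coefficients_flag_undefined_phase(self):
        w = np.array([[0.0, 0.0], [1.0, 1.0]])
        table = amplitude_phase(make_pair([1.0, 0.0], [0.0, 1.0], w))
        assert table.amplitude[0] == 0.0
        assert not table.phase_defined[0]
        assert table.phase_deg[0] == 0.0
        assert table.phase_defined[1]

    def test_polar_cartesian_round_trip(self, sim_small):
        _, x, _ = sim_small
        es = compute_eigensystem(x, rank=5)
        pair = extract_pops(propagator_to_system(estimate_propagator(es)), es).leading
        t = amplitude_phase(pair)
        theta = np.radians(t.phase_deg)
        assert np.allclose(t.amplitude * np.cos(theta), t.c1, atol=1e-9)
        assert np.allclose(t.amplitude * np.sin(theta), t.c2, atol=1e-9)

    def test_identity_loadings_reproduce_eigen_pops(self):
        p1, p2 = np.array([0.3, -0.2, 0.5]), np.array([0.1, 0.4, -0.3])
        table = amplitude_phase(make_pair(p1, p2, np.eye(3)))
        assert np.allclose(table.c1, p1)
        assert np.allclose(table.c2, p2)

    def test_gauge_rotation_preserves_amplitudes_shifts_phases(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=(50, 4))
        e = rng.normal(size=4) + 1j * rng.normal(size=4)
        for alpha in (0.4, 1.9, 3.5):
            base = make_pair(np.real(e), -np.imag(e), w)
            rot = e * np.exp(1j * alpha)
            rotated = make_pair(np.real(rot), -np.imag(rot), w)
            t0, t1 = amplitude_phase(base), amplitude_phase(rotated)
            assert np.allclose(t1.amplitude, t0.amplitude, atol=1e-10)
            shift = (t1.phase_deg - t0.phase_deg) % 360.0
            assert np.allclose(shift, shift[0], atol=1e-8)

    def test_projection_method_matches_direct_for_orthonormal_patterns(self):
        rng = np.random.default_rng(7)
        w = rng.normal(size=(20, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 2)))
        direct = amplitude_phase(make_pair(q[:, 0], q[:, 1], w), method="direct")
        proj = amplitude_phase(make_pair(q[:, 0], q[:, 1], w), method="projection")
        assert np.allclose(direct.amplitude, proj.amplitude, atol=1e-10)
        assert np.allclose(direct.phase_deg, proj.phase_deg, atol=1e-8)
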