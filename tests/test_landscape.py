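"""Exact energy landscape on the unit hypersphere: gradients, Hessians,
stationary-point classification, spectrum recovery, stereographic maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from statescape.errors import ContractError, DomainError
from statescape.fixtures import SpectrumSpec, random_hamiltonian, random_state
from statescape.landscape import (
    StatePoint,
    energy,
    enumerate_exact_stationary_points,
    global_gradient,
    local_curvature,
    local_gradient,
    local_hessian,
    spectrum_from_stationary_point,
    stereographic_inverse,
    stereographic_project,
    tangent_frame,
)
from statescape.extremals import variance


def _rand_sym(n, rng):
    A = rng.standard_normal((n, n))
    return (A + A.T) / 2.0


class TestEnergyAndGradient:
    def test_identity_hamiltonian(self, rng):
        c = random_state(5, rng)
        assert energy(c, np.eye(5)) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(global_gradient(c, np.eye(5)), 2 * c.coeffs)

    def test_diagonal_hamiltonian_on_axis(self):
        H = np.diag([0.3, -1.2, 2.5])
        c = StatePoint(np.array([0.0, 1.0, 0.0]))
        assert energy(c, H) == pytest.approx(-1.2)

    def test_csf_matrix_element(self, h2):
        ham = h2[2.0]
        c = StatePoint(np.array([1.0, 0.0, 0.0]))
        assert energy(c, ham.matrix) == pytest.approx(ham.matrix[0, 0], abs=1e-14)

    def test_gradient_matches_ambient_finite_differences(self, rng):
        H = _rand_sym(6, rng)
        c = random_state(6, rng).coeffs
        g = global_gradient(c, H)
        h = 1e-6
        for i in range(6):
            e = np.zeros(6); e[i] = h
            fd = ((c + e) @ H @ (c + e) - (c - e) @ H @ (c - e)) / (2 * h)
            assert g[i] == pytest.approx(fd, abs=1e-6)

    def test_radial_directional_derivative_is_twice_energy(self, rng):
        """Moving radially off the sphere changes E at rate 2E(c)."""
        H = _rand_sym(5, rng)
        c = random_state(5, rng).coeffs
        h = 1e-7
        fd = ((1 + h) ** 2 - (1 - h) ** 2) * (c @ H @ c) / (2 * h)
        assert float(global_gradient(c, H) @ c) == pytest.approx(fd, rel=1e-6)
        assert float(global_gradient(c, H) @ c) == pytest.approx(
            2 * energy(c, H), abs=1e-12)

    def test_contract_violations(self):
        with pytest.raises(ContractError):
            energy(np.array([1.0, 1.0]), np.eye(2))
        with pytest.raises(ContractError):
            energy(np.array([1.0, 0.0]), np.eye(3))
        with pytest.raises(DomainError):
            energy(np.array([1.0, 0.0]), np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestTangentFrame:
    @given(st.integers(2, 9), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_frame_invariants(self, n, seed):
        c = random_state(n, np.random.default_rng(seed))
        B = tangent_frame(c).basis
        assert B.shape == (n, n - 1)
        assert np.allclose(B.T @ B, np.eye(n - 1), atol=1e-12)
        assert np.allclose(B.T @ c.coeffs, 0.0, atol=1e-12)
        completeness = np.outer(c.coeffs, c.coeffs) + B @ B.T
        assert np.allclose(completeness, np.eye(n), atol=1e-12)

    def test_axis_point_spans_remaining_axes(self):
        B = tangent_frame(StatePoint(np.array([1.0, 0.0, 0.0]))).basis
        span = B @ B.T
        assert np.allclose(span, np.diag([0.0, 1.0, 1.0]), atol=1e-12)

    def test_deterministic(self, rng):
        c = random_state(7, rng)
        assert np.array_equal(tangent_frame(c).basis, tangent_frame(c).basis)

    def test_zero_vector_rejected(self):
        with pytest.raises(DomainError):
            tangent_frame(np.zeros(4))


class TestLocalDerivatives:
    def test_gradient_vanishes_at_eigenvectors(self, rng):
        H = _rand_sym(5, rng)
        _, V = np.linalg.eigh(H)
        for k in range(5):
            assert np.linalg.norm(local_gradient(V[:, k], H)) < 1e-10

    def test_gradient_norm_squared_is_four_variances(self, rng):
        for _ in range(20):
            H = _rand_sym(6, rng)
            c = random_state(6, rng)
            g2 = float(np.sum(local_gradient(c, H) ** 2))
            assert g2 == pytest.approx(4 * variance(c, H), abs=1e-10)

    def test_gradient_matches_great_circle_finite_differences(self, rng):
        H = _rand_sym(6, rng)
        c = random_state(6, rng).coeffs
        frame = tangent_frame(c)
        g = local_gradient(c, H, frame)
        h = 1e-6
        for a in range(5):
            b = frame.basis[:, a]
            ep = np.cos(h) * c + np.sin(h) * b
            em = np.cos(h) * c - np.sin(h) * b
            fd = (ep @ H @ ep - em @ H @ em) / (2 * h)
            assert g[a] == pytest.approx(fd, abs=1e-6)

    def test_hessian_spectrum_at_eigenstates(self, rng):
        H = _rand_sym(6, rng)
        evals, V = np.linalg.eigh(H)
        for k in range(6):
            Q = local_hessian(V[:, k], H)
            expected = np.sort(2 * (np.delete(evals, k) - evals[k]))
            assert np.allclose(np.sort(np.linalg.eigvalsh(Q)), expected, atol=1e-10)

    def test_hessian_matches_second_differences_on_sphere(self, rng):
        H = _rand_sym(5, rng)
        c = random_state(5, rng).coeffs
        frame = tangent_frame(c)
        Q = local_hessian(c, H, frame)
        h = 1e-4
        for a in range(4):
            b = frame.basis[:, a]
            def e_of(s):
                v = np.cos(s) * c + np.sin(s) * b
                return v @ H @ v
            fd = (e_of(h) - 2 * e_of(0.0) + e_of(-h)) / h ** 2
            assert Q[a, a] == pytest.approx(fd, abs=1e-4)

    def test_mismatched_frame_rejected(self, rng):
        c1, c2 = random_state(4, rng), random_state(4, rng)
        frame = tangent_frame(c1)
        with pytest.raises(ContractError):
            local_gradient(c2, np.eye(4), frame)

    def test_local_curvature_bundle(self, h2):
        lc = local_curvature(np.array([0.0, 1.0, 0.0]), h2[2.0].matrix)
        assert lc.local_hessian.shape == (2, 2)
        assert np.allclose(lc.local_hessian, lc.local_hessian.T, atol=1e-10)


class TestStationaryPoints:
    def test_h2_landscape_topology(self, h2):
        pts = enumerate_exact_stationary_points(h2[2.0].matrix)
        assert len(pts) == 6
        assert [sp.hessian_index for sp in pts] == [0, 0, 1, 1, 2, 2]
        assert [sp.label for sp in pts[:2]] == ["minimum", "minimum"]
        assert all(sp.label == "maximum" for sp in pts[4:])

    def test_sign_pairs(self, h2):
        pts = enumerate_exact_stationary_points(h2[2.0].matrix)
        for sp in pts:
            partner = sp.sign_partner
            assert np.allclose(partner.point.coeffs, -sp.point.coeffs)
            assert partner.energy == sp.energy
            assert partner.hessian_index == sp.hessian_index
            assert np.allclose(partner.hessian_eigenvalues, sp.hessian_eigenvalues)

    def test_fully_degenerate_continuum(self):
        pts = enumerate_exact_stationary_points(np.eye(4))
        assert all(sp.degenerate for sp in pts)

    def test_index_equals_excitation_level_random_spectra(self):
        for trial in range(100):
            n = 3 + trial % 6  # N in 3..8
            rng = np.random.default_rng(1000 + trial)
            spec = SpectrumSpec(n, tuple(np.sort(rng.uniform(-2, 2, n))),
                                seed=2000 + trial)
            H = random_hamiltonian(spec)
            pts = enumerate_exact_stationary_points(H)
            expected = sorted([k for k in range(n)] * 2)
            assert [sp.hessian_index for sp in pts] == expected

    def test_great_circle_zeros_are_enumerated_points(self):
        """Every vanishing of the local gradient on random great circles
        coincides with an enumerated +/- eigenvector."""
        from scipy.optimize import minimize_scalar
        rng = np.random.default_rng(42)
        H = _rand_sym(3, rng)
        pts = enumerate_exact_stationary_points(H)
        all_states = np.array([sp.point.coeffs for sp in pts])
        for _ in range(10):
            u = random_state(3, rng).coeffs
            w = random_state(3, rng).coeffs
            w = w - (w @ u) * u
            w /= np.linalg.norm(w)

            def gnorm(t):
                c = np.cos(t) * u + np.sin(t) * w
                return np.linalg.norm(local_gradient(c, H))

            ts = np.linspace(0, 2 * np.pi, 800)
            vals = np.array([gnorm(t) for t in ts])
            for i in range(len(ts)):
                if vals[i] <= vals[i - 1] and vals[i] <= vals[(i + 1) % len(ts)]:
                    res = minimize_scalar(gnorm, bracket=None,
                                          bounds=(ts[i] - 0.01, ts[i] + 0.01),
                                          method="bounded",
                                          options={"xatol": 1e-12})
                    if res.fun < 1e-8:  # a genuine zero of the gradient
                        c = np.cos(res.x) * u + np.sin(res.x) * w
                        dist = np.min(np.linalg.norm(all_states - c, axis=1))
                        assert dist < 1e-6

    def test_non_symmetric_rejected(self):
        with pytest.raises(DomainError):
            enumerate_exact_stationary_points(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestSpectrumRecovery:
    def test_round_trip_from_any_stationary_point(self, h2):
        H = h2[2.0].matrix
        direct = np.linalg.eigvalsh(H)
        for sp in enumerate_exact_stationary_points(H):
            recovered = spectrum_from_stationary_point(sp, H)
            assert np.allclose(recovered, direct, atol=1e-10)

    def test_two_level_example(self):
        H = np.array([[0.0, 0.0], [0.0, 1.0]])
        sp = enumerate_exact_stationary_points(H)[0]
        assert np.allclose(spectrum_from_stationary_point(sp), [0.0, 1.0])

    def test_non_stationary_input_rejected(self, h2, rng):
        H = h2[2.0].matrix
        sp = enumerate_exact_stationary_points(H)[0]
        fake = type(sp)(point=random_state(3, rng), energy=sp.energy,
                        hessian_index=0, hessian_eigenvalues=sp.hessian_eigenvalues,
                        label="minimum")
        with pytest.raises(ContractError):
            spectrum_from_stationary_point(fake, H)


class TestStereographic:
    def test_center_and_equator(self):
        assert stereographic_project(np.array([0.0, 1.0, 0.0])) == (0.0, 0.0)
        assert stereographic_project(np.array([1.0, 0.0, 0.0])) == (1.0, 0.0)

    def test_pole_maps_to_infinity(self):
        X, Y = stereographic_project(np.array([0.0, -1.0, 0.0]))
        assert np.isinf(X) and np.isinf(Y)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_round_trip(self, seed):
        c = random_state(3, np.random.default_rng(seed))
        if c.coeffs[1] < -0.99:
            return
        X, Y = stereographic_project(c)
        assert np.allclose(stereographic_inverse(X, Y).coeffs, c.coeffs, atol=1e-12)

    def test_wrong_dimension_rejected(self, rng):
        with pytest.raises(DomainError):
            stereographic_project(random_state(4, rng))


class TestSignSymmetry:
    def test_energy_index_and_spectrum_equal_at_antipodes(self, rng):
        for _ in range(10):
            H = _rand_sym(5, rng)
            c = random_state(5, rng)
            assert energy(c, H) == pytest.approx(energy(-c, H), abs=1e-12)
            Qp = np.sort(np.linalg.eigvalsh(local_hessian(c.coeffs, H)))
            Qm = np.sort(np.linalg.eigvalsh(local_hessian(-c.coeffs, H)))
            assert np.allclose(Qp, Qm, atol=1e-10)
            gp = np.linalg.norm(local_gradient(c.coeffs, H))
            gm = np.linalg.norm(local_gradient(-c.coeffs, H))
            assert gp == pytest.approx(gm, abs=1e-10)
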