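"""One-photon density operator and quantum Fisher information."""

import math

import numpy as np
import pytest

from polarsliver import (
    OpticalConfig,
    build_density_operator,
    dipole_one_photon_states,
    gaussian_one_photon_states,
    qfi_d,
    qfi_separation,
    sigma_inf_qcrb,
    sigma_qcrb,
)
from polarsliver.quantum import _generating_vectors


@pytest.fixture(scope="module")
def coarse_config():
    """33-point pupil: small enough for dense-operator oracles."""
    return OpticalConfig(pupil_grid_n=33, image_size=16)


@pytest.fixture(scope="module")
def dipole_states(coarse_config):
    return dipole_one_photon_states(coarse_config)


class TestDensityOperator:
    @pytest.mark.parametrize("d_nm", [0.0, 5.0, 120.0, 2000.0])
    def test_unit_trace(self, dipole_states, d_nm):
        rho, _, _ = build_density_operator(dipole_states, d_nm)
        assert np.trace(rho).real == pytest.approx(1.0, rel=1e-10)

    def test_coincident_emitters_spectrum(self, coarse_config):
        """At d = 0 the two emitters' states merge: three nonzero
        eigenvalues (one per dipole orientation) summing to 1; with
        equal orientation weighting each is exactly 1/3."""
        for weights, expect_third in (("collection", False), ("equal", True)):
            states = dipole_one_photon_states(
                coarse_config, orientation_weights=weights
            )
            rho, _, _ = build_density_operator(states, 0.0)
            lam = np.sort(np.linalg.eigvalsh(rho))[::-1]
            nonzero = lam[lam > 1e-10]
            assert len(nonzero) == 3
            assert nonzero.sum() == pytest.approx(1.0, rel=1e-10)
            # x and y dipoles collect identically
            assert nonzero[-1] == pytest.approx(nonzero[-2], rel=1e-8)
            if expect_third:
                np.testing.assert_allclose(nonzero, 1.0 / 3.0, rtol=1e-10)

    def test_orientation_states_are_orthonormal(self, dipole_states):
        for a in dipole_states.stacks:
            assert np.sum(np.abs(a) ** 2) == pytest.approx(1.0, rel=1e-12)
            for b in dipole_states.stacks:
                if a is not b:
                    ov = np.vdot(a, b)
                    assert abs(ov) < 1e-12

    def test_interemitter_overlap_matches_dense_integration(self, dipole_states):
        """Subspace Gram entries equal brute-force overlap integrals."""
        d = 80.0
        psis, _, _ = _generating_vectors(dipole_states, d, 0.0, (0.0, 0.0))
        # emitter 1 / emitter 2, same orientation (x): indices 0 and 1
        got = np.vdot(psis[0], psis[1])
        grid = dipole_states.grid
        KX = grid.KX * np.ones_like(grid.KY)
        stack = dipole_states.stacks[0]
        phase = np.exp(-1j * KX * (-d / 2)) * np.exp(-1j * KX * (d / 2)).conj()
        expected = np.sum(np.abs(stack) ** 2 * phase.conj()[np.newaxis])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_derivative_matches_finite_difference(self, dipole_states):
        """Analytic tip-tilt derivative of the states vs central difference."""
        d = 60.0
        h = 1e-4
        _, dpsis, _ = _generating_vectors(dipole_states, d, 0.0, (0.0, 0.0))
        plus, _, _ = _generating_vectors(dipole_states, d + h, 0.0, (0.0, 0.0))
        minus, _, _ = _generating_vectors(dipole_states, d - h, 0.0, (0.0, 0.0))
        fd = (plus[0] - minus[0]) / (2 * h)
        np.testing.assert_allclose(dpsis[0], fd, atol=1e-8 * np.abs(dpsis[0]).max())


class TestQFI:
    def test_pure_state_closed_form(self, coarse_config):
        """For a pure state, K = 4(⟨∂ψ|∂ψ⟩ − |⟨ψ|∂ψ⟩|²)."""
        states = gaussian_one_photon_states(coarse_config)
        grid = states.grid
        KX = grid.KX * np.ones_like(grid.KY)
        psi = (states.stacks[0] * np.exp(-1j * KX * 10.0)).ravel()
        dpsi = (-1j * KX.ravel() / 2.0) * psi
        # two-element orthonormal basis containing ψ and ∂ψ
        v2 = dpsi - np.vdot(psi, dpsi) * psi
        v2 /= np.linalg.norm(v2)
        basis = np.stack([psi, v2], axis=1)
        c = basis.conj().T @ psi
        dc = basis.conj().T @ dpsi
        rho = np.outer(c, c.conj())
        drho = np.outer(dc, c.conj()) + np.outer(c, dc.conj())
        K, _ = qfi_separation(rho, drho)
        expected = 4.0 * (
            np.vdot(dpsi, dpsi).real - abs(np.vdot(psi, dpsi)) ** 2
        )
        assert K == pytest.approx(expected, rel=1e-10)

    def test_gaussian_model_constant_qfi(self, coarse_config):
        """Two incoherent Gaussian emitters: K_d = 1/(4σ²) at every d."""
        states = gaussian_one_photon_states(coarse_config)
        kmax = float(np.abs(states.grid.kx).max())
        sigma = 4.0 / kmax
        expected = 1.0 / (4.0 * sigma**2)
        for d in (0.01 * sigma, sigma, 8.0 * sigma):
            assert qfi_d(states, d).K_d == pytest.approx(expected, rel=1e-6)

    def test_subspace_equals_dense_grid_oracle(self, coarse_config, dipole_states):
        """Reduced-subspace QFI equals a dense-operator eigendecomposition."""
        d = 100.0
        K_sub = qfi_d(dipole_states, d).K_d

        psis, dpsis, weights = _generating_vectors(dipole_states, d, 0.0, (0.0, 0.0))
        dim = psis[0].size
        rho = np.zeros((dim, dim), dtype=complex)
        drho = np.zeros_like(rho)
        for w, p, dp in zip(weights, psis, dpsis):
            rho += w * np.outer(p, p.conj())
            drho += w * (np.outer(dp, p.conj()) + np.outer(p, dp.conj()))
        lam, E = np.linalg.eigh(rho)
        idx = np.flatnonzero(lam > 1e-12)
        Ek = E[:, idx]  # eigenvectors with nonzero weight
        rows = Ek.conj().T @ drho  # ⟨e_i|∂ρ in the grid basis
        Mkk = rows @ Ek  # ⟨e_i|∂ρ|e_j⟩ for kept i, j
        # kept-kept block of the double sum
        denom = lam[idx][:, None] + lam[idx][None, :]
        K_dense = float(np.sum(2.0 * np.abs(Mkk) ** 2 / denom))
        # kept-null cross terms: Σ_{j null} |M_ij|² follows from the full
        # row norm (basis-independent) minus the kept part; each pair
        # (kept, null) appears twice in the symmetric double sum
        row_norm2 = np.sum(np.abs(rows) ** 2, axis=1)
        kept_part = np.sum(np.abs(Mkk) ** 2, axis=1)
        K_dense += float(
            np.sum(2.0 * 2.0 * (row_norm2 - kept_part) / lam[idx])
        )
        assert K_sub == pytest.approx(K_dense, rel=1e-6)

    def test_isotropy_in_alpha(self, dipole_states):
        # residual anisotropy reflects the square-grid discretization of
        # the pupil disc (~1e-6 relative on the coarse grid)
        ks = [qfi_d(dipole_states, 75.0, alpha=a).K_d for a in (0.0, 0.7, 2.1)]
        assert max(ks) / min(ks) - 1 < 1e-4

    def test_dipole_qfi_larger_at_small_d(self, dipole_states):
        """Unlike the Gaussian model, σ_QCRB(d→0) < σ_∞ for dipoles."""
        sig_ref = math.pi / (2 * float(np.abs(dipole_states.grid.kx).max()))
        near = sigma_qcrb(dipole_states, 0.01 * sig_ref)
        far = sigma_qcrb(dipole_states, 16 * sig_ref)
        assert near < far

    def test_sigma_inf_scales_inverse_sqrt_s(self, dipole_states):
        a = sigma_inf_qcrb(dipole_states, s=1.0)
        b = sigma_inf_qcrb(dipole_states, s=25.0)
        assert b == pytest.approx(a / 5.0, rel=1e-10)


class TestCFIvsQFI:
    @pytest.mark.parametrize("method", ["DD", "SLIVER", "SLIVER+DD",
                                        "DDA+DDR", "PolarSLIVER"])
    def test_classical_fi_bounded_by_qfi(self, small_config, method):
        """Every measurement's FI sits below the quantum FI (1% slack)."""
        from polarsliver import ParameterVector, TwoEmitterModel, fisher_matrix
        from polarsliver import get_engine, sigma_psf

        sig = sigma_psf(small_config)
        states = dipole_one_photon_states(small_config)
        model = TwoEmitterModel(get_engine(small_config, method))
        for d_sig in (0.05, 0.7, 4.0):
            d = d_sig * sig
            cfi = fisher_matrix(
                model, ParameterVector(d=d, s=1.0), params=("d",)
            ).fim[0, 0]
            K = qfi_d(states, d).K_d
            assert cfi <= K * 1.01
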