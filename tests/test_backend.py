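"""Backend: integrals, mean field, density functionals."""

import numpy as np
import pytest
from scipy.linalg import eigh

from dmrgembed.backend import ConfigurationError, Geometry, build_system
from dmrgembed.backend.basis import ANGSTROM_TO_BOHR, build_shells, primitive_norm
from dmrgembed.backend.scf import (dft_energy, run_mean_field,
                                   two_electron_matrix, two_electron_energy)
from dmrgembed.io_cli import fixtures as fx

from conftest import random_symmetric_eri


# ------------------------------------------------------------ build_system

def test_h2_minimal_basis_counts(h2_eq):
    system, _ = h2_eq
    assert system.nao == 2
    s01 = system.S[0, 1]
    assert 0.0 < s01 < 1.0


def test_propionitrile_ccpvdz_ao_count():
    # 4 heavy atoms x 14 + 5 H x 5 = 81 spherical functions
    g = fx.propionitrile()
    shells = build_shells(g.atoms, g.coords_bohr, "cc-pvdz")
    nao = sum(sh.nsph * sh.nctr for sh in shells)
    assert nao == 81


def test_unknown_element_raises():
    with pytest.raises(Exception):
        build_system(Geometry(["Xx"], np.zeros((1, 3))), "sto-3g")


def test_unknown_basis_raises():
    with pytest.raises(KeyError):
        build_system(fx.water(), "no-such-basis")


def test_overlap_against_quadrature_oracle(water_sto3g):
    """Brute-force numerical quadrature of AO products on sampled pairs.

    Valence pairs only: a uniform cartesian grid cannot resolve the O 1s
    core primitives, but integrates the diffuse functions to ~1e-5.
    """
    system, _ = water_sto3g
    from dmrgembed.backend.grid import ao_values

    lin = np.arange(-7.0, 7.0 + 1e-9, 0.1)
    step = 0.1
    X, Y, Z = np.meshgrid(lin, lin, lin, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    phi = ao_values(system.shells, pts)
    # AO order: O 1s, O 2s, O 2p(x3), H 1s, H 1s
    for (p, q) in [(2, 3), (2, 5), (5, 6)]:
        val = (phi[:, p] * phi[:, q]).sum() * step ** 3
        assert val == pytest.approx(system.S[p, q], abs=2e-5)
    # and a same-center valence norm
    val = (phi[:, 5] * phi[:, 5]).sum() * step ** 3
    assert val == pytest.approx(1.0, abs=2e-5)


def test_aosystem_invariants(water_sto3g):
    system, _ = water_sto3g
    S = system.S
    assert np.allclose(S, S.T)
    assert np.linalg.eigvalsh(S).min() > 0
    assert np.allclose(system.hcore, system.hcore.T)
    eri = system.eri
    rng = np.random.default_rng(0)
    for _ in range(10):
        p, q, r, s = rng.integers(0, system.nao, 4)
        assert eri[p, q, r, s] == pytest.approx(eri[q, p, r, s], abs=1e-12)
        assert eri[p, q, r, s] == pytest.approx(eri[p, q, s, r], abs=1e-12)
        assert eri[p, q, r, s] == pytest.approx(eri[r, s, p, q], abs=1e-12)


# --------------------------------------------------------- run_mean_field

def test_h2_rhf_vs_roothaan_oracle(h2_eq):
    """Independent 2x2 closed-shell Roothaan solve, iterated to a fixed point."""
    system, mf = h2_eq
    S, h, eri, enuc = system.S, system.hcore, system.eri, system.enuc
    w, V = eigh(S)
    X = V @ np.diag(w ** -0.5) @ V.T
    C = eigh(h, S)[1][:, :1]
    for _ in range(200):
        gamma = 2.0 * C @ C.T
        J = np.einsum("pqrs,rs->pq", eri, gamma)
        K = np.einsum("prqs,rs->pq", eri, gamma)
        F = h + J - 0.5 * K
        Fp = X.T @ F @ X
        e, Cp = np.linalg.eigh(Fp)
        C = (X @ Cp)[:, :1]
    gamma = 2.0 * C @ C.T
    e_ref = 0.5 * np.einsum("pq,pq->", gamma, h + F) + enuc
    assert mf.E_total == pytest.approx(e_ref, abs=1e-8)


def test_helium_single_orbital_closed_form():
    system = build_system(Geometry(["He"], np.zeros((1, 3))), "sto-3g")
    mf = run_mean_field(system, "hf")
    # one doubly occupied orbital: E = 2 h_11 + (11|11) in the MO basis
    c = mf.C_occ[:, 0]
    h11 = c @ system.hcore @ c
    j11 = np.einsum("p,q,r,s,pqrs->", c, c, c, c, system.eri)
    assert mf.E_total == pytest.approx(2 * h11 + j11, abs=1e-10)
    assert system.enuc == 0.0


def test_hybrid_self_consistency_identity(water_sto3g):
    system, _ = water_sto3g
    mf = run_mean_field(system, "b3lyp")
    assert dft_energy(system, mf.gamma, "b3lyp") == pytest.approx(
        mf.E_total, abs=1e-9)


def test_mean_field_invariants(water_sto3g):
    system, mf = water_sto3g
    S = system.S
    n = system.n_electrons
    assert np.trace(mf.gamma @ S) == pytest.approx(n, abs=1e-8)
    assert np.allclose(mf.gamma @ S @ mf.gamma, 2 * mf.gamma, atol=1e-7)
    assert np.allclose(mf.C.T @ S @ mf.C, np.eye(system.nao), atol=1e-8)
    assert np.allclose(mf.gamma, 2 * mf.C_occ @ mf.C_occ.T, atol=1e-10)


def test_odd_electron_count_rejected():
    with pytest.raises(ConfigurationError):
        build_system(Geometry(["H"], np.zeros((1, 3))), "sto-3g")


# ---------------------------------------------------- two_electron_matrix

def test_g_of_zero_density_is_zero(water_sto3g):
    system, _ = water_sto3g
    g = two_electron_matrix(system, np.zeros((system.nao,) * 2), "hf")
    assert np.abs(g).max() == 0.0


def test_coulomb_bilinearity(water_sto3g, rng):
    system, _ = water_sto3g
    n = system.nao
    g1 = rng.standard_normal((n, n))
    g1 = g1 + g1.T
    g2 = rng.standard_normal((n, n))
    g2 = g2 + g2.T
    lhs = two_electron_matrix(system, g1 + g2, "hf")
    rhs = two_electron_matrix(system, g1, "hf") + two_electron_matrix(
        system, g2, "hf")
    assert np.abs(lhs - rhs).max() < 1e-10


def test_g_matches_dense_loop_oracle(h2_eq, rng):
    system, _ = h2_eq
    gam = rng.standard_normal((2, 2))
    gam = gam + gam.T
    g = two_electron_matrix(system, gam, "hf")
    ref = np.zeros((2, 2))
    for p in range(2):
        for q in range(2):
            for r in range(2):
                for s in range(2):
                    ref[p, q] += system.eri[p, q, r, s] * gam[r, s]
                    ref[p, q] -= 0.5 * system.eri[p, r, q, s] * gam[r, s]
    assert np.abs(g - ref).max() < 1e-12


def test_g_dimension_mismatch(water_sto3g):
    system, _ = water_sto3g
    with pytest.raises(ValueError):
        two_electron_matrix(system, np.zeros((3, 3)), "hf")


# ------------------------------------------------------------- dft_energy

def test_dft_energy_of_converged_density(water_sto3g):
    system, mf = water_sto3g
    assert dft_energy(system, mf.gamma, "hf") == pytest.approx(
        mf.E_total, abs=1e-9)


def test_dft_energy_of_zero_density(water_sto3g):
    system, _ = water_sto3g
    assert dft_energy(system, np.zeros((system.nao,) * 2), "hf") == \
        pytest.approx(system.enuc, abs=1e-14)


def test_hf_energy_closed_form_arbitrary_idempotent(h2_eq):
    system, mf = h2_eq
    # an idempotent closed-shell density that is NOT the SCF one
    C = eigh(system.hcore + 0.3 * system.S, system.S)[1][:, :1]
    gamma = 2.0 * C @ C.T
    F = system.hcore + two_electron_matrix(system, gamma, "hf")
    e_ref = 0.5 * np.einsum("pq,pq->", gamma, system.hcore + F) + system.enuc
    assert dft_energy(system, gamma, "hf") == pytest.approx(e_ref, abs=1e-10)


def test_unknown_functional_rejected(water_sto3g):
    system, _ = water_sto3g
    with pytest.raises(KeyError):
        dft_energy(system, np.zeros((system.nao,) * 2), "not-a-functional")


# ------------------------------------------------------------- properties

def test_variational_bound(water_sto3g, rng):
    system, mf = water_sto3g
    nocc = system.n_electrons // 2
    # random S-orthonormal occupied set -> idempotent trial density
    w, V = eigh(system.S)
    X = V @ np.diag(w ** -0.5) @ V.T
    for _ in range(5):
        Q = np.linalg.qr(rng.standard_normal((system.nao, nocc)))[0]
        C = X @ Q
        gamma = 2.0 * C @ C.T
        assert np.trace(gamma @ system.S) == pytest.approx(
            system.n_electrons, abs=1e-8)
        assert dft_energy(system, gamma, "hf") >= mf.E_total - 1e-10


def test_translation_invariance():
    g = fx.water()
    e1 = run_mean_field(build_system(g, "sto-3g"), "hf").E_total
    e2 = run_mean_field(build_system(g.translated([1.7, -0.4, 2.9]),
                                     "sto-3g"), "hf").E_total
    assert e1 == pytest.approx(e2, abs=1e-8)


def test_two_electron_energy_consistency(water_sto3g):
    system, mf = water_sto3g
    e2 = two_electron_energy(system, mf.gamma, "hf")
    e_ref = mf.E_total - system.enuc - np.einsum(
        "pq,pq->", mf.gamma, system.hcore)
    assert e2 == pytest.approx(e_ref, abs=1e-9)
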