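"""Embedding operators, embedded SCF, integral transforms, energy assembly."""

import numpy as np
import pytest

from dmrgembed import embedding as emb
from dmrgembed.backend import build_system
from dmrgembed.backend.scf import run_mean_field
from dmrgembed.fci_oracle import fci_solve
from dmrgembed.io_cli import fixtures as fx
from dmrgembed.partition import build_partition

from conftest import whole_system_hamiltonian


# ---------------------------------------------------------- build_projector

def test_projector_empty_environment():
    S = np.eye(3)
    P, muP = emb.build_projector(S, np.zeros((3, 3)), mu=1e6)
    assert np.abs(P).max() == 0.0 and np.abs(muP).max() == 0.0


def test_projector_orthonormal_ao_limit(rng):
    g = rng.standard_normal((4, 4))
    gamma_B = g @ g.T
    P, _ = emb.build_projector(np.eye(4), gamma_B)
    assert np.allclose(P, gamma_B)


def test_projector_triple_product_oracle(rng):
    A = rng.standard_normal((3, 3))
    S = A @ A.T + 3 * np.eye(3)
    g = rng.standard_normal((3, 3))
    gamma_B = g + g.T
    P, muP = emb.build_projector(S, gamma_B, mu=2.5e5)
    ref = np.zeros((3, 3))
    for p in range(3):
        for q in range(3):
            for r in range(3):
                for s in range(3):
                    ref[p, q] += S[p, r] * gamma_B[r, s] * S[s, q]
    assert np.abs(P - ref).max() < 1e-10
    assert np.abs(muP - 2.5e5 * ref).max() < 1e-5


def test_projector_asymmetric_input_rejected():
    bad = np.array([[0.0, 1.0], [0.0, 0.0]])
    with pytest.raises(ValueError):
        emb.build_projector(np.eye(2), bad)


# ------------------------------------------------ build_embedding_potential

def test_vemb_zero_for_empty_environment(water_sto3g):
    system, mf = water_sto3g
    v = emb.build_embedding_potential(system, mf.gamma,
                                      np.zeros_like(mf.gamma), "hf")
    assert np.abs(v).max() < 1e-10


def test_vemb_hf_equals_jk_of_gamma_b(water_dimer_sto3g, water_dimer_hf):
    system, mf = water_dimer_sto3g, water_dimer_hf
    part = build_partition(mf, system, [0, 1, 2])
    v = emb.build_embedding_potential(system, part.gamma_A, part.gamma_B, "hf")
    gB = part.gamma_B
    n = system.nao
    ref = np.zeros((n, n))
    eri = system.eri
    for p in range(n):
        for q in range(n):
            ref[p, q] = np.sum(eri[p, q] * gB) - 0.5 * np.sum(eri[p, :, q, :] * gB)
    assert np.abs(v - ref).max() < 1e-9


def test_vemb_zero_when_whole_system_active(water_sto3g):
    system, mf = water_sto3g
    part = build_partition(mf, system, [0, 1, 2], all_virtuals=True)
    ops = emb.build_operators(system, part, "hf")
    assert np.abs(ops.v_emb).max() < 1e-8


# --------------------------------------------------------------- embedded_scf

def test_whole_system_embedding_reproduces_full_hf(water_sto3g):
    system, mf = water_sto3g
    part = build_partition(mf, system, [0, 1, 2], all_virtuals=True)
    ops = emb.build_operators(system, part, "hf")
    emf = emb.embedded_scf(system, ops, part)
    assert emf.E_hf_in_dft == pytest.approx(mf.E_total, abs=1e-8)
    assert np.abs(emf.gamma_A_tilde - mf.gamma).max() < 1e-6


def test_level_shift_orthogonality(water_dimer_sto3g, water_dimer_hf):
    system, mf = water_dimer_sto3g, water_dimer_hf
    part = build_partition(mf, system, [0, 1, 2])
    ops = emb.build_operators(system, part, "hf", mu=1e6)
    emf = emb.embedded_scf(system, ops, part, span="full")
    tr = np.einsum("pq,pq->", emf.gamma_A_tilde, ops.P_B)
    assert abs(tr) < 1e-6
    assert np.trace(emf.gamma_A_tilde @ system.S) == pytest.approx(
        part.n_act_elec, abs=1e-8)


def test_penalty_scaling_with_mu(water_dimer_sto3g, water_dimer_hf):
    """tr(gamma P_B) follows the quadratic penalty law ~ 1/mu^2.

    (First-order perturbation theory: the admixture amplitude of
    environment-occupied character scales as 1/mu, its weight as 1/mu^2;
    doubling mu divides the trace by ~4.)
    """
    system, mf = water_dimer_sto3g, water_dimer_hf
    part = build_partition(mf, system, [0, 1, 2])
    traces = {}
    for mu in (1e5, 2e5):
        ops = emb.build_operators(system, part, "hf", mu=mu)
        emf = emb.embedded_scf(system, ops, part, span="full")
        traces[mu] = float(np.einsum("pq,pq->", emf.gamma_A_tilde, ops.P_B))
    ratio = traces[1e5] / traces[2e5]
    assert 3.5 < ratio < 4.5


def test_occupied_count_exceeding_span_rejected(water_sto3g):
    system, mf = water_sto3g
    part = build_partition(mf, system, [0, 1, 2], all_virtuals=True)
    ops = emb.build_operators(system, part, "hf")
    part.C_occ_A = part.C_occ_A[:, :2]   # shrink span below occupied count
    part.C_virt_shells = []
    with pytest.raises(ValueError):
        emb.embedded_scf(system, ops, part)


# ------------------------------------------------- transform_active_integrals

def test_identity_span_toy(rng):
    """Orthonormal-AO limit: the transform is the identity."""
    from types import SimpleNamespace

    n = 3
    h = rng.standard_normal((n, n))
    h = h + h.T
    from conftest import random_symmetric_eri

    eri = random_symmetric_eri(n, rng)
    system = SimpleNamespace(S=np.eye(n), eri=eri, nao=n)
    ops = SimpleNamespace(h_tilde=h, level_env="hf", mu=1e6,
                          P_B=np.zeros((n, n)), v_emb=np.zeros((n, n)))
    part = SimpleNamespace(n_act_elec=2, gamma_A=np.zeros((n, n)),
                           gamma_B=np.zeros((n, n)))
    ham = emb.transform_active_integrals(system, ops, part, np.eye(n),
                                         e_core=0.0)
    assert np.abs(ham.h_pq - h).max() < 1e-12
    assert np.abs(ham.eri_pqrs - eri).max() < 1e-12


def test_two_orbital_transform_against_quadruple_loop(h2_eq):
    system, mf = h2_eq
    ham, part, ops, emf = whole_system_hamiltonian(system, mf)
    C = ham.C_active
    n = system.nao
    ref = np.zeros((2, 2, 2, 2))
    for p in range(2):
        for q in range(2):
            for r in range(2):
                for s in range(2):
                    acc = 0.0
                    for a in range(n):
                        for b in range(n):
                            for c in range(n):
                                for d in range(n):
                                    acc += (C[a, p] * C[b, q] * C[c, r]
                                            * C[d, s] * system.eri[a, b, c, d])
                    ref[p, q, r, s] = acc
    assert np.abs(ham.eri_pqrs - ref).max() < 1e-10


def test_non_orthonormal_span_rejected(water_sto3g, rng):
    system, mf = water_sto3g
    part = build_partition(mf, system, [0, 1, 2], all_virtuals=True)
    ops = emb.build_operators(system, part, "hf")
    bad = rng.standard_normal((system.nao, 3))
    with pytest.raises(ValueError):
        emb.transform_active_integrals(system, ops, part, bad)


# --------------------------------------------------------- energy assembly

@pytest.mark.parametrize("level", ["hf", "pbe", "b3lyp"])
def test_same_level_exactness(water_dimer_sto3g, level):
    """Same-functional embedding reproduces the full-system energy."""
    system = water_dimer_sto3g
    mf = run_mean_field(system, level)
    part = build_partition(mf, system, [0, 1, 2])
    ops = emb.build_operators(system, part, level)
    emf = emb.embedded_scf(system, ops, part, level_active=level)
    assert emf.E_hf_in_dft == pytest.approx(mf.E_total, abs=1e-6)


def test_empty_environment_wf_reduction(h4_chain):
    """Whole-system-active FCI-in-DFT equals plain FCI in the same space."""
    system, mf = h4_chain
    ham, part, ops, emf = whole_system_hamiltonian(system, mf)
    sol = fci_solve(ham)
    # plain FCI in the same orthonormal orbital space, no embedding plumbing
    C = ham.C_active
    h_plain = C.T @ system.hcore @ C
    ham_plain = emb.ActiveHamiltonian(
        norb=ham.norb, nelec=ham.nelec, h_pq=h_plain,
        eri_pqrs=ham.eri_pqrs, e_core=system.enuc)
    sol_plain = fci_solve(ham_plain)
    assert sol.energy == pytest.approx(sol_plain.energy, abs=1e-8)


def test_mu_robustness(water_dimer_sto3g, water_dimer_hf):
    system, mf = water_dimer_sto3g, water_dimer_hf
    part = build_partition(mf, system, [0, 1, 2])
    energies = []
    for mu in (1e5, 1e6, 1e7):
        ops = emb.build_operators(system, part, "hf", mu=mu)
        emf = emb.embedded_scf(system, ops, part)
        energies.append(emf.E_hf_in_dft)
    assert max(energies) - min(energies) < 1e-6


def test_monotone_virtual_truncation(water_dimer_hf, water_dimer_sto3g):
    """Adding a concentric shell never raises the correlated energy."""
    system, mf = water_dimer_sto3g, water_dimer_hf
    energies = []
    for n_shells in (1, 2):
        part = build_partition(mf, system, [0, 1, 2], n_shells=n_shells)
        ops = emb.build_operators(system, part, "hf")
        emf = emb.embedded_scf(system, ops, part)
        ham = emb.transform_active_integrals(system, ops, part, emf.C_emb)
        energies.append(fci_solve(ham).energy)
    assert energies[1] <= energies[0] + 1e-10


def test_levelshift_term_reported(water_dimer_sto3g, water_dimer_hf):
    system, mf = water_dimer_sto3g, water_dimer_hf
    part = build_partition(mf, system, [0, 1, 2])
    ops = emb.build_operators(system, part, "hf")
    emf = emb.embedded_scf(system, ops, part)
    rep = emf.energy_report
    for key in ("E_A_elec", "E_dft_total_density", "E_dft_gamma_A_electronic",
                "tr_gamma_A_v_emb", "mu_tr_gamma_P_B", "total"):
        assert key in rep
    assert abs(rep["mu_tr_gamma_P_B"]) < 1e-6


# -------------------------------------------------------------- FCIDUMP io

def test_fcidump_roundtrip(tmp_path, h4_ham):
    path = tmp_path / "h4.fcidump"
    h4_ham.write(path)
    back = emb.ActiveHamiltonian.read(path)
    assert back.norb == h4_ham.norb
    assert back.nelec == h4_ham.nelec
    assert back.e_core == pytest.approx(h4_ham.e_core, abs=1e-12)
    assert np.abs(back.h_pq - h4_ham.h_pq).max() < 1e-12
    assert np.abs(back.eri_pqrs - h4_ham.eri_pqrs).max() < 1e-12


def test_frozen_core_bookkeeping(h4_chain):
    system, mf = h4_chain
    ham, part, ops, emf = whole_system_hamiltonian(system, mf)
    frozen = emb.freeze_core(system, ham, 1)
    assert frozen.norb == ham.norb - 1
    assert frozen.nelec == ham.nelec - 2
    # freezing the lowest orbital of a mean-field-dominated system keeps the
    # FCI energy within the correlation contribution of that orbital
    e_full = fci_solve(ham).energy
    e_frozen = fci_solve(frozen).energy
    assert e_frozen >= e_full - 1e-10
    assert abs(e_frozen - e_full) < 0.05
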