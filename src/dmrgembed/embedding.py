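"""Projection-based embedding: operators, embedded SCF, active Hamiltonian,
and total-energy assembly.

Bookkeeping convention (pinned by the same-level exactness identity):

    E_total = E_A^elec[h-tilde]  +  E_DFT[gamma_A + gamma_B]
              - E_DFT^elec[gamma_A] - tr[gamma_A v_emb]

with h-tilde = hcore + v_emb + mu*P_B, so the embedding potential and the
level-shift penalty enter the active-subsystem energy through its
one-electron part.  Nuclear repulsion appears once, inside
E_DFT[gamma_A + gamma_B].  The scalar

    e_core = E_DFT[gamma_A + gamma_B] - E_DFT^elec[gamma_A] - tr[gamma_A v_emb]

is attached to the active Hamiltonian, so any solver of the FCIDUMP
(HF, FCI, DMRG) directly reports the embedded total energy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

log = logging.getLogger("dmrgembed.embedded_scf")

from .backend.scf import (MeanFieldSolution, SCFError, _DIIS, dft_energy,
                          two_electron_energy, two_electron_matrix)
from .backend.system import AOSystem
from .fcidump import read_fcidump, write_fcidump
from .partition import SubsystemPartition

__all__ = ["EmbeddingOperators", "ActiveHamiltonian", "EmbeddedMeanField",
           "build_projector", "build_embedding_potential", "build_operators",
           "embedded_scf", "transform_active_integrals", "assemble_total_energy"]

DEFAULT_MU = 1.0e6


# ------------------------------------------------------------- operators

@dataclass
class EmbeddingOperators:
    P_B: np.ndarray
    mu: float
    v_emb: np.ndarray
    h_tilde: np.ndarray
    level_env: str

    @property
    def mu_P_B(self) -> np.ndarray:
        return self.mu * self.P_B


def build_projector(S: np.ndarray, gamma_B: np.ndarray, mu: float = DEFAULT_MU):
    """P_B = S gamma_B S and its level-shifted form."""
    if not np.allclose(S, S.T) or not np.allclose(gamma_B, gamma_B.T):
        raise ValueError("S and gamma_B must be symmetric")
    P = S @ gamma_B @ S
    P = 0.5 * (P + P.T)
    return P, mu * P


def build_embedding_potential(system: AOSystem, gamma_A: np.ndarray,
                              gamma_B: np.ndarray, level_env: str) -> np.ndarray:
    """v_emb = g[gamma_A + gamma_B] - g[gamma_A] at the environment level."""
    g_tot = two_electron_matrix(system, gamma_A + gamma_B, level_env)
    g_a = two_electron_matrix(system, gamma_A, level_env)
    return g_tot - g_a


def build_operators(system: AOSystem, partition: SubsystemPartition,
                    level_env: str, mu: float = DEFAULT_MU) -> EmbeddingOperators:
    P_B, _ = build_projector(system.S, partition.gamma_B, mu)
    v_emb = build_embedding_potential(system, partition.gamma_A,
                                      partition.gamma_B, level_env)
    h_tilde = system.hcore + v_emb + mu * P_B
    return EmbeddingOperators(P_B=P_B, mu=mu, v_emb=v_emb,
                              h_tilde=h_tilde, level_env=level_env)


# --------------------------------------------------------- embedded SCF

@dataclass
class EmbeddedMeanField:
    gamma_A_tilde: np.ndarray            # relaxed AO density of subsystem A
    E_hf_in_dft: float                   # assembled mean-field total energy
    C_emb: np.ndarray                    # canonical embedded orbitals (AO x span)
    eps: np.ndarray
    n_occ: int
    level_active: str
    energy_report: dict = field(default_factory=dict)


def embedded_scf(system: AOSystem, operators: EmbeddingOperators,
                 partition: SubsystemPartition, level_active: str = "hf",
                 conv_tol: float = 1e-9, max_cycle: int = 200,
                 span: np.ndarray | str | None = None) -> EmbeddedMeanField:
    """Self-consistent subsystem-A mean field inside the active span.

    The density is constrained to ``span`` (default: occupied-A plus the
    retained virtual shells; pass ``"full"`` for the whole AO space, where
    only the mu-penalty keeps the density out of the environment).  The
    Fock matrix is F = h_tilde + g[gamma] with g evaluated at
    ``level_active`` (HF for the HF-in-DFT step, the environment
    functional for DFT-in-DFT).
    """
    if span is None:
        C = partition.C_span
    elif isinstance(span, str) and span == "full":
        w, V = eigh(system.S)
        C = V @ np.diag(w ** -0.5) @ V.T
    else:
        C = span
    nspan = C.shape[1]
    nocc = partition.n_act_elec // 2
    if nocc > nspan:
        raise ValueError(f"{nocc} occupied orbitals exceed span size {nspan}")
    h_s = C.T @ operators.h_tilde @ C
    gamma = partition.gamma_A.copy()
    diis = _DIIS()
    energies = []
    e_last = None
    eps = Cs = None
    for it in range(max_cycle):
        F = h_s + C.T @ two_electron_matrix(system, gamma, level_active) @ C
        e_elec = float(np.einsum("pq,pq->", gamma, operators.h_tilde)
                       + two_electron_energy(system, gamma, level_active))
        energies.append(e_elec)
        log.info("embedded scf cycle %d E_elec = %.12f", it, e_elec)
        occ = (C.T @ system.S @ gamma @ system.S @ C) / 2.0
        err = F @ occ - occ @ F
        F = diis.update(F, err)
        eps, Cs = eigh(F)
        C_occ = C @ Cs[:, :nocc]
        gamma_new = 2.0 * C_occ @ C_occ.T
        if e_last is not None and abs(e_elec - e_last) < conv_tol \
                and np.abs(err).max() < 1e-5:
            gamma = gamma_new
            break
        gamma = gamma_new
        e_last = e_elec
    else:
        raise SCFError(f"embedded SCF did not converge in {max_cycle} cycles",
                       energies)
    # one clean final diagonalization for reporting quantities
    F = h_s + C.T @ two_electron_matrix(system, gamma, level_active) @ C
    eps, Cs = eigh(F)
    C_emb = C @ Cs
    C_occ = C_emb[:, :nocc]
    gamma = 2.0 * C_occ @ C_occ.T
    report = assemble_total_energy(system, operators, partition,
                                   gamma_wf=gamma, level_active=level_active)
    return EmbeddedMeanField(gamma_A_tilde=gamma, E_hf_in_dft=report["total"],
                             C_emb=C_emb, eps=eps, n_occ=nocc,
                             level_active=level_active, energy_report=report)


# ------------------------------------------------- active-space Hamiltonian

@dataclass
class ActiveHamiltonian:
    norb: int
    nelec: int
    h_pq: np.ndarray
    eri_pqrs: np.ndarray          # chemist (pq|rs), 8-fold symmetric
    e_core: float
    C_active: np.ndarray = field(repr=False, default=None)   # AO x norb

    def write(self, path):
        write_fcidump(path, self.h_pq, self.eri_pqrs, self.e_core, self.nelec)

    @classmethod
    def read(cls, path):
        h, eri, e_core, norb, nelec, _ = read_fcidump(path)
        return cls(norb=norb, nelec=nelec, h_pq=h, eri_pqrs=eri, e_core=e_core)


def transform_active_integrals(system: AOSystem, operators: EmbeddingOperators,
                               partition: SubsystemPartition,
                               C_active: np.ndarray,
                               e_core: float | None = None) -> ActiveHamiltonian:
    """AO -> active-MO transform of h_tilde and the ERIs.

    ``C_active`` must be S-orthonormal (typically the canonical orbitals
    of the embedded mean field).  ``e_core`` defaults to the assembly
    constant of the pinned energy convention.
    """
    S = system.S
    dev = np.abs(C_active.T @ S @ C_active - np.eye(C_active.shape[1])).max()
    if dev > 1e-8:
        raise ValueError(f"active span not S-orthonormal (deviation {dev:.2e})")
    h = C_active.T @ operators.h_tilde @ C_active
    eri = system.eri
    C = C_active
    t = np.tensordot(eri, C, axes=([3], [0]))
    t = np.tensordot(t, C, axes=([2], [0]))
    t = np.tensordot(t, C, axes=([1], [0]))
    t = np.tensordot(t, C, axes=([0], [0]))
    eri_mo = np.ascontiguousarray(t.transpose(3, 2, 1, 0))
    if e_core is None:
        e_core = _assembly_constant(system, operators, partition)
    return ActiveHamiltonian(norb=C.shape[1], nelec=partition.n_act_elec,
                             h_pq=0.5 * (h + h.T), eri_pqrs=eri_mo,
                             e_core=float(e_core), C_active=C)


def _assembly_constant(system, operators, partition) -> float:
    gamma_A, gamma_B = partition.gamma_A, partition.gamma_B
    e_full = dft_energy(system, gamma_A + gamma_B, operators.level_env)
    e_a = dft_energy(system, gamma_A, operators.level_env, include_enuc=False)
    tr_vemb = float(np.einsum("pq,pq->", gamma_A, operators.v_emb))
    return e_full - e_a - tr_vemb


def freeze_core(system: AOSystem, ham: ActiveHamiltonian,
                n_core: int) -> ActiveHamiltonian:
    """Fold the lowest ``n_core`` active orbitals into the core constant.

    The core orbitals are taken as the first columns of the active basis
    (canonical order, energies ascending); their mean-field (HF-level)
    field is absorbed into the one-electron part.
    """
    if n_core == 0:
        return ham
    if 2 * n_core > ham.nelec:
        raise ValueError("cannot freeze more electrons than present")
    norb = ham.norb
    core = list(range(n_core))
    act = list(range(n_core, norb))
    h, eri = ham.h_pq, ham.eri_pqrs
    # J/K of the closed-shell core in the active MO basis
    Jc = 2.0 * np.einsum("pqii->pq", eri[:, :, core][:, :, :, core])
    Kc = np.einsum("piiq->pq", eri[:, core][:, :, core, :])
    e_core_mf = float(2.0 * np.trace(h[np.ix_(core, core)])
                      + np.trace((Jc - Kc)[np.ix_(core, core)]))
    h_eff = (h + Jc - Kc)[np.ix_(act, act)]
    eri_act = eri[np.ix_(act, act, act, act)]
    C_act = ham.C_active[:, act] if ham.C_active is not None else None
    return ActiveHamiltonian(norb=len(act), nelec=ham.nelec - 2 * n_core,
                             h_pq=h_eff, eri_pqrs=eri_act,
                             e_core=ham.e_core + e_core_mf, C_active=C_act)


# --------------------------------------------------------- energy assembly

def assemble_total_energy(system: AOSystem, operators: EmbeddingOperators,
                          partition: SubsystemPartition, *,
                          e_wf_elec: float | None = None,
                          gamma_wf: np.ndarray | None = None,
                          level_active: str = "hf") -> dict:
    """Assemble the embedded total energy and its components.

    Either ``e_wf_elec`` (correlated electronic energy of subsystem A with
    the h_tilde one-electron part, no core constant) together with the AO
    back-transformed 1-RDM ``gamma_wf``, or a mean-field AO density
    ``gamma_wf`` alone (its E_A is evaluated at ``level_active``).
    """
    if gamma_wf is None:
        raise ValueError("gamma_wf (AO 1-RDM of subsystem A) is required")
    if e_wf_elec is None:
        e_a = float(np.einsum("pq,pq->", gamma_wf, operators.h_tilde)
                    + two_electron_energy(system, gamma_wf, level_active))
    else:
        e_a = float(e_wf_elec)
    const = _assembly_constant(system, operators, partition)
    mu_term = float(operators.mu * np.einsum("pq,pq->", gamma_wf, operators.P_B))
    gamma_A = partition.gamma_A
    report = {
        "E_A_elec": e_a,
        "E_dft_total_density": dft_energy(system, gamma_A + partition.gamma_B,
                                          operators.level_env),
        "E_dft_gamma_A_electronic": dft_energy(system, gamma_A,
                                               operators.level_env,
                                               include_enuc=False),
        "tr_gamma_A_v_emb": float(np.einsum("pq,pq->", gamma_A, operators.v_emb)),
        "mu_tr_gamma_P_B": mu_term,
        "total": e_a + const,
    }
    return report


def energy_report_json(report: dict) -> str:
    return json.dumps({k: float(v) for k, v in report.items()}, indent=1)
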