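"""Occupied-space SPADE partitioning and concentric virtual localization.

``spade_split`` rotates the occupied orbitals so the density cleanly
separates into an active fragment (A) and environment (B) at the largest
singular-value gap of the fragment-projected orthogonalized occupieds.
``concentric_shells`` builds a truncated virtual space for A: shell 1 is
the span of the virtuals' projection onto the fragment AOs; each further
shell is generated by one application of the converged full-system Fock
matrix, restricted to the remaining virtual complement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, svd

from .backend.scf import MeanFieldSolution, two_electron_matrix
from .backend.system import AOSystem

__all__ = ["SubsystemPartition", "spade_split", "concentric_shells",
           "assemble_densities", "build_partition", "DegenerateGapError",
           "frozen_core_counts"]

_CORE_ORBITALS = {0: 0}   # per-Z chemical core sizes


def _n_core(Z: int) -> int:
    if Z <= 2:
        return 0
    if Z <= 10:
        return 1
    if Z <= 18:
        return 5
    if Z <= 36:
        return 9
    raise NotImplementedError(f"no frozen-core rule for Z={Z}")


def frozen_core_counts(system: AOSystem) -> dict:
    """Orbital/electron bookkeeping for a frozen-core full-molecule treatment."""
    ncore = int(sum(_n_core(int(z)) for z in system.geometry.charges))
    nelec = system.n_electrons
    return {
        "n_core_orbitals": ncore,
        "n_correlated_orbitals": system.nao - ncore,
        "n_correlated_electrons": nelec - 2 * ncore,
    }


class DegenerateGapError(ValueError):
    """Two maximal SPADE gaps coincide; an explicit k override is required."""


@dataclass
class SubsystemPartition:
    active_atoms: list
    C_occ_A: np.ndarray
    C_occ_B: np.ndarray
    gamma_A: np.ndarray
    gamma_B: np.ndarray
    C_virt_shells: list[np.ndarray]
    n_act_elec: int
    sigma: np.ndarray
    mf: MeanFieldSolution = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.C_occ_A.shape[1]

    @property
    def shell_sizes(self) -> list[int]:
        return [b.shape[1] for b in self.C_virt_shells]

    @property
    def n_act_orb(self) -> int:
        return self.k + sum(self.shell_sizes)

    @property
    def C_span(self) -> np.ndarray:
        """S-orthonormal active span: occupied-A columns then virtual shells."""
        return np.hstack([self.C_occ_A] + list(self.C_virt_shells))

    def report(self) -> dict:
        return {
            "active_atoms": [int(a) for a in self.active_atoms],
            "singular_values": [float(s) for s in self.sigma],
            "k": self.k,
            "shell_sizes": self.shell_sizes,
            "n_active_electrons": int(self.n_act_elec),
            "n_active_orbitals": int(self.n_act_orb),
        }

    def report_json(self) -> str:
        return json.dumps(self.report(), indent=1)


def _sqrtm_spd(S: np.ndarray) -> np.ndarray:
    w, V = eigh(S)
    return V @ np.diag(np.sqrt(w)) @ V.T


def spade_split(mf: MeanFieldSolution, system: AOSystem, active_atoms,
                k_override: int | None = None):
    """SVD split of the occupied space over fragment AO rows.

    Returns (C_occ_A, C_occ_B, sigma, n_act_elec).
    """
    active_atoms = list(active_atoms)
    if not active_atoms:
        raise ValueError("active_atoms must be non-empty")
    rows = system.fragment_ao_indices(active_atoms)
    if len(rows) == 0:
        raise ValueError("active atoms carry no basis functions")
    C_occ = mf.C_occ
    nocc = C_occ.shape[1]
    Shalf = _sqrtm_spd(system.S)
    Obar = (Shalf @ C_occ)[rows, :]
    _, sigma, Vt = svd(Obar, full_matrices=True)
    sigma = np.concatenate([sigma, np.zeros(nocc - len(sigma))])
    C_rot = C_occ @ Vt.T
    if k_override is not None:
        k = int(k_override)
    else:
        gaps = sigma - np.concatenate([sigma[1:], [0.0]])
        k = int(np.argmax(gaps)) + 1
        best = gaps[k - 1]
        ties = np.nonzero(np.abs(gaps - best) < 1e-8)[0]
        if len(ties) > 1:
            raise DegenerateGapError(
                f"SPADE gap degenerate at k candidates {list(ties + 1)}; "
                "pass an explicit k override")
    return C_rot[:, :k], C_rot[:, k:], sigma, 2 * k


def concentric_shells(mf: MeanFieldSolution, system: AOSystem,
                      C_occ_A: np.ndarray, active_atoms,
                      n_shells: int = 2, rank_tol: float = 1e-8):
    """Virtual shell blocks by concentric localization. Returns list of blocks."""
    import warnings

    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    rows = system.fragment_ao_indices(list(active_atoms))
    C_virt = mf.C[:, mf.n_occ:]
    if C_virt.shape[1] == 0:
        return []
    # shell 1: projection of virtuals onto the fragment AO subspace
    A = (system.S @ C_virt)[rows, :]
    _, s, Vt = svd(A, full_matrices=True)
    r = int(np.sum(s > rank_tol * max(s[0], 1e-30)))
    shells = [C_virt @ Vt.T[:, :r]]
    C_rest = C_virt @ Vt.T[:, r:]
    F = system.hcore + two_electron_matrix(system, mf.gamma, mf.level)
    for t in range(1, n_shells):
        if C_rest.shape[1] == 0:
            warnings.warn(f"virtual space exhausted after {t} shells")
            break
        M = shells[-1].T @ F @ C_rest
        _, s, Vt = svd(M, full_matrices=True)
        r = int(np.sum(s > rank_tol * max(s[0] if len(s) else 0.0, 1e-30)))
        if r == 0:
            warnings.warn(f"shell {t + 1} has empty span; stopping")
            break
        shells.append(C_rest @ Vt.T[:, :r])
        C_rest = C_rest @ Vt.T[:, r:]
    return shells


def assemble_densities(C_occ_A: np.ndarray, C_occ_B: np.ndarray):
    gamma_A = 2.0 * C_occ_A @ C_occ_A.T
    gamma_B = 2.0 * C_occ_B @ C_occ_B.T
    return gamma_A, gamma_B


def build_partition(mf: MeanFieldSolution, system: AOSystem, active_atoms,
                    n_shells: int = 2, k_override: int | None = None,
                    all_virtuals: bool = False) -> SubsystemPartition:
    """Full partitioning pipeline: SPADE + concentric shells + densities."""
    C_A, C_B, sigma, n_act = spade_split(mf, system, active_atoms, k_override)
    if all_virtuals:
        shells = [mf.C[:, mf.n_occ:]] if mf.C.shape[1] > mf.n_occ else []
    else:
        shells = concentric_shells(mf, system, C_A, active_atoms, n_shells)
    gamma_A, gamma_B = assemble_densities(C_A, C_B)
    return SubsystemPartition(
        active_atoms=list(active_atoms), C_occ_A=C_A, C_occ_B=C_B,
        gamma_A=gamma_A, gamma_B=gamma_B, C_virt_shells=shells,
        n_act_elec=n_act, sigma=sigma, mf=mf)
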