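"""Restricted HF / Kohn-Sham SCF and density-functional evaluation.

Density convention throughout: gamma is spin-summed, tr(gamma S) = N_elec,
gamma = 2 C_occ C_occ^T for a closed shell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

log = logging.getLogger("dmrgembed.scf")

from .grid import MolecularGrid, ao_values
from .system import AOSystem, ConfigurationError
from .xc import eval_xc, get_functional


class SCFError(RuntimeError):
    """SCF failed to converge; carries the energy history."""

    def __init__(self, msg, energies=None):
        super().__init__(msg)
        self.energies = list(energies or [])


@dataclass
class MeanFieldSolution:
    """Converged full-system mean field (HF or KS)."""

    level: str
    C: np.ndarray                # AO x MO coefficients, S-orthonormal columns
    eps: np.ndarray
    gamma: np.ndarray            # AO density, tr(gamma S) = N
    E_total: float
    n_occ: int
    system: AOSystem = field(repr=False, default=None)

    @property
    def C_occ(self) -> np.ndarray:
        return self.C[:, : self.n_occ]

    def save(self, path):
        np.savez(path, level=self.level, C=self.C, eps=self.eps,
                 gamma=self.gamma, E_total=self.E_total, n_occ=self.n_occ)

    @classmethod
    def load(cls, path, system=None):
        d = np.load(path, allow_pickle=False)
        return cls(level=str(d["level"]), C=d["C"], eps=d["eps"], gamma=d["gamma"],
                   E_total=float(d["E_total"]), n_occ=int(d["n_occ"]), system=system)


# ---------------------------------------------------------------- grid cache

def _get_grid_data(system: AOSystem, needs_sigma: bool):
    cache = getattr(system, "_grid_cache", None)
    if cache is None:
        grid = MolecularGrid(system.geometry.atoms, system.geometry.coords)
        phi, dphi = ao_values(system.shells, grid.points, deriv=True)
        cache = (grid, phi, dphi)
        system._grid_cache = cache
    return cache


def _density_on_grid(gamma, phi, dphi):
    t = phi @ gamma
    rho = np.einsum("pi,pi->p", t, phi)
    grad = np.stack([2.0 * np.einsum("pi,pi->p", t, dphi[ax]) for ax in range(3)])
    return rho, grad


def _xc_matrix_energy(system, gamma, level):
    """(Vxc, Exc) on the molecular grid; zero for pure HF."""
    fn = get_functional(level)
    if fn.is_hf:
        n = system.nao
        return np.zeros((n, n)), 0.0
    grid, phi, dphi = _get_grid_data(system, fn.needs_sigma)
    rho, grad = _density_on_grid(gamma, phi, dphi)
    sigma = np.einsum("xp,xp->p", grad, grad)
    e, vr, vs = eval_xc(level, rho, sigma)
    w = grid.weights
    exc = float(w @ e)
    vxc = phi.T @ (phi * (w * vr)[:, None])
    if fn.needs_sigma:
        # 2 * vsigma * grad rho . grad(phi_p phi_q)
        gphi = sum((dphi[ax] * (2.0 * w * vs * grad[ax])[:, None]) for ax in range(3))
        m = phi.T @ gphi
        vxc += m + m.T
    return 0.5 * (vxc + vxc.T), exc


# --------------------------------------------------------- matrix functionals

def coulomb_exchange(system: AOSystem, gamma: np.ndarray):
    eri = system.eri
    J = np.einsum("pqrs,rs->pq", eri, gamma)
    K = np.einsum("prqs,rs->pq", eri, gamma)
    return J, K


def two_electron_matrix(system: AOSystem, gamma: np.ndarray, level: str) -> np.ndarray:
    """g[gamma]: Coulomb + scaled exact exchange + XC potential matrix."""
    gamma = np.asarray(gamma, float)
    if gamma.shape != (system.nao, system.nao):
        raise ValueError(f"gamma has shape {gamma.shape}, expected {(system.nao,) * 2}")
    fn = get_functional(level)
    J, K = coulomb_exchange(system, gamma)
    g = J - 0.5 * fn.hyb * K
    if fn.parts:
        vxc, _ = _xc_matrix_energy(system, gamma, level)
        g = g + vxc
    return g


def two_electron_energy(system: AOSystem, gamma: np.ndarray, level: str) -> float:
    """Coulomb + scaled exchange + XC energy of a density (no core, no enuc)."""
    fn = get_functional(level)
    J, K = coulomb_exchange(system, gamma)
    e = float(0.5 * np.einsum("pq,pq->", gamma, J)
              - 0.25 * fn.hyb * np.einsum("pq,pq->", gamma, K))
    if fn.parts:
        _, exc = _xc_matrix_energy(system, gamma, level)
        e += exc
    return e


def dft_energy(system: AOSystem, gamma: np.ndarray, level: str,
               include_enuc: bool = True) -> float:
    """Energy functional of an arbitrary (not necessarily SCF) density."""
    fn = get_functional(level)
    J, K = coulomb_exchange(system, gamma)
    e = float(np.einsum("pq,pq->", gamma, system.hcore)
              + 0.5 * np.einsum("pq,pq->", gamma, J)
              - 0.25 * fn.hyb * np.einsum("pq,pq->", gamma, K))
    if fn.parts:
        _, exc = _xc_matrix_energy(system, gamma, level)
        e += exc
    if include_enuc:
        e += system.enuc
    return e


# ------------------------------------------------------------------- SCF

class _DIIS:
    def __init__(self, maxlen=8):
        self.f, self.e = [], []
        self.maxlen = maxlen

    def update(self, F, err):
        self.f.append(F.copy())
        self.e.append(err.ravel().copy())
        if len(self.f) > self.maxlen:
            self.f.pop(0)
            self.e.pop(0)
        n = len(self.f)
        if n < 2:
            return F
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = self.e[i] @ self.e[j]
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            return F
        return sum(ci * fi for ci, fi in zip(c, self.f))


def run_mean_field(system: AOSystem, level: str = "hf",
                   conv_tol: float = 1e-9, max_cycle: int = 200) -> MeanFieldSolution:
    """Solve restricted HF/KS to |dE| < conv_tol (plus a gradient check)."""
    nelec = system.n_electrons
    if nelec % 2:
        raise ConfigurationError("odd electron count; closed-shell only")
    nocc = nelec // 2
    S, h = system.S, system.hcore
    w, V = eigh(S)
    if w.min() < 1e-10:
        raise ConfigurationError("overlap matrix near-singular")
    X = V @ np.diag(w ** -0.5) @ V.T
    # core guess
    e0, C0 = eigh(h, S)
    C = C0
    gamma = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    diis = _DIIS()
    energies = []
    e_last = None
    for it in range(max_cycle):
        g = two_electron_matrix(system, gamma, level)
        F = h + g
        e_tot = dft_energy(system, gamma, level)
        energies.append(e_tot)
        log.info("scf cycle %d E = %.12f", it, e_tot)
        err = X.T @ (F @ gamma @ S - S @ gamma @ F) @ X
        F_use = diis.update(F, err)
        eps, C = eigh(F_use, S)
        gamma_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        if e_last is not None and abs(e_tot - e_last) < conv_tol \
                and np.abs(err).max() < 1e-5:
            gamma = gamma_new
            break
        gamma = gamma_new
        e_last = e_tot
    else:
        raise SCFError(f"SCF did not converge in {max_cycle} cycles", energies)
    # final consistent quantities
    g = two_electron_matrix(system, gamma, level)
    eps, C = eigh(h + g, S)
    gamma = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    e_tot = dft_energy(system, gamma, level)
    return MeanFieldSolution(level=level, C=C, eps=eps, gamma=gamma,
                             E_total=e_tot, n_occ=nocc, system=system)
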