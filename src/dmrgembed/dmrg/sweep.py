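"""Two-site DMRG sweeps with dynamical block state selection.

The local eigenproblem is solved by Davidson with a diagonal
preconditioner; decimation is a quantum-number-blocked SVD whose rank is
chosen as the smallest bond dimension keeping the discarded Schmidt
weight below the preset truncation-error target (DBSS).  A decaying
perturbative noise term helps escape local minima during the early
sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .local_ops import DIM, QNUMS
from .mpo import MPO, build_mpo, _update_left_env
from .mps import MPS, product_state_mps

__all__ = ["SweepConfig", "DMRGResult", "run_dmrg", "warmup_mps",
           "dbss_truncate", "davidson"]

_SITE_Q = np.array(QNUMS, dtype=int)


@dataclass
class SweepConfig:
    tre_target: float = 1e-6
    m_min: int = 2
    m_max: int = 256
    max_sweeps: int = 12
    e_conv: float = 1e-8
    noise: tuple = (1e-3, 1e-4, 1e-4, 1e-5, 1e-6, 0.0)
    warmup: str = "determinant+noise"        # or "entropy-guided"
    ordering: list | None = None
    seed: int = 0
    davidson_tol_ratio: float = 1e-2
    davidson_max_iter: int = 100

    def __post_init__(self):
        if not (0.0 <= self.tre_target < 1.0):
            raise ValueError("tre_target must be in [0, 1)")
        if self.m_min > self.m_max:
            raise ValueError("m_min must not exceed m_max")
        if self.warmup not in ("determinant+noise", "entropy-guided"):
            raise ValueError(f"unknown warmup strategy {self.warmup!r}")


@dataclass
class DMRGResult:
    energy: float
    sweep_energies: list
    bond_dims: list
    discarded_weights: list          # (sweep, bond, m, weight, overrun_flag)
    entropies: np.ndarray
    mutual_information: np.ndarray
    one_rdm: np.ndarray
    mps: MPS
    converged: bool
    log_lines: list = field(default_factory=list)

    @property
    def max_bond_dim(self) -> int:
        return max(self.bond_dims) if self.bond_dims else 1

    def save(self, path):
        np.savez(path, energy=self.energy,
                 sweep_energies=np.array(self.sweep_energies),
                 bond_dims=np.array(self.bond_dims),
                 entropies=self.entropies,
                 mutual_information=self.mutual_information,
                 one_rdm=self.one_rdm)


# ------------------------------------------------------------------ davidson

def davidson(matvec, diag, x0, tol=1e-9, max_iter=100, max_space=16):
    """Lowest eigenpair of a symmetric operator; returns (e, x, niters, ok)."""
    x = x0 / np.linalg.norm(x0)
    V = [x]
    AV = [matvec(x)]
    u, theta = x, float(x @ AV[0])
    for it in range(max_iter):
        m = len(V)
        G = np.empty((m, m))
        for i in range(m):
            for j in range(i, m):
                G[i, j] = G[j, i] = V[i] @ AV[j]
        w, S = np.linalg.eigh(G)
        theta = w[0]
        y = S[:, 0]
        u = sum(c * v for c, v in zip(y, V))
        Au = sum(c * av for c, av in zip(y, AV))
        un = np.linalg.norm(u)
        u, Au = u / un, Au / un
        r = Au - theta * u
        if np.linalg.norm(r) < tol:
            return theta, u, it + 1, True
        if m >= max_space:
            V, AV = [u], [Au]
        denom = diag - theta
        denom = np.where(np.abs(denom) < 1e-8, 1e-8, denom)
        t = r / denom
        for v in V:
            t -= (v @ t) * v
        tn = np.linalg.norm(t)
        if tn < 1e-12:
            return theta, u, it + 1, True
        V.append(t / tn)
        AV.append(matvec(V[-1]))
    return theta, u, max_iter, False


# ------------------------------------------------------- effective H pieces

def _update_right_env(mpo: MPO, j, R, Abra, Aket):
    """R'[c, a_bra, a_ket] at bond j-1 from R at bond j."""
    Dr, Mb, Mk = R.shape
    ml_k = Aket.shape[0]
    T1 = np.tensordot(Aket, R, axes=([2], [2]))      # (a_l_ket, s_ket, c, b_bra)
    T1 = T1.transpose(2, 1, 0, 3).reshape(Dr * DIM, ml_k * Mb)
    T2 = mpo.csr_r[j] @ T1                           # (c_in*4_bra, a_l_ket*b_bra)
    Din = mpo.bond_dims[j]
    T2 = T2.reshape(Din, DIM, ml_k, Mb)
    out = np.tensordot(T2, Abra, axes=([1, 3], [1, 2]))   # (c, a_l_ket, a_l_bra)
    return np.transpose(out, (0, 2, 1))


def _matvec_two_site(mpo, j, L, R, x, Ml, Mr):
    """H_eff @ x for the two-site tensor at bond (j, j+1)."""
    Dl = L.shape[0]
    t = np.tensordot(L, x.reshape(Ml, DIM, DIM, Mr), axes=([2], [0]))
    t = t.transpose(0, 2, 1, 3, 4).reshape(Dl * DIM, -1)   # (cl*s1k | a,s2,mr)
    t = mpo.csr[j] @ t
    Dm = mpo.bond_dims[j + 1]
    t = t.reshape(Dm, DIM, Ml, DIM, Mr)              # (cm, s1_bra, a, s2_ket, mr)
    t = t.transpose(0, 3, 1, 2, 4).reshape(Dm * DIM, -1)
    t = mpo.csr[j + 1] @ t
    Dr = mpo.bond_dims[j + 2]
    t = t.reshape(Dr, DIM, DIM, Ml, Mr)              # (cr, s2_bra, s1_bra, a, mr_ket)
    y = np.tensordot(t, R, axes=([0, 4], [0, 2]))    # (s2, s1, a, b_bra)
    return y.transpose(2, 1, 0, 3).reshape(-1)


def _diag_two_site(mpo, j, L, R, Ml, Mr):
    Ld = np.einsum("caa->ca", L)
    Rd = np.einsum("caa->ca", R)
    Dm = mpo.bond_dims[j + 1]
    M1 = np.zeros((Dm, DIM, Ml))
    for (ci, co), mat in mpo.site_entries[j].items():
        d = np.diag(mat)
        if np.any(d):
            M1[co] += d[:, None] * Ld[ci][None, :]
    Dr2 = mpo.bond_dims[j + 2]
    M2 = np.zeros((Dr2, DIM, DIM, Ml))
    for (ci, co), mat in mpo.site_entries[j + 1].items():
        d = np.diag(mat)
        if np.any(d):
            M2[co] += d[:, None, None] * M1[ci][None, :, :]
    out = np.tensordot(M2, Rd, axes=([0], [0]))      # (s2, s1, a, b)
    return out.transpose(2, 1, 0, 3).reshape(-1)


# ------------------------------------------------------------- decimation

def dbss_truncate(theta, qL, qR, cfg: SweepConfig, rng=None,
                  noise: float = 0.0, gauge: str = "left",
                  enrich: np.ndarray | None = None):
    """Quantum-number-blocked SVD of a two-site tensor with DBSS rank choice.

    theta: (Ml, 4, 4, Mr); qL/qR: cumulative-left charges of the adjacent
    bonds.  ``gauge`` = "left": A orthonormal, B carries the weights;
    "right": the reverse.  ``enrich`` (typically H*theta) supplies the
    perturbative-noise direction so new symmetry sectors reachable through
    the Hamiltonian survive the decimation.  Returns (A, B, new_bond_q,
    discarded_weight, m_new, overrun_flag).
    """
    Ml, _, _, Mr = theta.shape
    if noise > 0.0:
        if enrich is not None:
            pert = enrich.reshape(theta.shape).copy()
            if rng is not None:
                pert += 0.1 * np.linalg.norm(pert) * \
                    rng.standard_normal(theta.shape)
        elif rng is not None:
            pert = rng.standard_normal(theta.shape)
        else:
            pert = np.zeros_like(theta)
        pert = _mask_sector(pert, qL, qR)
        pn = np.linalg.norm(pert)
        if pn > 0:
            theta = theta + noise * np.linalg.norm(theta) * pert / pn
    nrm = np.linalg.norm(theta)
    if nrm == 0:
        raise ValueError("zero two-site tensor")
    theta = theta / nrm
    row_q = (qL[:, None, :] + _SITE_Q[None, :, :]).reshape(Ml * DIM, 2)
    col_q = (qR[None, :, :] - _SITE_Q[:, None, :]).reshape(DIM * Mr, 2)
    mat = theta.reshape(Ml * DIM, DIM * Mr)
    blocks = []
    for c in np.unique(row_q, axis=0):
        rows = np.nonzero((row_q == c).all(axis=1))[0]
        cols = np.nonzero((col_q == c).all(axis=1))[0]
        if len(cols) == 0 or len(rows) == 0:
            continue
        sub = mat[np.ix_(rows, cols)]
        if not np.any(sub):
            continue
        U, s, Vt = np.linalg.svd(sub, full_matrices=False)
        for k in range(len(s)):
            blocks.append((s[k], c, rows, cols, U[:, k], Vt[k]))
    blocks.sort(key=lambda blk: -blk[0])
    w2 = np.array([blk[0] ** 2 for blk in blocks])
    total = float(w2.sum())
    disc_after = np.maximum(total - np.cumsum(w2), 0.0)  # keep m -> disc_after[m-1]
    m_new = int(np.searchsorted(-disc_after, -cfg.tre_target * total) + 1)
    m_new = min(max(m_new, cfg.m_min), len(blocks))
    overrun = False
    if m_new > cfg.m_max:
        m_new = cfg.m_max
        overrun = True
    kept = blocks[:m_new]
    discarded = float(disc_after[m_new - 1] / total)
    A = np.zeros((Ml * DIM, m_new))
    B = np.zeros((m_new, DIM * Mr))
    new_q = np.zeros((m_new, 2), dtype=int)
    snorm = np.sqrt(sum(blk[0] ** 2 for blk in kept))
    for k, (s, c, rows, cols, u, vt) in enumerate(kept):
        if gauge == "left":
            A[rows, k] = u
            B[k, cols] = s * vt / snorm
        else:
            A[rows, k] = s * u / snorm
            B[k, cols] = vt
        new_q[k] = c
    return (A.reshape(Ml, DIM, m_new), B.reshape(m_new, DIM, Mr),
            new_q, discarded, m_new, overrun)


def _mask_sector(theta, qL, qR):
    Ml, _, _, Mr = theta.shape
    row_q = (qL[:, None, :] + _SITE_Q[None, :, :])          # (Ml, 4, 2)
    col_q = (qR[None, :, :] - _SITE_Q[:, None, :])          # (4, Mr, 2)
    ok = (row_q[:, :, None, None, :] == col_q[None, None, :, :, :]).all(-1)
    return theta * ok


# ------------------------------------------------------------------ warm-up

def _fock_diagonal(ham, occ_idx):
    """Closed-shell Fock diagonal for a trial doubly-occupied set."""
    eri = ham.eri_pqrs
    f = np.diag(ham.h_pq).copy()
    for q in occ_idx:
        f += 2.0 * np.einsum("pp->p", eri[:, :, q, q]) - eri[:, q, q, :].diagonal()
    return f


def _mean_field_energy(ham, occ_idx):
    h, eri = ham.h_pq, ham.eri_pqrs
    e = 2.0 * sum(h[i, i] for i in occ_idx)
    for i in occ_idx:
        for j in occ_idx:
            e += 2.0 * eri[i, i, j, j] - eri[i, j, j, i]
    return e


def _aufbau_occupations(ham):
    """Doubly occupy the best closed-shell determinant among cheap candidates.

    Candidates: the first nelec/2 orbitals (exact for canonically ordered
    inputs), the lowest-h_pp set, and a greedy Fock-diagonal fixed point;
    the one with the lowest mean-field energy wins.
    """
    nocc = ham.nelec // 2
    candidates = [tuple(range(nocc))]
    order = np.argsort(np.diag(ham.h_pq), kind="stable")
    candidates.append(tuple(sorted(order[:nocc])))
    occ_idx = set(order[:nocc])
    for _ in range(8):
        f = _fock_diagonal(ham, sorted(occ_idx))
        new_idx = set(np.argsort(f, kind="stable")[:nocc])
        if new_idx == occ_idx:
            break
        occ_idx = new_idx
    candidates.append(tuple(sorted(occ_idx)))
    best = min(dict.fromkeys(candidates),
               key=lambda c: _mean_field_energy(ham, c))
    occ = np.zeros(ham.norb, dtype=int)
    occ[list(best)] = 3                             # doubly occupied
    return occ


def _site_entropy_estimates(ham):
    """Rough single-orbital entropies from the Hamiltonian diagonal."""
    eps = np.diag(ham.h_pq)
    nocc = ham.nelec // 2
    srt = np.sort(eps)
    mu = srt[max(nocc - 1, 0): nocc + 1].mean() if nocc < ham.norb else srt[-1]
    spread = max(np.ptp(eps) / 10.0, 1e-3)
    f = 1.0 / (1.0 + np.exp(np.abs(eps - mu) / spread))
    f = np.clip(f, 1e-6, 1 - 1e-6)
    return -(f * np.log(f) + (1 - f) * np.log(1 - f))


def warmup_mps(ham, cfg: SweepConfig, ordering=None) -> MPS:
    """Quantum-number-valid starting state with bond dims <= m_min."""
    occ = _aufbau_occupations(ham)
    if ordering is not None:
        occ = occ[np.asarray(ordering)]
    mps = product_state_mps(list(occ))
    mps.canonicalize(0)
    return mps


# ------------------------------------------------------------------ driver

class DavidsonBreakdown(RuntimeError):
    pass


def run_dmrg(ham, cfg: SweepConfig) -> DMRGResult:
    """Ground-state two-site DMRG for an ActiveHamiltonian."""
    from .observables import entropies_and_mutual_information, one_rdm

    norb = ham.norb
    if ham.nelec > 2 * norb:
        raise ValueError("more electrons than spin-orbitals")
    ordering = list(cfg.ordering) if cfg.ordering is not None \
        else list(range(norb))
    if sorted(ordering) != list(range(norb)):
        raise ValueError("ordering must be a permutation of range(norb)")
    mpo = build_mpo(ham, ordering)
    rng = np.random.default_rng(cfg.seed)
    log = []
    if norb == 1:
        return _run_single_site(ham, mpo, log)

    mps = warmup_mps(ham, cfg, ordering)
    ent_scale = None
    if cfg.warmup == "entropy-guided":
        ent = _site_entropy_estimates(ham)[np.asarray(ordering)]
        ent_scale = 0.25 + ent / max(float(ent.max()), 1e-12)

    # R_envs[j]: environment right of site j; valid for tensors j+1.. right-orthonormal
    R_envs = [None] * norb
    L_envs = [None] * norb
    R_envs[norb - 1] = mpo.right_boundary()[:, None, None].copy()
    for j in range(norb - 1, 0, -1):
        R_envs[j - 1] = _update_right_env(mpo, j, R_envs[j],
                                          mps.tensors[j], mps.tensors[j])
    L_envs[0] = mpo.left_boundary()[:, None, None].copy()

    sweep_energies = []
    discarded_log = []
    e_prev_sweep = None
    delta_last = 1e-3
    converged = False
    nrestart = 0

    for isweep in range(cfg.max_sweeps):
        noise = cfg.noise[min(isweep, len(cfg.noise) - 1)]
        e_sweep = np.inf
        for direction, bonds in (("->", range(norb - 1)),
                                 ("<-", range(norb - 2, -1, -1))):
            for b in bonds:
                L, R = L_envs[b], R_envs[b + 1]
                Ml = mps.tensors[b].shape[0]
                Mr = mps.tensors[b + 1].shape[2]
                theta0 = np.tensordot(mps.tensors[b], mps.tensors[b + 1],
                                      axes=([2], [0]))
                x0 = theta0.reshape(-1)
                diag = _diag_two_site(mpo, b, L, R, Ml, Mr)
                tol = float(np.clip(cfg.davidson_tol_ratio * abs(delta_last),
                                    1e-11, 1e-6))
                site_noise = noise if ent_scale is None or isweep > 0 \
                    else noise * ent_scale[b]
                try:
                    e, x, nit, ok = davidson(
                        lambda v: _matvec_two_site(mpo, b, L, R, v, Ml, Mr),
                        diag, x0, tol=tol, max_iter=cfg.davidson_max_iter)
                except np.linalg.LinAlgError:
                    nrestart += 1
                    if nrestart > 2:
                        raise DavidsonBreakdown(
                            f"local eigensolver failed twice near bond {b}")
                    site_noise = max(site_noise, 1e-3)
                    x = x0 / np.linalg.norm(x0)
                    e = float(x @ _matvec_two_site(mpo, b, L, R, x, Ml, Mr))
                e_sweep = min(e_sweep, e)
                theta = x.reshape(Ml, DIM, DIM, Mr)
                gauge = "left" if direction == "->" else "right"
                enrich = None
                if site_noise > 0.0:
                    enrich = _matvec_two_site(mpo, b, L, R, x, Ml, Mr)
                A, B, new_q, disc, m_new, overrun = dbss_truncate(
                    theta, mps.qnums[b], mps.qnums[b + 2], cfg,
                    rng=rng, noise=site_noise, gauge=gauge, enrich=enrich)
                discarded_log.append((isweep, b, m_new, disc, overrun))
                mps.tensors[b] = A
                mps.tensors[b + 1] = B
                mps.qnums[b + 1] = new_q
                if direction == "->":
                    mps.center = b + 1
                    L_envs[b + 1] = _update_left_env(mpo, b, L_envs[b], A, A)
                else:
                    mps.center = b
                    R_envs[b] = _update_right_env(mpo, b + 1, R_envs[b + 1], B, B)
                log.append(f"sweep {isweep} {direction} bond {b} m {m_new} "
                           f"disc {disc:.3e} E {e:.12f}")
        sweep_energies.append(e_sweep)
        if e_prev_sweep is not None:
            delta_last = e_sweep - e_prev_sweep
            if abs(delta_last) < cfg.e_conv and noise == 0.0:
                converged = True
                break
        e_prev_sweep = e_sweep
    mps.normalize()
    gamma = one_rdm(mps)
    inv = np.argsort(ordering)
    gamma = gamma[np.ix_(inv, inv)]
    s_i, I_ij = entropies_and_mutual_information(mps)
    s_i = s_i[inv]
    I_ij = I_ij[np.ix_(inv, inv)]
    return DMRGResult(
        energy=float(sweep_energies[-1] + ham.e_core),
        sweep_energies=[float(e + ham.e_core) for e in sweep_energies],
        bond_dims=list(mps.bond_dims),
        discarded_weights=discarded_log,
        entropies=s_i, mutual_information=I_ij, one_rdm=gamma,
        mps=mps, converged=converged, log_lines=log)


def _run_single_site(ham, mpo, log):
    from .observables import entropies_and_mutual_information, one_rdm

    H = mpo.to_dense()
    qn = np.array(QNUMS)
    idx = np.nonzero((qn[:, 0] == ham.nelec) & (qn[:, 1] == 0))[0]
    w, V = np.linalg.eigh(H[np.ix_(idx, idx)])
    vec = np.zeros(DIM)
    vec[idx] = V[:, 0]
    mps = MPS([vec.reshape(1, DIM, 1)],
              [np.zeros((1, 2), int), np.array([[ham.nelec, 0]])], center=0)
    gamma = one_rdm(mps)
    s_i, I_ij = entropies_and_mutual_information(mps)
    return DMRGResult(energy=float(w[0] + ham.e_core),
                      sweep_energies=[float(w[0] + ham.e_core)],
                      bond_dims=[], discarded_weights=[],
                      entropies=s_i, mutual_information=I_ij,
                      one_rdm=gamma, mps=mps, converged=True, log_lines=log)
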