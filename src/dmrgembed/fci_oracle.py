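"""Determinant-basis full CI in the S_z = 0 sector: the truth oracle.

Alpha/beta occupation strings are bit patterns over spatial orbitals;
the sigma vector is built from precomputed single-excitation coupling
lists (Slater–Condon rules), with doubles entering through the
spin-summed one-particle intermediate.  Clarity over speed — this is the
brute-force reference the MPS machinery is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.sparse.linalg import LinearOperator, eigsh

from .embedding import ActiveHamiltonian

__all__ = ["FCISolution", "fci_solve", "expectation", "FCISpace"]

MAX_DETERMINANTS = 2_000_000


def _strings(norb: int, ne: int) -> np.ndarray:
    out = []
    for occ in combinations(range(norb), ne):
        s = 0
        for p in occ:
            s |= 1 << p
        out.append(s)
    return np.array(sorted(out), dtype=np.int64)


def _excitation_table(strings: np.ndarray, norb: int):
    """All E_pq couplings within one spin channel.

    Returns arrays (bra_idx, ket_idx, p, q, sign) including diagonal
    p = q number operators.
    """
    index = {int(s): i for i, s in enumerate(strings)}
    bra, ket, ps, qs, sg = [], [], [], [], []
    for i, s in enumerate(strings):
        s = int(s)
        occ = [p for p in range(norb) if s >> p & 1]
        for q in occ:
            # diagonal
            bra.append(i); ket.append(i); ps.append(q); qs.append(q); sg.append(1.0)
            for p in range(norb):
                if s >> p & 1:
                    continue
                t = (s ^ (1 << q)) | (1 << p)
                j = index[t]
                lo, hi = (p, q) if p < q else (q, p)
                nbetween = bin(s >> (lo + 1) & ((1 << (hi - lo - 1)) - 1)).count("1")
                bra.append(j); ket.append(i); ps.append(p); qs.append(q)
                sg.append(-1.0 if nbetween % 2 else 1.0)
    return (np.array(bra), np.array(ket), np.array(ps), np.array(qs),
            np.array(sg))


class FCISpace:
    """Determinant space and sigma-vector machinery for one Hamiltonian."""

    def __init__(self, ham: ActiveHamiltonian):
        norb, nelec = ham.norb, ham.nelec
        if nelec % 2:
            raise ValueError("S_z = 0 sector requires an even electron count")
        na = nelec // 2
        ndet = _binom(norb, na) ** 2
        if ndet > MAX_DETERMINANTS:
            raise ValueError(
                f"determinant space {ndet} exceeds cap {MAX_DETERMINANTS}")
        self.ham = ham
        self.norb, self.na = norb, na
        self.strings = _strings(norb, na)
        self.nstr = len(self.strings)
        self.exc = _excitation_table(self.strings, norb)
        eri = ham.eri_pqrs
        # k_pq = h_pq - 1/2 sum_r (pr|rq): folds the E_pq E_rs contraction term
        self.k_eff = ham.h_pq - 0.5 * np.einsum("prrq->pq", eri)
        self.eri = eri

    # ---- spin-resolved one-particle operator application ----
    def _apply_epq_alpha(self, mats, c):
        """sum_pq mats[p,q] E^alpha_pq |c>, c shape (nstr, nstr)."""
        bra, ket, ps, qs, sg = self.exc
        w = mats[ps, qs] * sg
        out = np.zeros_like(c)
        np.add.at(out, bra, w[:, None] * c[ket])
        return out

    def _apply_epq_beta(self, mats, c):
        return self._apply_epq_alpha(mats, c.T).T

    def sigma(self, cvec: np.ndarray) -> np.ndarray:
        c = np.asarray(cvec, dtype=float).reshape(self.nstr, self.nstr)
        sig = self._apply_epq_alpha(self.k_eff, c)
        sig += self._apply_epq_beta(self.k_eff, c)
        # doubles: 1/2 sum_pq E_pq G_pq with G_pq = sum_rs (pq|rs) E_rs c
        bra, ket, ps, qs, sg = self.exc
        n = self.norb
        idx = ps * n + qs
        w = sg[:, None]
        # D[rs] = E_rs |c>, spin-summed
        D = np.zeros((n * n, self.nstr, self.nstr))
        np.add.at(D, (idx, bra), w * c[ket])                 # alpha rows
        Db = np.zeros((n * n, self.nstr, self.nstr))
        np.add.at(Db, (idx, bra), w * c.T[ket])              # beta on transpose
        D += Db.transpose(0, 2, 1)
        G = (self.eri.reshape(n * n, n * n) @ D.reshape(n * n, -1)
             ).reshape(n * n, self.nstr, self.nstr)
        acc = np.zeros_like(c)
        np.add.at(acc, bra, w * G[idx, ket, :])              # alpha application
        accb = np.zeros_like(c)
        Gt = G.transpose(0, 2, 1)
        np.add.at(accb, bra, w * Gt[idx, ket, :])            # beta application
        sig += 0.5 * (acc + accb.T)
        return sig.reshape(-1)

    def one_rdm(self, cvec: np.ndarray) -> np.ndarray:
        c = cvec.reshape(self.nstr, self.nstr)
        bra, ket, ps, qs, sg = self.exc
        n = self.norb
        g = np.zeros((n, n))
        # alpha: <c| E_pq |c> = sum over couplings sign * c[bra,:] . c[ket,:]
        ov = np.einsum("ei,ei->e", c[bra], c[ket])
        np.add.at(g, (ps, qs), sg * ov)
        ovb = np.einsum("ei,ei->e", c.T[bra], c.T[ket])
        np.add.at(g, (ps, qs), sg * ovb)
        return 0.5 * (g + g.T)

    def aufbau_vector(self) -> np.ndarray:
        s0 = 0
        for p in range(self.na):
            s0 |= 1 << p
        i0 = int(np.searchsorted(self.strings, s0))
        v = np.zeros(self.nstr * self.nstr)
        v[i0 * self.nstr + i0] = 1.0
        return v


def _binom(n, k):
    from math import comb
    return comb(n, k)


def _eye_rows(n):
    return np.eye(n)


def _scatter_rows(vals, rows, n):
    """(nexc, n) values -> (nexc, n, n) one-hot rows; memory-lean loop-free."""
    out = np.zeros((len(rows), n, n))
    out[np.arange(len(rows)), rows] = vals
    return out


@dataclass
class FCISolution:
    energy: float
    ci_vector: np.ndarray
    one_rdm: np.ndarray
    space: FCISpace


def fci_solve(ham: ActiveHamiltonian, tol: float = 1e-11) -> FCISolution:
    """Ground state of the active Hamiltonian (+ core constant)."""
    space = FCISpace(ham)
    ndet = space.nstr ** 2
    if ndet == 1:
        v = np.ones(1)
        e = float(v @ space.sigma(v))
        return FCISolution(e + ham.e_core, v, space.one_rdm(v), space)
    op = LinearOperator((ndet, ndet), matvec=space.sigma, dtype=float)
    # seeded dense start: overlaps every spin sector (an aufbau start would
    # confine the Krylov space to S = 0)
    v0 = space.aufbau_vector()
    v0 += 1e-3 * np.random.default_rng(12345).standard_normal(ndet)
    v0 /= np.linalg.norm(v0)
    w, V = eigsh(op, k=1, which="SA", v0=v0, tol=tol, maxiter=5000)
    vec = V[:, 0]
    if vec[np.argmax(np.abs(vec))] < 0:
        vec = -vec
    gamma = space.one_rdm(vec)
    # spin-summed convention: trace = nelec
    gamma *= ham.nelec / np.trace(gamma)
    return FCISolution(float(w[0]) + ham.e_core, vec, gamma, space)


def ci_to_occupation_tensor(space: FCISpace, ci_vector: np.ndarray) -> np.ndarray:
    """Map a determinant CI vector to the 4^n occupation tensor.

    Determinant convention: alpha creation operators (ascending orbital)
    then beta ones.  Tensor convention: site-major Jordan-Wigner order
    (orbital-0 up, orbital-0 down, orbital-1 up, ...), local states
    |0>, |dn>, |up>, |updn> with |updn> = c_up+ c_dn+ |0>.
    """
    n = space.norb
    c = np.asarray(ci_vector, float).reshape(space.nstr, space.nstr)
    out = np.zeros((4,) * n)
    for ia, sa in enumerate(space.strings):
        aocc = [p for p in range(n) if int(sa) >> p & 1]
        for ib, sb in enumerate(space.strings):
            bocc = [q for q in range(n) if int(sb) >> q & 1]
            # inversions from interleaving beta modes (2q+1) among alpha (2p)
            inv = sum(1 for q in bocc for p in aocc if p > q)
            sign = -1.0 if inv % 2 else 1.0
            idx = tuple((2 if p in aocc else 0) + (1 if p in bocc else 0)
                        for p in range(n))
            out[idx] = sign * c[ia, ib]
    return out


def expectation(ci_vector: np.ndarray, ham: ActiveHamiltonian,
                space: FCISpace | None = None) -> float:
    """<c|H|c> + e_core for a normalized vector."""
    if space is None:
        space = FCISpace(ham)
    n = np.linalg.norm(ci_vector)
    if abs(n - 1.0) > 1e-8:
        raise ValueError("ci_vector must be normalized")
    return float(ci_vector @ space.sigma(ci_vector)) + ham.e_core
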