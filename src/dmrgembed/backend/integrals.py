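"""McMurchie–Davidson Gaussian integrals (overlap, kinetic, nuclear, ERI).

Integrals are evaluated over contracted cartesian Gaussians in numba
kernels and transformed to real solid harmonics at the end.  Supports
s, p and d shells with general contraction — enough for the minimal,
split-valence and cc-pVDZ bases shipped with the package.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .basis import Shell, cart2sph_matrix, cartesian_components

__all__ = ["overlap", "kinetic", "nuclear_attraction", "eri_tensor", "cart_to_sph"]

_LMAX = 2


# ------------------------------------------------------------------ helpers

@njit(cache=True)
def _boys(mmax, T, out):
    """Boys function F_m(T) for m = 0..mmax via series + downward recursion."""
    if T < 1e-13:
        for m in range(mmax + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if T > 35.0:
        # asymptotic F_0, upward recursion is stable for large T
        out[0] = 0.5 * np.sqrt(np.pi / T)
        expT = np.exp(-T)
        for m in range(1, mmax + 1):
            out[m] = ((2 * m - 1) * out[m - 1] - expT) / (2.0 * T)
        return
    # series at m = mmax, then downward
    s = 1.0 / (2 * mmax + 1)
    term = s
    k = 1
    while True:
        term *= 2.0 * T / (2 * mmax + 2 * k + 1)
        s += term
        if term < 1e-17 * s or k > 200:
            break
        k += 1
    expT = np.exp(-T)
    out[mmax] = s * expT
    for m in range(mmax - 1, -1, -1):
        out[m] = (2.0 * T * out[m + 1] + expT) / (2 * m + 1)


@njit(cache=True)
def _hermite_e(i_max, j_max, a, b, AB, E):
    """Hermite expansion coefficients E[i, j, t] for a 1D Gaussian pair."""
    p = a + b
    q = a * b / p
    E[:, :, :] = 0.0
    E[0, 0, 0] = np.exp(-q * AB * AB)
    PA = -b * AB / p
    PB = a * AB / p
    for i in range(i_max + 1):
        for j in range(j_max + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    v = PA * E[i - 1, j, t]
                    if t > 0:
                        v += E[i - 1, j, t - 1] / (2 * p) * 1.0
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i - 1, j, t + 1]
                    E[i, j, t] = v
            else:
                for t in range(i + j + 1):
                    v = PB * E[i, j - 1, t]
                    if t > 0:
                        v += E[i, j - 1, t - 1] / (2 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v


@njit(cache=True)
def _hermite_r(Ltot, alpha, X, Y, Z, R):
    """Hermite Coulomb integrals R[t, u, v] (auxiliary index folded in)."""
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.empty(Ltot + 1)
    _boys(Ltot, T, F)
    # Rn[n, t, u, v] built by downward n-recursion
    n4 = Ltot + 1
    Rn = np.zeros((n4, n4, n4, n4))
    for n in range(Ltot + 1):
        Rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for total in range(1, Ltot + 1):
        for n in range(Ltot - total, -1, -1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if v > 0:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    Rn[n, t, u, v] = val
    R[:, :, :] = Rn[0, : Ltot + 1, : Ltot + 1, : Ltot + 1]


@njit(cache=True)
def _comp_table(l):
    n = (l + 1) * (l + 2) // 2
    out = np.empty((n, 3), dtype=np.int64)
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out[k, 0] = lx
            out[k, 1] = ly
            out[k, 2] = l - lx - ly
            k += 1
    return out


# ------------------------------------------------- one-electron, per pair

@njit(cache=True)
def _pair_1e(la, lb, ea, eb, ca, cb, A, B, atom_Z, atom_xyz, S, T, V):
    """Contracted cartesian S/T/V blocks for one shell pair.

    ca, cb: (nprim, nctr) coefficient tables.  Output blocks have shape
    (nctr_a*ncart_a, nctr_b*ncart_b).
    """
    ncta, nctb = ca.shape[1], cb.shape[1]
    compa = _comp_table(la)
    compb = _comp_table(lb)
    na, nb = compa.shape[0], compb.shape[0]
    Ltot = la + lb + 2
    Ex = np.zeros((la + 1, lb + 3, Ltot + 1))
    Ey = np.zeros((la + 1, lb + 3, Ltot + 1))
    Ez = np.zeros((la + 1, lb + 3, Ltot + 1))
    natm = atom_Z.shape[0]
    Rh = np.zeros((la + lb + 1, la + lb + 1, la + lb + 1))
    S[:, :] = 0.0
    T[:, :] = 0.0
    V[:, :] = 0.0
    for ia in range(ea.shape[0]):
        a = ea[ia]
        for ib in range(eb.shape[0]):
            b = eb[ib]
            p = a + b
            _hermite_e(la, lb + 2, a, b, A[0] - B[0], Ex)
            _hermite_e(la, lb + 2, a, b, A[1] - B[1], Ey)
            _hermite_e(la, lb + 2, a, b, A[2] - B[2], Ez)
            sfac = (np.pi / p) ** 1.5
            Px = (a * A[0] + b * B[0]) / p
            Py = (a * A[1] + b * B[1]) / p
            Pz = (a * A[2] + b * B[2]) / p
            # nuclear attraction needs Hermite sums per atom
            for ka in range(na):
                ax, ay, az = compa[ka, 0], compa[ka, 1], compa[ka, 2]
                for kb in range(nb):
                    bx, by, bz = compb[kb, 0], compb[kb, 1], compb[kb, 2]
                    s1 = Ex[ax, bx, 0] * Ey[ay, by, 0] * Ez[az, bz, 0] * sfac
                    # kinetic via 1D relations on the b index
                    tx = -2.0 * b * b * Ex[ax, bx + 2, 0] + b * (2 * bx + 1) * Ex[ax, bx, 0]
                    if bx >= 2:
                        tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                    ty = -2.0 * b * b * Ey[ay, by + 2, 0] + b * (2 * by + 1) * Ey[ay, by, 0]
                    if by >= 2:
                        ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                    tz = -2.0 * b * b * Ez[az, bz + 2, 0] + b * (2 * bz + 1) * Ez[az, bz, 0]
                    if bz >= 2:
                        tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                    t1 = (tx * Ey[ay, by, 0] * Ez[az, bz, 0]
                          + Ex[ax, bx, 0] * ty * Ez[az, bz, 0]
                          + Ex[ax, bx, 0] * Ey[ay, by, 0] * tz) * sfac
                    # nuclear
                    v1 = 0.0
                    for iat in range(natm):
                        _hermite_r(ax + bx + ay + by + az + bz, p,
                                   Px - atom_xyz[iat, 0], Py - atom_xyz[iat, 1],
                                   Pz - atom_xyz[iat, 2], Rh)
                        acc = 0.0
                        for t in range(ax + bx + 1):
                            for u in range(ay + by + 1):
                                for v in range(az + bz + 1):
                                    acc += (Ex[ax, bx, t] * Ey[ay, by, u]
                                            * Ez[az, bz, v] * Rh[t, u, v])
                        v1 -= atom_Z[iat] * acc
                    v1 *= 2.0 * np.pi / p
                    for cai in range(ncta):
                        for cbi in range(nctb):
                            w = ca[ia, cai] * cb[ib, cbi]
                            r = cai * na + ka
                            c = cbi * nb + kb
                            S[r, c] += w * s1
                            T[r, c] += w * t1
                            V[r, c] += w * v1


# --------------------------------------------------------------- ERI kernel

@njit(cache=True)
def _pair_hermite_tables(la, lb, ea, eb, A, B):
    """Per-primitive-pair Hermite E product tables for a shell pair.

    Returns (ptab, Btab): ptab[np_] = (p, Px, Py, Pz); Btab[np_, c12, tuv]
    flattened over tuv with stride (L+1).
    """
    compa = _comp_table(la)
    compb = _comp_table(lb)
    na, nb = compa.shape[0], compb.shape[0]
    L = la + lb
    npair = ea.shape[0] * eb.shape[0]
    ptab = np.empty((npair, 4))
    Btab = np.zeros((npair, na * nb, (L + 1) ** 3))
    Ex = np.zeros((la + 1, lb + 1, L + 1))
    Ey = np.zeros((la + 1, lb + 1, L + 1))
    Ez = np.zeros((la + 1, lb + 1, L + 1))
    k = 0
    for ia in range(ea.shape[0]):
        a = ea[ia]
        for ib in range(eb.shape[0]):
            b = eb[ib]
            p = a + b
            _hermite_e(la, lb, a, b, A[0] - B[0], Ex)
            _hermite_e(la, lb, a, b, A[1] - B[1], Ey)
            _hermite_e(la, lb, a, b, A[2] - B[2], Ez)
            ptab[k, 0] = p
            ptab[k, 1] = (a * A[0] + b * B[0]) / p
            ptab[k, 2] = (a * A[1] + b * B[1]) / p
            ptab[k, 3] = (a * A[2] + b * B[2]) / p
            for ka in range(na):
                ax, ay, az = compa[ka, 0], compa[ka, 1], compa[ka, 2]
                for kb in range(nb):
                    bx, by, bz = compb[kb, 0], compb[kb, 1], compb[kb, 2]
                    c12 = ka * nb + kb
                    for t in range(ax + bx + 1):
                        for u in range(ay + by + 1):
                            for v in range(az + bz + 1):
                                Btab[k, c12, (t * (L + 1) + u) * (L + 1) + v] = (
                                    Ex[ax, bx, t] * Ey[ay, by, u] * Ez[az, bz, v])
            k += 1
    return ptab, Btab


@njit(cache=True)
def _eri_quartet(L12, L34, p12, B12, p34, B34, w12, w34, out):
    """Contracted cartesian ERI block for a (bra pair, ket pair) quartet.

    w12[np12, nc12], w34[np34, nc34]: contraction weight tables (products of
    primitive coefficients).  out[nc12, c12cart, nc34, c34cart].
    """
    n12 = B12.shape[1]
    n34 = B34.shape[1]
    Ltot = L12 + L34
    Rh = np.zeros((Ltot + 1, Ltot + 1, Ltot + 1))
    s12 = L12 + 1
    s34 = L34 + 1
    nc12 = w12.shape[1]
    nc34 = w34.shape[1]
    tmp = np.zeros((n12, n34))
    for k1 in range(p12.shape[0]):
        p = p12[k1, 0]
        for k2 in range(p34.shape[0]):
            q = p34[k2, 0]
            alpha = p * q / (p + q)
            _hermite_r(Ltot, alpha,
                       p12[k1, 1] - p34[k2, 1],
                       p12[k1, 2] - p34[k2, 2],
                       p12[k1, 3] - p34[k2, 3], Rh)
            pref = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
            for c1 in range(n12):
                for c2 in range(n34):
                    acc = 0.0
                    for t in range(s12):
                        for u in range(s12):
                            for v in range(s12):
                                b1 = B12[k1, c1, (t * s12 + u) * s12 + v]
                                if b1 == 0.0:
                                    continue
                                for tp in range(s34):
                                    for up in range(s34):
                                        for vp in range(s34):
                                            b2 = B34[k2, c2, (tp * s34 + up) * s34 + vp]
                                            if b2 == 0.0:
                                                continue
                                            sgn = 1.0 if (tp + up + vp) % 2 == 0 else -1.0
                                            acc += b1 * b2 * sgn * Rh[t + tp, u + up, v + vp]
                    tmp[c1, c2] = acc * pref
            for i1 in range(nc12):
                for i2 in range(nc34):
                    w = w12[k1, i1] * w34[k2, i2]
                    if w == 0.0:
                        continue
                    for c1 in range(n12):
                        for c2 in range(n34):
                            out[i1, c1, i2, c2] += w * tmp[c1, c2]


# ------------------------------------------------------------- public API

def _cart_layout(shells: list[Shell]):
    offs = []
    n = 0
    for sh in shells:
        offs.append(n)
        n += sh.nctr * sh.ncart
    return offs, n


def cart_to_sph(shells: list[Shell]) -> np.ndarray:
    """Block-diagonal (ncart_total, nsph_total) transform."""
    offs, ncart = _cart_layout(shells)
    nsph = sum(sh.nctr * sh.nsph for sh in shells)
    Tm = np.zeros((ncart, nsph))
    r = c = 0
    for sh in shells:
        blk = cart2sph_matrix(sh.l)
        for _ in range(sh.nctr):
            Tm[r:r + sh.ncart, c:c + sh.nsph] = blk
            r += sh.ncart
            c += sh.nsph
    return Tm


def _one_electron(shells: list[Shell], atom_Z: np.ndarray, atom_xyz: np.ndarray):
    offs, ncart = _cart_layout(shells)
    S = np.zeros((ncart, ncart))
    T = np.zeros((ncart, ncart))
    V = np.zeros((ncart, ncart))
    for i, shi in enumerate(shells):
        for j, shj in enumerate(shells):
            if j > i:
                continue
            ni = shi.nctr * shi.ncart
            nj = shj.nctr * shj.ncart
            Sb = np.zeros((ni, nj))
            Tb = np.zeros((ni, nj))
            Vb = np.zeros((ni, nj))
            _pair_1e(shi.l, shj.l, shi.exps, shj.exps, shi.coefs, shj.coefs,
                     shi.center, shj.center, atom_Z, atom_xyz, Sb, Tb, Vb)
            S[offs[i]:offs[i] + ni, offs[j]:offs[j] + nj] = Sb
            T[offs[i]:offs[i] + ni, offs[j]:offs[j] + nj] = Tb
            V[offs[i]:offs[i] + ni, offs[j]:offs[j] + nj] = Vb
            if i != j:
                S[offs[j]:offs[j] + nj, offs[i]:offs[i] + ni] = Sb.T
                T[offs[j]:offs[j] + nj, offs[i]:offs[i] + ni] = Tb.T
                V[offs[j]:offs[j] + nj, offs[i]:offs[i] + ni] = Vb.T
    return S, T, V


def overlap(shells, atom_Z, atom_xyz):
    S, _, _ = one_electron_cart_cached(shells, atom_Z, atom_xyz)
    Tm = cart_to_sph(shells)
    return Tm.T @ S @ Tm


def kinetic(shells, atom_Z, atom_xyz):
    _, T, _ = one_electron_cart_cached(shells, atom_Z, atom_xyz)
    Tm = cart_to_sph(shells)
    return Tm.T @ T @ Tm


def nuclear_attraction(shells, atom_Z, atom_xyz):
    _, _, V = one_electron_cart_cached(shells, atom_Z, atom_xyz)
    Tm = cart_to_sph(shells)
    return Tm.T @ V @ Tm


_one_e_cache: dict = {}


def one_electron_cart_cached(shells, atom_Z, atom_xyz):
    key = id(shells)
    hit = _one_e_cache.get(key)
    if hit is None:
        hit = _one_electron(shells, np.asarray(atom_Z, float), np.asarray(atom_xyz, float))
        _one_e_cache.clear()          # hold at most one system
        _one_e_cache[key] = hit
    return hit


def eri_tensor(shells: list[Shell]) -> np.ndarray:
    """Full spherical-AO ERI tensor in chemist notation (pq|rs)."""
    offs, ncart = _cart_layout(shells)
    nsh = len(shells)
    # per-pair Hermite tables (i >= j)
    pair_idx = {}
    tables = []
    for i in range(nsh):
        for j in range(i + 1):
            ptab, Btab = _pair_hermite_tables(
                shells[i].l, shells[j].l, shells[i].exps, shells[j].exps,
                shells[i].center, shells[j].center)
            ni, nj = shells[i].nprim, shells[j].nprim
            w = np.einsum("pa,qb->pqab", shells[i].coefs, shells[j].coefs)
            w = w.reshape(ni * nj, -1)
            pair_idx[(i, j)] = len(tables)
            tables.append((ptab, Btab, w))
    G = np.zeros((ncart, ncart, ncart, ncart))
    for i in range(nsh):
        for j in range(i + 1):
            t12 = tables[pair_idx[(i, j)]]
            L12 = shells[i].l + shells[j].l
            for k in range(i + 1):
                lmax = k if k < i else j
                for l in range(k + 1):
                    if k == i and l > j:
                        continue
                    t34 = tables[pair_idx[(k, l)]]
                    L34 = shells[k].l + shells[l].l
                    nc12 = shells[i].nctr * shells[j].nctr
                    nc34 = shells[k].nctr * shells[l].nctr
                    n12 = shells[i].ncart * shells[j].ncart
                    n34 = shells[k].ncart * shells[l].ncart
                    out = np.zeros((nc12, n12, nc34, n34))
                    _eri_quartet(L12, L34, t12[0], t12[1], t34[0], t34[1],
                                 t12[2], t34[2], out)
                    _scatter_quartet(G, out, shells, offs, i, j, k, l)
    Tm = cart_to_sph(shells)
    G = np.tensordot(G, Tm, axes=([3], [0]))
    G = np.tensordot(G, Tm, axes=([2], [0]))
    G = np.tensordot(G, Tm, axes=([1], [0]))
    G = np.tensordot(G, Tm, axes=([0], [0]))
    return np.ascontiguousarray(G.transpose(3, 2, 1, 0))


def _scatter_quartet(G, out, shells, offs, i, j, k, l):
    """Write a contracted cartesian quartet block into G with 8-fold symmetry."""
    shi, shj, shk, shl = shells[i], shells[j], shells[k], shells[l]
    blk = out.reshape(shi.nctr, shj.nctr, shi.ncart, shj.ncart,
                      shk.nctr, shl.nctr, shk.ncart, shl.ncart)
    blk = blk.transpose(0, 2, 1, 3, 4, 6, 5, 7).reshape(
        shi.nctr * shi.ncart, shj.nctr * shj.ncart,
        shk.nctr * shk.ncart, shl.nctr * shl.ncart)
    oi, oj, ok, ol = offs[i], offs[j], offs[k], offs[l]
    ni, nj, nk, nl = blk.shape
    si, sj, sk, sl = slice(oi, oi + ni), slice(oj, oj + nj), slice(ok, ok + nk), slice(ol, ol + nl)
    G[si, sj, sk, sl] = blk
    G[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
    G[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
    G[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
    G[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
    G[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
    G[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
    G[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
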