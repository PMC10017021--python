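"""Brute-force dense oracles shared by the MPS/MPO/FCI tests."""

import numpy as np

from dmrgembed.dmrg.local_ops import C_DAG, I4, P, QNUMS


def kron_chain(mats):
    out = np.array([[1.0]])
    for m in mats:
        out = np.kron(out, m)
    return out


def dense_jw_hamiltonian(norb: int, h: np.ndarray, eri: np.ndarray) -> np.ndarray:
    """4^n x 4^n Hamiltonian built from Jordan-Wigner strings.

    Site-major mode order, parity strings to the left; eri in chemist
    notation (pq|rs).
    """
    cdag = {}
    for site in range(norb):
        for spin in (0, 1):
            cdag[(site, spin)] = kron_chain(
                [P] * site + [C_DAG[spin]] + [I4] * (norb - site - 1))
    dim = 4 ** norb
    H = np.zeros((dim, dim))
    for p in range(norb):
        for q in range(norb):
            for s1 in (0, 1):
                H += h[p, q] * cdag[(p, s1)] @ cdag[(q, s1)].T
    for p in range(norb):
        for q in range(norb):
            for r in range(norb):
                for s in range(norb):
                    v = eri[p, r, q, s]
                    if v == 0.0:
                        continue
                    for s1 in (0, 1):
                        for s2 in (0, 1):
                            H += 0.5 * v * (cdag[(p, s1)] @ cdag[(q, s2)]
                                            @ cdag[(s, s2)].T @ cdag[(r, s1)].T)
    return H


def sector_indices(norb: int, nelec: int, sz2: int = 0) -> np.ndarray:
    """Flat occupation-basis indices of the (N, 2Sz) sector."""
    qn = np.array(QNUMS, dtype=int)
    states = np.indices((4,) * norb).reshape(norb, -1).T
    N = qn[states, 0].sum(axis=1)
    Sz = qn[states, 1].sum(axis=1)
    return np.nonzero((N == nelec) & (Sz == sz2))[0]


def dense_ground_state(ham):
    """(energy, 4^n ground vector) of an ActiveHamiltonian, by full diag."""
    H = dense_jw_hamiltonian(ham.norb, ham.h_pq, ham.eri_pqrs)
    idx = sector_indices(ham.norb, ham.nelec)
    w, V = np.linalg.eigh(H[np.ix_(idx, idx)])
    vec = np.zeros(4 ** ham.norb)
    vec[idx] = V[:, 0]
    return w[0] + ham.e_core, vec
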