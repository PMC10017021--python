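"""1-RDM, entropies, mutual information, Fiedler ordering."""

import numpy as np
import pytest

from dmrgembed.dmrg import (SweepConfig, entropies_and_mutual_information,
                            fiedler_ordering, one_rdm, run_dmrg,
                            two_orbital_rdm)
from dmrgembed.dmrg.mps import mps_from_dense, product_state_mps
from dmrgembed.fci_oracle import ci_to_occupation_tensor, fci_solve


# ---------------------------------------------------------------- one_rdm

def test_single_determinant_occupations():
    mps = product_state_mps([3, 3, 0, 0])
    gamma = one_rdm(mps)
    assert np.allclose(np.diag(gamma), [2, 2, 0, 0], atol=1e-12)
    assert np.abs(gamma - np.diag(np.diag(gamma))).max() < 1e-12


def test_h2_dissociation_natural_occupations(h2_stretched_ham):
    res = run_dmrg(h2_stretched_ham, SweepConfig(m_max=8, max_sweeps=8, seed=1))
    occ = np.linalg.eigvalsh(res.one_rdm)
    assert abs(occ[0] - 1.0) < 0.05
    assert abs(occ[1] - 1.0) < 0.05


def test_one_rdm_matches_fci_on_h4(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=64, max_sweeps=10, seed=1,
                                       tre_target=1e-10))
    sol = fci_solve(h4_ham)
    assert np.abs(res.one_rdm - sol.one_rdm).max() < 1e-7


def test_one_rdm_basic_invariants(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=32, max_sweeps=6, seed=1))
    g = res.one_rdm
    assert np.abs(g - g.T).max() < 1e-10
    assert np.trace(g) == pytest.approx(h4_ham.nelec, abs=1e-8)
    ev = np.linalg.eigvalsh(g)
    assert ev.min() > -1e-8 and ev.max() < 2 + 1e-8


# ----------------------------------------------- entropies / mutual info

def test_product_state_entropies_vanish():
    mps = product_state_mps([3, 0, 3])
    s, I = entropies_and_mutual_information(mps)
    assert np.abs(s).max() < 1e-12
    assert np.abs(I).max() < 1e-12


def test_h2_dissociation_mutual_information(h2_stretched_ham):
    res = run_dmrg(h2_stretched_ham, SweepConfig(m_max=8, max_sweeps=8, seed=1))
    # two maximally entangled sigma orbitals
    assert res.mutual_information[0, 1] > 1.0
    assert res.entropies[0] > 0.6


def test_mutual_information_symmetric_nonnegative(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=32, max_sweeps=8, seed=1))
    I = res.mutual_information
    assert np.abs(I - I.T).max() < 1e-10
    assert I.min() >= -1e-10


def test_entropy_subadditivity_on_h4(h4_ham):
    """Sum of single-orbital entropies bounds any bipartition entropy."""
    sol = fci_solve(h4_ham)
    psi = ci_to_occupation_tensor(sol.space, sol.ci_vector)
    mps, _ = mps_from_dense(psi)
    s, _ = entropies_and_mutual_information(mps)
    for cut in (1, 2, 3):
        mat = psi.reshape(4 ** cut, -1)
        lam = np.linalg.svd(mat, compute_uv=False) ** 2
        lam = lam[lam > 1e-14]
        s_cut = float(-(lam * np.log(lam)).sum())
        assert s.sum() >= s_cut - 1e-8


def test_two_orbital_rdm_against_dense_partial_trace(rng):
    """Oracle: dense mode-reordering partial trace on a random state."""
    n = 4
    psi = rng.standard_normal((4,) * n)
    psi /= np.linalg.norm(psi)
    mps, _ = mps_from_dense(psi)
    occ_modes = {0: (0, 0), 1: (0, 1), 2: (1, 0), 3: (1, 1)}

    def oracle(i, j):
        acc = {}
        idx = np.indices((4,) * n).reshape(n, -1).T
        amp = psi.reshape(-1)
        for k, states in enumerate(idx):
            modes = []
            for s_ix, st in enumerate(states):
                nu, nd = occ_modes[st]
                if nu:
                    modes.append(2 * s_ix)
                if nd:
                    modes.append(2 * s_ix + 1)
            front = [m for m in modes if m // 2 in (i, j)]
            front.sort(key=lambda m: ((0 if m // 2 == i else 1), m % 2))
            rest = [m for m in modes if m // 2 not in (i, j)]
            perm = [modes.index(m) for m in front + rest]
            sign = 1
            seen = [False] * len(perm)
            for s0 in range(len(perm)):
                if seen[s0]:
                    continue
                clen, x = 0, s0
                while not seen[x]:
                    seen[x] = True
                    x = perm[x]
                    clen += 1
                if clen % 2 == 0:
                    sign = -sign
            key = tuple(st for s_ix, st in enumerate(states)
                        if s_ix not in (i, j))
            acc.setdefault(key, np.zeros(16))[4 * states[i] + states[j]] += \
                sign * amp[k]
        rho = np.zeros((16, 16))
        for v in acc.values():
            rho += np.outer(v, v)
        return rho

    for (i, j) in [(0, 1), (0, 3), (1, 2), (2, 3)]:
        assert np.abs(two_orbital_rdm(mps, i, j) - oracle(i, j)).max() < 1e-12


# --------------------------------------------------------------- fiedler

def test_fiedler_zero_matrix_identity():
    assert fiedler_ordering(np.zeros((5, 5))) == [0, 1, 2, 3, 4]


def test_fiedler_recovers_shuffled_chain(rng):
    n = 7
    chain = np.zeros((n, n))
    for i in range(n - 1):
        chain[i, i + 1] = chain[i + 1, i] = 1.0
    perm = rng.permutation(n)
    shuffled = chain[np.ix_(perm, perm)]
    order = fiedler_ordering(shuffled)
    # order maps shuffled labels back to a path: perm[order] is the chain
    recovered = [int(perm[k]) for k in order]
    assert recovered == list(range(n)) or recovered == list(range(n))[::-1]


def test_fiedler_keeps_blocks_contiguous():
    I = np.zeros((6, 6))
    for (a, b) in [(0, 2), (2, 4), (0, 4)]:
        I[a, b] = I[b, a] = 1.0
    for (a, b) in [(1, 3), (3, 5), (1, 5)]:
        I[a, b] = I[b, a] = 0.5
    order = fiedler_ordering(I)
    pos = {v: k for k, v in enumerate(order)}
    blk1 = sorted(pos[v] for v in (0, 2, 4))
    blk2 = sorted(pos[v] for v in (1, 3, 5))
    assert blk1 == list(range(blk1[0], blk1[0] + 3))
    assert blk2 == list(range(blk2[0], blk2[0] + 3))


def test_fiedler_rejects_bad_input():
    with pytest.raises(ValueError):
        fiedler_ordering(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        fiedler_ordering(-np.ones((3, 3)))
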