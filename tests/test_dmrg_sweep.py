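"""Two-site sweeps: DBSS, warm-up, convergence to the FCI oracle."""

import numpy as np
import pytest

from dmrgembed.dmrg import SweepConfig, dbss_truncate, run_dmrg, warmup_mps
from dmrgembed.dmrg.local_ops import QNUMS
from dmrgembed.dmrg.mps import mps_from_dense
from dmrgembed.fci_oracle import ci_to_occupation_tensor, fci_solve


def _theta_with_schmidt(weights, rng):
    """Two-site tensor with a prescribed Schmidt spectrum in one charge block.

    Bond dims 4/4 with uniform labels; the spectrum lives in the
    (s1= up, s2= dn) slice so row and column charges match.  Returns
    (theta, qL, qR).
    """
    U = np.linalg.qr(rng.standard_normal((4, 4)))[0]
    V = np.linalg.qr(rng.standard_normal((4, 4)))[0]
    lam = np.sqrt(np.array(weights))
    mat = U @ np.diag(lam) @ V.T
    theta = np.zeros((4, 4, 4, 4))
    theta[:, 2, 1, :] = mat                      # |up> then |dn>: charge (2,0)
    qL = np.zeros((4, 2), dtype=int)
    qR = np.tile([[2, 0]], (4, 1))
    return theta, qL, qR


def test_dbss_zero_tre_keeps_full_rank(rng):
    theta, qL, qR = _theta_with_schmidt([0.4, 0.3, 0.2, 0.1], rng)
    cfg = SweepConfig(tre_target=0.0, m_min=1, m_max=64)
    A, B, q, disc, m, over = dbss_truncate(theta, qL, qR, cfg)
    assert disc == pytest.approx(0.0, abs=1e-12)
    assert not over


def test_dbss_hand_built_spectrum(rng):
    """Schmidt weights {0.6, 0.3, 0.09, 0.01}, TRE 0.05 -> keep 3, drop 0.01."""
    theta, qL, qR = _theta_with_schmidt([0.6, 0.3, 0.09, 0.01], rng)
    cfg = SweepConfig(tre_target=0.05, m_min=1, m_max=64)
    A, B, q, disc, m, over = dbss_truncate(theta, qL, qR, cfg)
    assert m == 3
    assert disc == pytest.approx(0.01, abs=1e-10)
    assert not over


def test_dbss_discard_equals_one_minus_kept(rng):
    theta, qL, qR = _theta_with_schmidt([0.5, 0.25, 0.15, 0.1], rng)
    cfg = SweepConfig(tre_target=0.2, m_min=1, m_max=64)
    A, B, q, disc, m, over = dbss_truncate(theta, qL, qR, cfg)
    # discarded weight = 1 - sum of kept normalized weights
    kept = [0.5, 0.25, 0.15, 0.1][:m]
    assert disc == pytest.approx(1.0 - sum(kept), abs=1e-12)


def test_dbss_overrun_flag(rng):
    theta, qL, qR = _theta_with_schmidt([0.4, 0.3, 0.2, 0.1], rng)
    cfg = SweepConfig(tre_target=1e-12, m_min=1, m_max=2)
    *_, disc, m, over = dbss_truncate(theta, qL, qR, cfg)
    assert m == 2 and over and disc > cfg.tre_target


def test_warmup_determinism(h4_ham):
    cfg = SweepConfig(seed=7)
    a = warmup_mps(h4_ham, cfg)
    b = warmup_mps(h4_ham, cfg)
    for ta, tb in zip(a.tensors, b.tensors):
        assert np.array_equal(ta, tb)


def test_warmup_aufbau_overlap_with_fci(h2_ham):
    sol = fci_solve(h2_ham)
    psi = ci_to_occupation_tensor(sol.space, sol.ci_vector)
    mps = warmup_mps(h2_ham, SweepConfig())
    ref, _ = mps_from_dense(psi)
    ov = abs(mps.overlap(ref))
    assert ov > 0.9


def test_warmup_strategies_reach_same_energy(h4_ham):
    e = {}
    for strat in ("determinant+noise", "entropy-guided"):
        cfg = SweepConfig(m_max=32, max_sweeps=10, warmup=strat, seed=3,
                          tre_target=1e-10)
        e[strat] = run_dmrg(h4_ham, cfg).energy
    assert e["determinant+noise"] == pytest.approx(
        e["entropy-guided"], abs=1e-7)


def test_h2_dmrg_matches_fci(h2_ham):
    res = run_dmrg(h2_ham, SweepConfig(m_max=16, max_sweeps=8, seed=1))
    assert res.energy == pytest.approx(fci_solve(h2_ham).energy, abs=1e-8)


def test_h4_dmrg_matches_fci(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=64, max_sweeps=10, seed=1,
                                       tre_target=1e-10))
    sol = fci_solve(h4_ham)
    assert res.energy == pytest.approx(sol.energy, abs=1e-7)
    assert np.abs(res.one_rdm - sol.one_rdm).max() < 1e-6


def test_variational_bound_and_monotone_convergence(h4_ham):
    sol = fci_solve(h4_ham)
    gaps = []
    for m in (2, 4, 8, 16):
        res = run_dmrg(h4_ham, SweepConfig(m_max=m, max_sweeps=8, seed=1,
                                           tre_target=1e-12))
        gap = res.energy - sol.energy
        assert gap >= -1e-9            # variational
        gaps.append(max(gap, 1e-12))
    assert gaps[-1] <= gaps[0]
    assert gaps[-1] < 1e-6


def test_sweep_energy_non_increasing(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=32, max_sweeps=8, seed=1,
                                       tre_target=1e-10))
    e = res.sweep_energies
    for a, b in zip(e, e[1:]):
        assert b <= a + 1e-8


def test_seeded_determinism(h4_ham):
    cfg = dict(m_max=16, max_sweeps=6, seed=11, tre_target=1e-8)
    r1 = run_dmrg(h4_ham, SweepConfig(**cfg))
    r2 = run_dmrg(h4_ham, SweepConfig(**cfg))
    assert r1.sweep_energies == r2.sweep_energies
    assert r1.log_lines == r2.log_lines


def test_dbss_contract_every_decimation(h4_ham):
    cfg = SweepConfig(m_max=64, max_sweeps=8, seed=1, tre_target=1e-9)
    res = run_dmrg(h4_ham, cfg)
    assert res.discarded_weights
    for (sweep, bond, m, disc, overrun) in res.discarded_weights:
        if not overrun:
            # noise perturbs theta before decimation; allow its scale on
            # noisy sweeps, exact contract once noise is off
            noise = cfg.noise[min(sweep, len(cfg.noise) - 1)]
            assert disc <= cfg.tre_target + 10 * noise ** 2 + 1e-12


def test_quantum_number_conservation(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=32, max_sweeps=6, seed=1))
    mps = res.mps
    # final bond carries (nelec, 0)
    assert tuple(mps.qnums[-1][0]) == (h4_ham.nelec, 0)
    # every bond label consistent with a cumulative site-charge path
    for j, t in enumerate(mps.tensors):
        qL, qR = mps.qnums[j], mps.qnums[j + 1]
        site_q = np.array(QNUMS)
        for l in range(t.shape[0]):
            for s in range(4):
                for r in range(t.shape[2]):
                    if abs(t[l, s, r]) > 1e-10:
                        assert np.array_equal(qL[l] + site_q[s], qR[r])


def test_canonical_form_after_sweeps(h4_ham):
    res = run_dmrg(h4_ham, SweepConfig(m_max=32, max_sweeps=6, seed=1))
    errs = res.mps.orthonormality_errors()
    assert all(e < 1e-10 for e in errs)


def test_single_orbital_edge_case():
    from dmrgembed.embedding import ActiveHamiltonian

    ham = ActiveHamiltonian(1, 2, np.array([[-0.5]]),
                            np.full((1, 1, 1, 1), 0.2), e_core=1.0)
    res = run_dmrg(ham, SweepConfig())
    assert res.energy == pytest.approx(2 * (-0.5) + 0.2 + 1.0, abs=1e-12)


def test_too_many_electrons_rejected(h2_ham):
    import dataclasses

    bad = dataclasses.replace(h2_ham, nelec=6)
    with pytest.raises(ValueError):
        run_dmrg(bad, SweepConfig())


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SweepConfig(tre_target=1.5)
    with pytest.raises(ValueError):
        SweepConfig(m_min=10, m_max=2)
    with pytest.raises(ValueError):
        SweepConfig(warmup="nope")
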