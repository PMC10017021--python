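"""Shared fixtures: small systems are expensive enough to cache per session."""

from __future__ import annotations

import numpy as np
import pytest

from dmrgembed import embedding as emb
from dmrgembed.backend import build_system
from dmrgembed.backend.scf import run_mean_field
from dmrgembed.io_cli import fixtures as fx
from dmrgembed.partition import build_partition


@pytest.fixture(scope="session")
def h2_eq():
    system = build_system(fx.h_chain(2, 0.74), "sto-3g")
    mf = run_mean_field(system, "hf")
    return system, mf


@pytest.fixture(scope="session")
def h2_stretched():
    system = build_system(fx.h_chain(2, 5.0), "sto-3g")
    mf = run_mean_field(system, "hf")
    return system, mf


@pytest.fixture(scope="session")
def h4_chain():
    system = build_system(fx.h_chain(4, 1.0), "sto-3g")
    mf = run_mean_field(system, "hf")
    return system, mf


@pytest.fixture(scope="session")
def water_sto3g():
    system = build_system(fx.water(), "sto-3g")
    mf = run_mean_field(system, "hf")
    return system, mf


@pytest.fixture(scope="session")
def water_dimer_sto3g():
    system = build_system(fx.water_dimer(), "sto-3g")
    return system


@pytest.fixture(scope="session")
def water_dimer_hf(water_dimer_sto3g):
    return run_mean_field(water_dimer_sto3g, "hf")


def whole_system_hamiltonian(system, mf, level="hf"):
    """Active Hamiltonian with everything active (plain WF in full space)."""
    part = build_partition(mf, system, list(range(len(system.geometry.atoms))),
                           all_virtuals=True)
    ops = emb.build_operators(system, part, level)
    emf = emb.embedded_scf(system, ops, part, level_active="hf")
    ham = emb.transform_active_integrals(system, ops, part, emf.C_emb)
    return ham, part, ops, emf


@pytest.fixture(scope="session")
def h2_ham(h2_eq):
    return whole_system_hamiltonian(*h2_eq)[0]


@pytest.fixture(scope="session")
def h2_stretched_ham(h2_stretched):
    return whole_system_hamiltonian(*h2_stretched)[0]


@pytest.fixture(scope="session")
def h4_ham(h4_chain):
    return whole_system_hamiltonian(*h4_chain)[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric_eri(norb, rng, scale=1.0):
    """Random ERI tensor with full 8-fold permutational symmetry."""
    e = rng.standard_normal((norb,) * 4) * scale
    e = e + e.transpose(1, 0, 2, 3)
    e = e + e.transpose(0, 1, 3, 2)
    e = e + e.transpose(2, 3, 0, 1)
    return e
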