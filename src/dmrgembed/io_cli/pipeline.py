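"""End-to-end driver: SCF -> partition -> embedding -> solver -> assembly."""

from __future__ import annotations

import json
import logging
import os

import numpy as np

from .. import embedding as emb
from ..backend import build_system
from ..backend.scf import run_mean_field
from ..dmrg import SweepConfig, fiedler_ordering, run_dmrg
from ..fci_oracle import fci_solve
from ..partition import build_partition, frozen_core_counts
from .config import RunConfig
from .fixtures import fixture
from .xyz import read_xyz

__all__ = ["run_pipeline"]

log = logging.getLogger("dmrgembed")


def _geometry(cfg: RunConfig):
    if cfg.fixture is not None:
        return fixture(cfg.fixture, **cfg.fixture_params)
    return read_xyz(cfg.geometry)


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full embedding workflow; returns the result bundle."""
    out = {"config_seed": cfg.seed}
    stage = "geometry"
    try:
        geom = _geometry(cfg)
        stage = "scf"
        system = build_system(geom, cfg.basis)
        mf = run_mean_field(system, cfg.env_level)
        log.info("stage scf done: E_total = %.12f", mf.E_total)
        out["E_mean_field_full"] = mf.E_total
        stage = "partition"
        part = build_partition(mf, system, cfg.active_atoms,
                               n_shells=cfg.n_shells, k_override=cfg.spade_k,
                               all_virtuals=cfg.all_virtuals)
        out["partition"] = part.report()
        out["frozen_core_counts"] = frozen_core_counts(system)
        log.info("stage partition done: %s", part.report())
        stage = "embed"
        ops = emb.build_operators(system, part, cfg.env_level, mu=cfg.mu)
        emf = emb.embedded_scf(system, ops, part,
                               level_active=cfg.active_level)
        out["E_mean_field_embedded"] = emf.E_hf_in_dft
        out["energy_report_mean_field"] = emf.energy_report
        log.info("stage embed done: E = %.12f", emf.E_hf_in_dft)
        if cfg.wf_solver == "HF":
            out["E_total"] = emf.E_hf_in_dft
            out["energy_report"] = emf.energy_report
        else:
            stage = "integrals"
            ham = emb.transform_active_integrals(system, ops, part, emf.C_emb)
            if cfg.frozen_core:
                ncore = out["frozen_core_counts"]["n_core_orbitals"]
                ham = emb.freeze_core(system, ham, ncore)
            out["active_space"] = {"norb": ham.norb, "nelec": ham.nelec}
            stage = "solve"
            if cfg.wf_solver == "FCI":
                sol = fci_solve(ham)
                e_total = sol.energy
                gamma_span = sol.one_rdm
                out["solver"] = {"energy": e_total}
            else:
                sweep = SweepConfig(
                    tre_target=cfg.tre_target, m_min=cfg.m_min,
                    m_max=cfg.m_max, max_sweeps=cfg.max_sweeps,
                    e_conv=cfg.e_conv, warmup=cfg.warmup, seed=cfg.seed)
                if cfg.use_fiedler:
                    pre = SweepConfig(tre_target=1e-4, m_min=2, m_max=16,
                                      max_sweeps=3, e_conv=1e-6, seed=cfg.seed)
                    pre_res = run_dmrg(ham, pre)
                    sweep.ordering = fiedler_ordering(pre_res.mutual_information)
                    out["fiedler_ordering"] = list(map(int, sweep.ordering))
                res = run_dmrg(ham, sweep)
                e_total = res.energy
                gamma_span = res.one_rdm
                out["solver"] = {
                    "energy": res.energy,
                    "sweep_energies": res.sweep_energies,
                    "max_bond_dim": res.max_bond_dim,
                    "converged": res.converged,
                    "n_overruns": sum(1 for d in res.discarded_weights if d[4]),
                }
                out["_dmrg_result"] = res
                for line in res.log_lines:
                    log.info("%s", line)
            stage = "assembly"
            C = ham.C_active
            gamma_ao = C @ gamma_span @ C.T
            report = emb.assemble_total_energy(
                system, ops, part, e_wf_elec=e_total - ham.e_core,
                gamma_wf=gamma_ao)
            out["E_total"] = report["total"]
            out["energy_report"] = report
            out["_active_hamiltonian"] = ham
            log.info("stage solve done: E = %.12f", e_total)
        out["_objects"] = {"system": system, "mf": mf, "partition": part,
                           "operators": ops, "embedded_mf": emf}
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise
    if write_outputs:
        _write_outputs(cfg, out)
    return out


def _serializable(out: dict) -> dict:
    clean = {}
    for k, v in out.items():
        if k.startswith("_"):
            continue
        clean[k] = v
    return json.loads(json.dumps(clean, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not serializable: {type(obj)}")


def _write_outputs(cfg: RunConfig, out: dict):
    os.makedirs(cfg.output_dir, exist_ok=True)
    path = os.path.join(cfg.output_dir, "result.json")
    with open(path, "w") as f:
        json.dump(_serializable(out), f, indent=1, sort_keys=True)
    if "partition" in out:
        with open(os.path.join(cfg.output_dir, "partition.json"), "w") as f:
            json.dump(out["partition"], f, indent=1)
    if "energy_report" in out:
        with open(os.path.join(cfg.output_dir, "energy_report.json"), "w") as f:
            json.dump({k: float(v) for k, v in out["energy_report"].items()},
                      f, indent=1)
    ham = out.get("_active_hamiltonian")
    if ham is not None:
        ham.write(os.path.join(cfg.output_dir, "active_space.fcidump"))
    res = out.get("_dmrg_result")
    if res is not None:
        res.save(os.path.join(cfg.output_dir, "dmrg_result.npz"))
        with open(os.path.join(cfg.output_dir, "dmrg_sweeps.log"), "w") as f:
            f.write("\n".join(res.log_lines) + "\n")
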