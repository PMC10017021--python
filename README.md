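# dmrgembed

Projection-based WF-in-DFT embedding with a two-site DMRG solver, in
pure scientific Python. A strongly correlated molecular fragment is
solved with a matrix-product-state (DMRG) solver while the rest of the
molecule is treated with Kohn–Sham DFT:

1. full-system restricted HF/KS mean field (built-in Gaussian-integral
   engine: McMurchie–Davidson integrals with numba kernels, Becke-grid
   XC quadrature, LDA/PBE/PBE0/B3LYP functionals, DIIS SCF);
2. SPADE partitioning of the occupied orbitals into active (A) and
   environment (B) subsystems, plus two-shell concentric localization of
   the virtual space;
3. embedding operators: level-shift projector `P_B = S γ_B S` (μ = 1e6
   by default), embedding potential `v_emb = g[γ_A+γ_B] − g[γ_A]`, and
   the effective core Hamiltonian `h̃ = h + v_emb + μ P_B`;
4. embedded mean field in the active span, AO→MO transform of the
   active-space Hamiltonian (FCIDUMP in/out);
5. correlated solvers: determinant FCI (oracle) and two-site DMRG with
   quantum-number-blocked decimation, DBSS adaptive bond dimensions,
   CI-DEAS-inspired warm-up, perturbative noise, Davidson local solver,
   Fiedler orbital ordering, 1-RDM / orbital-entropy / mutual-information
   outputs;
6. total-energy assembly with the same-level exactness identity as the
   bookkeeping anchor (same-functional DFT-in-DFT equals the full-system
   KS energy to better than 1e-6 Eh).

## CLI

```sh
dmrgembed run config.yaml       # scf -> partition -> embed -> solve -> assembly
dmrgembed scf|partition|embed|fcidump config.yaml
dmrgembed solve active_space.fcidump --solver DMRG --tre 1e-6
```

Example config:

```yaml
fixture: propionitrile          # or geometry: path/to/file.xyz
fixture_params: {r_cn: 1.8}
basis: sto-3g
active_atoms: [2, 3]            # nitrile C and N
env_level: b3lyp
wf_solver: DMRG                 # HF | FCI | DMRG
n_shells: 2
tre_target: 1.0e-6
m_max: 64
seed: 1
output_dir: out
```

Outputs: `result.json`, `partition.json` (SPADE singular values, shell
sizes, active counts), `energy_report.json` (assembly components incl.
the μ·tr[Γ P_B] level-shift term), `active_space.fcidump`,
`dmrg_result.npz`, and per-sweep logs.

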