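"""Molecular geometry and AO-integral containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import integrals
from .basis import ANGSTROM_TO_BOHR, atomic_number, ao_atom_map, build_shells, count_ao


class ConfigurationError(ValueError):
    """Bad user input: unknown element, basis, functional, ..."""


@dataclass
class Geometry:
    """Nuclear frame in Å. Closed-shell only (spin = 2S = 0)."""

    atoms: list[str]
    coords: np.ndarray            # (natm, 3) Å
    charge: int = 0
    spin: int = 0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atoms) != len(self.coords):
            raise ConfigurationError("len(atoms) != len(coords)")
        if self.spin != 0:
            raise ConfigurationError("only closed-shell (spin=0) systems supported")
        if self.n_electrons % 2 != 0:
            raise ConfigurationError(
                f"odd electron count {self.n_electrons}; closed-shell required")

    @property
    def charges(self) -> np.ndarray:
        return np.array([atomic_number(a) for a in self.atoms], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(sum(atomic_number(a) for a in self.atoms)) - self.charge

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANGSTROM_TO_BOHR

    def translated(self, shift_angstrom) -> "Geometry":
        return Geometry(list(self.atoms), self.coords + np.asarray(shift_angstrom),
                        self.charge, self.spin)


def nuclear_repulsion(Z: np.ndarray, xyz_bohr: np.ndarray) -> float:
    e = 0.0
    for i in range(len(Z)):
        for j in range(i):
            e += Z[i] * Z[j] / np.linalg.norm(xyz_bohr[i] - xyz_bohr[j])
    return float(e)


@dataclass
class AOSystem:
    """AO integrals of one geometry/basis combination.

    The ERI tensor is stored dense in chemist notation (pq|rs); fine at
    desk scale (<= ~100 AOs).
    """

    geometry: Geometry
    basis: str
    shells: list = field(repr=False)
    S: np.ndarray = field(repr=False)
    hcore: np.ndarray = field(repr=False)
    enuc: float = 0.0
    _eri: np.ndarray | None = field(default=None, repr=False)

    @property
    def nao(self) -> int:
        return self.S.shape[0]

    @property
    def n_electrons(self) -> int:
        return self.geometry.n_electrons

    @property
    def eri(self) -> np.ndarray:
        if self._eri is None:
            self._eri = integrals.eri_tensor(self.shells)
        return self._eri

    @property
    def ao_atoms(self) -> np.ndarray:
        return ao_atom_map(self.shells)

    def fragment_ao_indices(self, atom_indices) -> np.ndarray:
        owner = self.ao_atoms
        mask = np.isin(owner, np.asarray(atom_indices, dtype=int))
        return np.nonzero(mask)[0]


def build_system(geometry: Geometry, basis: str) -> AOSystem:
    """Assemble overlap, core Hamiltonian and (lazily) ERIs."""
    shells = build_shells(geometry.atoms, geometry.coords_bohr, basis)
    Z = geometry.charges
    xyz = geometry.coords_bohr
    S = integrals.overlap(shells, Z, xyz)
    T = integrals.kinetic(shells, Z, xyz)
    V = integrals.nuclear_attraction(shells, Z, xyz)
    assert S.shape[0] == count_ao(shells)
    return AOSystem(geometry=geometry, basis=basis, shells=shells,
                    S=S, hcore=T + V, enuc=nuclear_repulsion(Z, xyz))
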