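"""Gaussian basis sets: vendored data, contraction normalization, shell tables.

Basis data is stored as JSON (one file per basis set) in ``basis_data/``;
each entry is a list of shells ``[l, [exp, c1, c2, ...], ...]`` where
multiple contraction columns share the same primitives (general
contraction).  Coefficients are the published ones; normalization happens
here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammaln

ELEMENTS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
]

ANGSTROM_TO_BOHR = 1.0 / 0.52917721092

_L_LETTER = "spdfgh"


def atomic_number(symbol: str) -> int:
    try:
        return ELEMENTS.index(symbol.capitalize())
    except ValueError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None


def _double_factorial(n: int) -> float:
    if n <= 0:
        return 1.0
    return float(np.prod(np.arange(n, 0, -2, dtype=float)))


def primitive_norm(l: int, alpha: float) -> float:
    """Norm of a cartesian primitive x^l exp(-a r^2) (all exponent on one axis)."""
    num = 2.0 ** (2 * l + 1.5) * alpha ** (l + 1.5)
    den = _double_factorial(2 * l - 1) * np.pi ** 1.5
    return np.sqrt(num / den)


@dataclass
class Shell:
    """One contracted shell (possibly several contraction columns)."""

    l: int
    center: np.ndarray          # Bohr
    atom: int
    exps: np.ndarray            # (nprim,)
    coefs: np.ndarray           # (nprim, nctr) primitive-normalized + contraction-normalized
    ao_offset: int = 0          # spherical AO offset of first function

    @property
    def nprim(self) -> int:
        return len(self.exps)

    @property
    def nctr(self) -> int:
        return self.coefs.shape[1]

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    @property
    def nsph(self) -> int:
        return 2 * self.l + 1


def _normalize_contraction(l: int, exps: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Primitive-normalize, then scale each column to unit self-overlap."""
    cs = coefs * np.array([primitive_norm(l, a) for a in exps])[:, None]
    # self-overlap of a contracted cartesian function with l on one axis
    ee = exps[:, None] + exps[None, :]
    s_prim = (
        _double_factorial(2 * l - 1)
        * np.pi ** 1.5
        / (2.0 ** l * ee ** (l + 1.5))
    )
    for c in range(cs.shape[1]):
        norm2 = cs[:, c] @ s_prim @ cs[:, c]
        cs[:, c] /= np.sqrt(norm2)
    return cs


def load_basis(name: str, elements: list[str]) -> dict:
    """Load raw basis data for the given elements.

    Returns ``{element: [[l, [exp, c...], ...], ...]}``.
    """
    fname = name.lower().replace("*", "s").replace(" ", "")
    ref = resources.files("dmrgembed.backend").joinpath(f"basis_data/{fname}.json")
    try:
        data = json.loads(ref.read_text())
    except FileNotFoundError:
        raise KeyError(f"basis set {name!r} not available") from None
    out = {}
    for el in elements:
        key = el.capitalize()
        if key not in data:
            raise KeyError(f"basis set {name!r} has no entry for element {el!r}")
        out[key] = data[key]
    return out


def build_shells(atoms: list[str], coords_bohr: np.ndarray, basis_name: str) -> list[Shell]:
    """Expand a geometry into an ordered list of contracted shells.

    AO ordering: shells in atom order as listed in the basis file; within a
    shell, spherical components m = -l..l (pyscf convention: p ordered
    x, y, z).
    """
    raw = load_basis(basis_name, sorted(set(atoms)))
    shells: list[Shell] = []
    offset = 0
    for iat, (el, xyz) in enumerate(zip(atoms, coords_bohr)):
        for block in raw[el.capitalize()]:
            l = block[0]
            rows = np.array(block[1:], dtype=float)
            exps = rows[:, 0]
            coefs = rows[:, 1:]
            # split general contraction columns that use disjoint primitives
            coefs = _normalize_contraction(l, exps, coefs.copy())
            sh = Shell(l=l, center=np.asarray(xyz, float), atom=iat,
                       exps=exps, coefs=coefs, ao_offset=offset)
            shells.append(sh)
            offset += sh.nsph * sh.nctr
        # deterministic ordering is the file ordering; nothing to sort
    return shells


def count_ao(shells: list[Shell]) -> int:
    return sum(sh.nsph * sh.nctr for sh in shells)


def ao_atom_map(shells: list[Shell]) -> np.ndarray:
    """Atom index owning each (spherical) AO."""
    owner = []
    for sh in shells:
        owner.extend([sh.atom] * (sh.nsph * sh.nctr))
    return np.array(owner, dtype=int)


def ao_labels(shells: list[Shell], atoms: list[str]) -> list[str]:
    out = []
    for sh in shells:
        for c in range(sh.nctr):
            for m in range(sh.nsph):
                out.append(f"{sh.atom}{atoms[sh.atom]} {_L_LETTER[sh.l]}{m}")
    return out


# --- cartesian -> real solid harmonic transforms (pyscf component order) ---

def cart2sph_matrix(l: int) -> np.ndarray:
    """(ncart, nsph) transform for unit-normalized cartesians.

    Rows follow the lexicographic cartesian order used by the integral
    kernels (x then y then z exponents descending); columns m = -l..l,
    except l=1 which stays x, y, z.
    """
    if l == 0:
        return np.ones((1, 1))
    if l == 1:
        return np.eye(3)
    if l == 2:
        # cart order: xx, xy, xz, yy, yz, zz
        s3 = np.sqrt(3.0)
        m_m2 = np.array([0, s3, 0, 0, 0, 0])        # xy
        m_m1 = np.array([0, 0, 0, 0, s3, 0])        # yz
        m_0 = np.array([-0.5, 0, 0, -0.5, 0, 1.0])  # (2zz-xx-yy)/2
        m_p1 = np.array([0, 0, s3, 0, 0, 0])        # xz
        m_p2 = np.array([s3 / 2, 0, 0, -s3 / 2, 0, 0])  # (xx-yy)*sqrt3/2
        return np.stack([m_m2, m_m1, m_0, m_p1, m_p2], axis=1)
    raise NotImplementedError(f"l={l} not supported (s, p, d only)")


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """(lx, ly, lz) triples in the kernel's cartesian order."""
    comps = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            comps.append((lx, ly, l - lx - ly))
    return comps
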