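"""Built-in test geometries.

All fixtures are generated from internal coordinates, so every stage of
the pipeline is testable without external files.  ``propionitrile(r_cn)``
displaces the nitrile N along the C–N axis so the requested distance is
exact.
"""

from __future__ import annotations

import numpy as np

from ..backend.system import ConfigurationError, Geometry

__all__ = ["fixture", "FIXTURES"]


def _zmat_place(coords, ref, dist, ang_ref=None, angle=None, dih_ref=None, dihedral=None):
    """Place one atom from distance / angle (deg) / dihedral (deg) references."""
    a = np.asarray(coords[ref], float)
    if ang_ref is None:
        return a + np.array([0.0, 0.0, dist])
    b = np.asarray(coords[ang_ref], float)
    ang = np.deg2rad(angle)
    if dih_ref is None:
        # in the xz-plane through a-b
        u = (b - a) / np.linalg.norm(b - a)
        perp = np.array([1.0, 0.0, 0.0])
        perp = perp - u * (perp @ u)
        if np.linalg.norm(perp) < 1e-8:
            perp = np.array([0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return a + dist * (np.cos(ang) * u + np.sin(ang) * perp)
    c = np.asarray(coords[dih_ref], float)
    dih = np.deg2rad(dihedral)
    u = (b - a) / np.linalg.norm(b - a)
    v = c - b
    v = v - u * (v @ u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return a + dist * (np.cos(ang) * u
                       + np.sin(ang) * (np.cos(dih) * v + np.sin(dih) * w))


def h_chain(n: int = 4, r: float = 1.0) -> Geometry:
    """n collinear H atoms with spacing r Å."""
    coords = np.zeros((n, 3))
    coords[:, 2] = r * np.arange(n)
    return Geometry(["H"] * n, coords)


def n2(r: float = 1.0977) -> Geometry:
    return Geometry(["N", "N"], np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]))


def he2(r: float = 50.0) -> Geometry:
    return Geometry(["He", "He"], np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]]))


def water() -> Geometry:
    return Geometry(
        ["O", "H", "H"],
        np.array([[0.0, 0.0, 0.1173],
                  [0.0, 0.7572, -0.4692],
                  [0.0, -0.7572, -0.4692]]))


def water_dimer() -> Geometry:
    """Near-equilibrium hydrogen-bonded water dimer (donor first)."""
    return Geometry(
        ["O", "H", "H", "O", "H", "H"],
        np.array([
            [-1.551007, -0.114520, 0.000000],
            [-1.934259, 0.762503, 0.000000],
            [-0.599677, 0.040712, 0.000000],
            [1.350625, 0.111469, 0.000000],
            [1.680398, -0.373741, -0.758561],
            [1.680398, -0.373741, 0.758561],
        ]))


def propionitrile(r_cn: float = 1.161) -> Geometry:
    """CH3CH2CN at a standard equilibrium frame; nitrile C–N set to r_cn Å.

    Atom order: C(methyl), C(methylene), C(nitrile), N, 5 H.
    """
    coords = {}
    coords[0] = np.array([0.0, 0.0, 0.0])                      # C methyl
    coords[1] = _zmat_place(coords, 0, 1.540)                  # C methylene
    coords[2] = _zmat_place(coords, 1, 1.458, 0, 111.0)        # C nitrile
    coords[3] = _zmat_place(coords, 2, 1.161, 1, 178.0, 0, 180.0)   # N
    coords[4] = _zmat_place(coords, 0, 1.095, 1, 110.5, 2, 180.0)   # H methyl anti
    coords[5] = _zmat_place(coords, 0, 1.095, 1, 110.5, 2, 60.0)
    coords[6] = _zmat_place(coords, 0, 1.095, 1, 110.5, 2, -60.0)
    coords[7] = _zmat_place(coords, 1, 1.096, 2, 109.5, 3, 120.5)   # H methylene
    coords[8] = _zmat_place(coords, 1, 1.096, 2, 109.5, 3, -120.5)
    xyz = np.array([coords[i] for i in range(9)])
    # set exact nitrile distance along the equilibrium C->N direction
    axis = xyz[3] - xyz[2]
    axis /= np.linalg.norm(axis)
    xyz[3] = xyz[2] + r_cn * axis
    return Geometry(["C", "C", "C", "N"] + ["H"] * 5, xyz)


PROPIONITRILE_NITRILE_ATOMS = (2, 3)   # active fragment: nitrile C and N

FIXTURES = {
    "h_chain": h_chain,
    "n2": n2,
    "he2": he2,
    "water": water,
    "water_dimer": water_dimer,
    "propionitrile": propionitrile,
}


def fixture(name: str, **params) -> Geometry:
    try:
        fn = FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return fn(**params)
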