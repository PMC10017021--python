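"""XYZ geometry files (Å); the comment line may carry charge/spin."""

from __future__ import annotations

import re

import numpy as np

from ..backend.system import ConfigurationError, Geometry

__all__ = ["read_xyz", "write_xyz"]


def read_xyz(path) -> Geometry:
    with open(path) as f:
        lines = f.read().splitlines()
    if not lines:
        raise ConfigurationError(f"{path}: empty XYZ file")
    try:
        natm = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ConfigurationError(f"{path}:1: expected an atom count") from None
    comment = lines[1] if len(lines) > 1 else ""
    charge = spin = 0
    m = re.search(r"charge\s*=\s*(-?\d+)", comment)
    if m:
        charge = int(m.group(1))
    m = re.search(r"spin\s*=\s*(-?\d+)", comment)
    if m:
        spin = int(m.group(1))
    atoms, coords = [], []
    for ln, line in enumerate(lines[2: 2 + natm], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ConfigurationError(f"{path}:{ln}: malformed XYZ line {line!r}")
        try:
            xyz = [float(x) for x in parts[1:4]]
        except ValueError:
            raise ConfigurationError(
                f"{path}:{ln}: non-numeric coordinate in {line!r}") from None
        atoms.append(parts[0])
        coords.append(xyz)
    if len(atoms) != natm:
        raise ConfigurationError(
            f"{path}: header promises {natm} atoms, found {len(atoms)}")
    return Geometry(atoms, np.array(coords), charge=charge, spin=spin)


def write_xyz(geometry: Geometry, path, comment: str | None = None):
    if comment is None:
        comment = f"charge={geometry.charge} spin={geometry.spin}"
    with open(path, "w") as f:
        f.write(f"{len(geometry.atoms)}\n{comment}\n")
        for a, (x, y, z) in zip(geometry.atoms, geometry.coords):
            f.write(f"{a:<3s} {x:20.12f} {y:20.12f} {z:20.12f}\n")
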