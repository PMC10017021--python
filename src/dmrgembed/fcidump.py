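"""FCIDUMP (Molpro dialect) serialization of active-space Hamiltonians.

Chemist-notation integrals (ij|kl) with 8-fold permutational symmetry;
the zero-index record carries the scalar core energy.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_fcidump", "read_fcidump"]


def write_fcidump(path, h: np.ndarray, eri: np.ndarray, e_core: float,
                  nelec: int, ms2: int = 0, tol: float = 1e-14):
    """Write h_pq, (pq|rs) and the core constant; indices are 1-based."""
    norb = h.shape[0]
    with open(path, "w") as f:
        f.write(f"&FCI NORB={norb},NELEC={nelec},MS2={ms2},\n")
        f.write("  ORBSYM=" + ",".join(["1"] * norb) + ",\n")
        f.write("  ISYM=1,\n&END\n")
        for i in range(norb):
            for j in range(i + 1):
                for k in range(i + 1):
                    lmax = j if k == i else k
                    for l in range(lmax + 1):
                        v = eri[i, j, k, l]
                        if abs(v) > tol:
                            f.write(f"{v:23.16E} {i+1:4d} {j+1:4d} {k+1:4d} {l+1:4d}\n")
        for i in range(norb):
            for j in range(i + 1):
                if abs(h[i, j]) > tol:
                    f.write(f"{h[i, j]:23.16E} {i+1:4d} {j+1:4d}    0    0\n")
        f.write(f"{e_core:23.16E}    0    0    0    0\n")


def read_fcidump(path):
    """Returns (h, eri, e_core, norb, nelec, ms2)."""
    header = ""
    lines = open(path).read().splitlines()
    it = iter(lines)
    for line in it:
        header += line.upper() + " "
        if "&END" in line.upper() or "/" in line:
            break
    import re

    def field(name, default=None):
        m = re.search(rf"{name}\s*=\s*([0-9\-]+)", header)
        if m is None:
            if default is None:
                raise ValueError(f"FCIDUMP header missing {name}")
            return default
        return int(m.group(1))

    norb = field("NORB")
    nelec = field("NELEC")
    ms2 = field("MS2", 0)
    h = np.zeros((norb, norb))
    eri = np.zeros((norb, norb, norb, norb))
    e_core = 0.0
    for line in it:
        parts = line.split()
        if not parts:
            continue
        v = float(parts[0])
        i, j, k, l = (int(x) for x in parts[1:5])
        if i == 0:
            e_core = v
        elif k == 0:
            i, j = i - 1, j - 1
            h[i, j] = h[j, i] = v
        else:
            i, j, k, l = i - 1, j - 1, k - 1, l - 1
            for a, b, c, d in ((i, j, k, l), (j, i, k, l), (i, j, l, k),
                               (j, i, l, k), (k, l, i, j), (l, k, i, j),
                               (k, l, j, i), (l, k, j, i)):
                eri[a, b, c, d] = v
    return h, eri, e_core, norb, nelec, ms2
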