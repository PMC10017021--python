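"""Fiedler orbital ordering from a mutual-information graph."""

from __future__ import annotations

import numpy as np

__all__ = ["fiedler_ordering"]


def _components(I: np.ndarray):
    n = I.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for w in np.nonzero(I[v] > 0)[0]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def _order_component(I: np.ndarray, nodes):
    if len(nodes) == 1:
        return list(nodes)
    sub = I[np.ix_(nodes, nodes)]
    L = np.diag(sub.sum(axis=1)) - sub
    w, V = np.linalg.eigh(L)
    fv = V[:, 1]
    # deterministic tie-break: stable sort, canonical direction
    order = np.argsort(fv, kind="stable")
    perm = [nodes[k] for k in order]
    if perm[0] > perm[-1]:
        perm = perm[::-1]
    return perm


def fiedler_ordering(I: np.ndarray) -> list[int]:
    """Permutation sorting orbitals by the Fiedler vector of L = D - I.

    Disconnected components are ordered independently and concatenated
    largest first (ties by smallest orbital index).
    """
    I = np.asarray(I, dtype=float)
    if I.shape[0] != I.shape[1] or np.abs(I - I.T).max() > 1e-10:
        raise ValueError("mutual-information matrix must be square symmetric")
    if np.any(I < -1e-12):
        raise ValueError("mutual information must be non-negative")
    n = I.shape[0]
    I = np.where(I > 1e-14, I, 0.0)
    np.fill_diagonal(I, 0.0)
    comps = _components(I)
    if len(comps) == 1:
        return _order_component(I, comps[0])
    comps.sort(key=lambda c: (-len(c), c[0]))
    out = []
    for c in comps:
        out.extend(_order_component(I, c))
    return out
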