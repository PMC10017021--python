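"""Matrix product states over 4-dimensional orbital sites.

Tensors are dense (left, phys, right); each bond carries per-index
(N, 2Sz) labels so decimation can respect the abelian symmetry even
though the storage is dense.  Bond labels are ``None`` for states without
a definite particle number (e.g., MPS factorized from an arbitrary
tensor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .local_ops import DIM, QNUMS

__all__ = ["MPS", "product_state_mps", "mps_from_dense", "svd_truncate"]


@dataclass
class MPS:
    tensors: list            # site tensors (Dl, 4, Dr)
    qnums: list | None       # per-bond: array (D, 2) of (N, 2Sz); len = nsites+1
    center: int = 0          # canonical center (mixed canonical form)

    @property
    def nsites(self) -> int:
        return len(self.tensors)

    @property
    def bond_dims(self) -> list:
        return [t.shape[2] for t in self.tensors[:-1]]

    def copy(self) -> "MPS":
        return MPS([t.copy() for t in self.tensors],
                   None if self.qnums is None else [q.copy() for q in self.qnums],
                   self.center)

    def norm(self) -> float:
        t = self.tensors[self.center]
        return float(np.linalg.norm(t))

    def normalize(self):
        t = self.tensors[self.center]
        n = np.linalg.norm(t)
        if n > 0:
            self.tensors[self.center] = t / n

    def to_dense(self) -> np.ndarray:
        """Contract to the full 4^n occupation tensor (test scale only)."""
        if self.nsites > 12:
            raise ValueError("to_dense only at test scale")
        out = self.tensors[0]
        for t in self.tensors[1:]:
            out = np.tensordot(out, t, axes=([out.ndim - 1], [0]))
        return np.squeeze(out, axis=(0, out.ndim - 1)).reshape((DIM,) * self.nsites)

    def overlap(self, other: "MPS") -> float:
        E = np.ones((1, 1))
        for a, b in zip(self.tensors, other.tensors):
            E = np.einsum("ab,asc,bsd->cd", E, a, b, optimize=True)
        return float(E[0, 0])

    # ---- canonicalization ----
    def shift_center_right(self):
        i = self.center
        t = self.tensors[i]
        dl, d, dr = t.shape
        m = t.reshape(dl * d, dr)
        if self.qnums is None:
            q, r = np.linalg.qr(m)
            new_q = None
        else:
            row_q = _combine_charges(self.qnums[i], dl)
            q, r, new_q = _blocked_qr(m, row_q, self.qnums[i + 1])
            self.qnums[i + 1] = new_q
        self.tensors[i] = q.reshape(dl, d, q.shape[1])
        self.tensors[i + 1] = np.tensordot(r, self.tensors[i + 1], axes=([1], [0]))
        self.center = i + 1

    def shift_center_left(self):
        i = self.center
        t = self.tensors[i]
        dl, d, dr = t.shape
        m = t.reshape(dl, d * dr).T                      # (d*dr, dl)
        if self.qnums is None:
            q, r = np.linalg.qr(m)
            new_q = None
        else:
            # row charge of the transposed matrix = charge entering from left
            row_q = _combine_charges_right(self.qnums[i + 1], dr)
            q, r, new_q = _blocked_qr(m, row_q, self.qnums[i])
            self.qnums[i] = new_q
        self.tensors[i] = q.T.reshape(q.shape[1], d, dr)
        self.tensors[i - 1] = np.tensordot(self.tensors[i - 1], r.T, axes=([2], [0]))
        self.center = i - 1

    def canonicalize(self, center: int = 0):
        while self.center > center:
            self.shift_center_left()
        while self.center < center:
            self.shift_center_right()

    def orthonormality_errors(self):
        """Max deviation of left/right orthonormality away from the center."""
        errs = []
        for i, t in enumerate(self.tensors):
            dl, d, dr = t.shape
            if i < self.center:
                m = t.reshape(dl * d, dr)
                errs.append(np.abs(m.T @ m - np.eye(dr)).max())
            elif i > self.center:
                m = t.reshape(dl, d * dr)
                errs.append(np.abs(m @ m.T - np.eye(dl)).max())
        return errs


def _combine_charges(left_q: np.ndarray, dl: int) -> np.ndarray:
    """Row charges of a (dl*4, dr) unfolding: left bond charge + site charge."""
    site_q = np.array(QNUMS, dtype=int)
    return (left_q[:, None, :] + site_q[None, :, :]).reshape(dl * DIM, 2)


def _combine_charges_right(right_q: np.ndarray, dr: int) -> np.ndarray:
    """Charges entering from the left for a (4*dr,) column unfolding."""
    site_q = np.array(QNUMS, dtype=int)
    return (right_q[None, :, :] - site_q[:, None, :]).reshape(DIM * dr, 2)


def _blocked_qr(m: np.ndarray, row_q: np.ndarray, col_q: np.ndarray):
    """QR of a charge-block-structured matrix, block by block.

    Nonzeros of ``m`` must satisfy row_q[i] == col_q[j]; the returned Q has
    one orthonormal column group per charge sector, R maps back to the
    original columns, and the new bond charges are returned per Q column.
    """
    ncols = m.shape[1]
    new_charges = []
    Qparts, blocks = [], []
    for c in np.unique(col_q, axis=0):
        cols = np.nonzero((col_q == c).all(axis=1))[0]
        rows = np.nonzero((row_q == c).all(axis=1))[0]
        if len(rows) == 0:
            continue
        q, r = np.linalg.qr(m[np.ix_(rows, cols)])
        Qb = np.zeros((m.shape[0], q.shape[1]))
        Qb[rows] = q
        Qparts.append(Qb)
        blocks.append((cols, r))
        new_charges.extend([c] * q.shape[1])
    Q = np.hstack(Qparts) if Qparts else np.zeros((m.shape[0], 0))
    R = np.zeros((Q.shape[1], ncols))
    pos = 0
    for cols, r in blocks:
        R[pos:pos + r.shape[0], cols] = r
        pos += r.shape[0]
    return Q, R, np.array(new_charges, dtype=int).reshape(-1, 2)


def product_state_mps(occupations: list[int]) -> MPS:
    """Bond-dimension-1 MPS for a product state; occupations in {0,1,2,3}."""
    tensors = []
    qn = [np.zeros((1, 2), dtype=int)]
    N = Sz = 0
    for occ in occupations:
        t = np.zeros((1, DIM, 1))
        t[0, occ, 0] = 1.0
        tensors.append(t)
        N += QNUMS[occ][0]
        Sz += QNUMS[occ][1]
        qn.append(np.array([[N, Sz]], dtype=int))
    return MPS(tensors, qn, center=len(occupations) - 1)


def svd_truncate(theta_mat: np.ndarray, m_max: int | None = None,
                 tre_target: float = 0.0, m_min: int = 1):
    """Plain (symmetry-blind) truncated SVD used by the dense factorizer.

    Returns (U, s, Vt, discarded_weight).
    """
    U, s, Vt = np.linalg.svd(theta_mat, full_matrices=False)
    w2 = s ** 2
    total = w2.sum()
    if total <= 0:
        return U[:, :1], s[:1], Vt[:1], 0.0
    keep = len(s)
    if tre_target > 0 or m_max is not None:
        cum = np.cumsum(w2[::-1])[::-1]          # cum[i] = sum of w2[i:]
        keep = 1
        for m in range(1, len(s) + 1):
            disc = cum[m] if m < len(s) else 0.0
            if disc / total <= tre_target:
                keep = m
                break
        else:
            keep = len(s)
        keep = max(keep, m_min)
        if m_max is not None:
            keep = min(keep, m_max)
    disc = float(w2[keep:].sum() / total)
    return U[:, :keep], s[:keep], Vt[:keep], disc


def mps_from_dense(tensor: np.ndarray, m_max: int | None = None,
                   tre_target: float = 0.0):
    """Successive-SVD factorization of a 4^n occupation tensor into an MPS.

    Returns (mps, discarded_weights).  Without truncation the
    reconstruction is exact.
    """
    shape = tensor.shape
    n = len(shape)
    if any(d != DIM for d in shape):
        raise ValueError(f"tensor must be 4^n, got shape {shape}")
    rest = tensor.reshape(1, -1)
    tensors = []
    discarded = []
    dl = 1
    for i in range(n - 1):
        m = rest.reshape(dl * DIM, DIM ** (n - 1 - i))
        U, s, Vt, disc = svd_truncate(m, m_max=m_max, tre_target=tre_target)
        discarded.append(disc)
        tensors.append(U.reshape(dl, DIM, U.shape[1]))
        rest = s[:, None] * Vt
        dl = U.shape[1]
    tensors.append(rest.reshape(dl, DIM, 1))
    return MPS(tensors, None, center=n - 1), discarded
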