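"""Local (single spatial orbital) operator algebra for the MPS machinery.

Basis order per site: |0>, |dn>, |up>, |updn> with |updn> = c_up^+ c_dn^+ |0>.
Intra-site fermionic signs live in these matrices; inter-site signs are
handled by Jordan-Wigner parity strings (operator P).
"""

from __future__ import annotations

import numpy as np

DIM = 4

# quantum numbers (N, 2Sz) of the local states
QNUMS = ((0, 0), (1, -1), (1, 1), (2, 0))

I4 = np.eye(4)
P = np.diag([1.0, -1.0, -1.0, 1.0])            # (-1)^n

CUP_DAG = np.zeros((4, 4))
CUP_DAG[2, 0] = 1.0
CUP_DAG[3, 1] = 1.0
CUP = CUP_DAG.T.copy()

CDN_DAG = np.zeros((4, 4))
CDN_DAG[1, 0] = 1.0
CDN_DAG[3, 2] = -1.0                            # c_dn^+|up> = -|updn>
CDN = CDN_DAG.T.copy()

N_UP = CUP_DAG @ CUP
N_DN = CDN_DAG @ CDN
N_TOT = N_UP + N_DN

# creation/annihilation by spin channel: 0 = up, 1 = dn
C_DAG = (CUP_DAG, CDN_DAG)
C = (CUP, CDN)


def op_charge(m: np.ndarray) -> tuple[int, int]:
    """(dN, d2Sz) carried by a local operator; raises if not well-defined."""
    dq = None
    for i in range(4):
        for j in range(4):
            if abs(m[i, j]) > 1e-14:
                d = (QNUMS[i][0] - QNUMS[j][0], QNUMS[i][1] - QNUMS[j][1])
                if dq is None:
                    dq = d
                elif dq != d:
                    raise ValueError("operator does not carry a definite charge")
    return dq or (0, 0)
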