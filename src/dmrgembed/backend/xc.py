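"""Closed-shell exchange–correlation functionals.

Each primitive functional maps (rho, sigma) -> (e, de/drho, de/dsigma)
where e is the energy density per volume and sigma = |grad rho|^2.
LDA derivatives are hand-coded; GGA derivatives (B88, LYP, PBE) are
generated symbolically with sympy at first use and cached as lambdified
numpy functions — one source of truth for energy and potential.

Composite functionals are linear combinations plus an exact-exchange
fraction:  b3lyp uses the VWN3 local correlation (Gaussian convention);
b3lyp5 is the VWN5 variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

RHO_CUT = 1e-12


# ----------------------------------------------------------------- LDA parts

def _slater_x(rho):
    cx = (3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0)
    e = -cx * rho ** (4.0 / 3.0)
    vrho = -(4.0 / 3.0) * cx * rho ** (1.0 / 3.0)
    return e, vrho, np.zeros_like(rho)


def _vwn(rho, A, x0, b, c):
    """VWN paramagnetic correlation energy density and potential."""
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    x = np.sqrt(rs)
    X = x * x + b * x + c
    X0 = x0 * x0 + b * x0 + c
    Q = np.sqrt(4.0 * c - b * b)
    atn = np.arctan(Q / (2.0 * x + b))
    eps = A * (np.log(x * x / X) + 2.0 * b / Q * atn
               - b * x0 / X0 * (np.log((x - x0) ** 2 / X)
                                + 2.0 * (b + 2.0 * x0) / Q * atn))
    # d eps / dx
    dlog = 2.0 / x - (2.0 * x + b) / X
    datn = -2.0 * Q / (Q * Q + (2.0 * x + b) ** 2)
    d2 = 2.0 / (x - x0) - (2.0 * x + b) / X
    deps = A * (dlog + 2.0 * b / Q * datn
                - b * x0 / X0 * (d2 + 2.0 * (b + 2.0 * x0) / Q * datn))
    # v = eps - rs/3 * deps/drs ; deps/drs = deps/dx * dx/drs = deps/(2x)
    v = eps - (x / 6.0) * deps
    return eps * rho, v, np.zeros_like(rho)


def _vwn5(rho):
    return _vwn(rho, 0.0310907, -0.10498, 3.72744, 12.9352)


def _vwn3(rho):
    return _vwn(rho, 0.0310907, -0.409286, 13.0720, 42.7198)


def _pw92_sym(rho_s):
    """PW92 paramagnetic correlation energy per particle (sympy expression)."""
    import sympy as sp

    rs = (3 / (4 * sp.pi * rho_s)) ** sp.Rational(1, 3)
    A, a1, b1, b2, b3, b4 = (0.0310907, 0.21370, 7.5957, 3.5876, 1.6382, 0.49294)
    srs = sp.sqrt(rs)
    den = 2 * A * (b1 * srs + b2 * rs + b3 * rs * srs + b4 * rs ** 2)
    return -2 * A * (1 + a1 * rs) * sp.log(1 + 1 / den)


# ------------------------------------------------------- symbolic GGA parts

@lru_cache(maxsize=None)
def _gga_lambdified(name: str):
    import sympy as sp

    rho_s, sigma_s = sp.symbols("rho sigma", positive=True)
    if name == "b88_gc":
        # gradient correction only (total B88 minus Slater), closed shell
        beta = 0.0042
        rho_a = rho_s / 2
        grad_a = sp.sqrt(sigma_s) / 2
        x = grad_a / rho_a ** sp.Rational(4, 3)
        e_spin = -beta * rho_a ** sp.Rational(4, 3) * x ** 2 / (
            1 + 6 * beta * x * sp.asinh(x))
        expr = 2 * e_spin
    elif name == "lyp":
        a, b, c, d = 0.04918, 0.132, 0.2533, 0.349
        cf = sp.Rational(3, 10) * (3 * sp.pi ** 2) ** sp.Rational(2, 3)
        rho13 = rho_s ** sp.Rational(-1, 3)
        om = sp.exp(-c * rho13) / (1 + d * rho13) * rho_s ** sp.Rational(-11, 3)
        dl = c * rho13 + d * rho13 / (1 + d * rho13)
        rho_a = rho_s / 2
        ga2 = sigma_s / 4          # |grad rho_a|^2, closed shell
        gab = sigma_s / 4          # grad rho_a . grad rho_b
        gtot = sigma_s
        t1 = -a * 4 / (1 + d * rho13) * rho_a * rho_a / rho_s
        inner = (2 ** sp.Rational(11, 3) * cf * 2 * rho_a ** sp.Rational(8, 3)
                 + (sp.Rational(47, 18) - sp.Rational(7, 18) * dl) * gtot
                 - (sp.Rational(5, 2) - sp.Rational(1, 18) * dl) * (ga2 + ga2)
                 - (dl - 11) / 9 * (rho_a / rho_s * ga2 + rho_a / rho_s * ga2))
        t2 = rho_a * rho_a * inner
        t3 = (-sp.Rational(2, 3) * rho_s ** 2 * gtot
              + (sp.Rational(2, 3) * rho_s ** 2 - rho_a ** 2) * ga2
              + (sp.Rational(2, 3) * rho_s ** 2 - rho_a ** 2) * ga2)
        expr = t1 - a * b * om * (t2 + t3)
    elif name == "pbe_x":
        kappa, mu = 0.8040, 0.2195149727645171
        kf = (3 * sp.pi ** 2 * rho_s) ** sp.Rational(1, 3)
        s2 = sigma_s / (4 * kf ** 2 * rho_s ** 2)
        fx = 1 + kappa - kappa / (1 + mu * s2 / kappa)
        cx = sp.Rational(3, 4) * (3 / sp.pi) ** sp.Rational(1, 3)
        expr = -cx * rho_s ** sp.Rational(4, 3) * fx
    elif name == "pbe_c":
        gamma_ = (1 - sp.log(2)) / sp.pi ** 2
        beta = 0.06672455060314922
        eps = _pw92_sym(rho_s)
        kf = (3 * sp.pi ** 2 * rho_s) ** sp.Rational(1, 3)
        ks = sp.sqrt(4 * kf / sp.pi)
        t2 = sigma_s / (4 * ks ** 2 * rho_s ** 2)
        Aa = beta / gamma_ / (sp.exp(-eps / gamma_) - 1)
        H = gamma_ * sp.log(1 + beta / gamma_ * t2 * (1 + Aa * t2)
                            / (1 + Aa * t2 + Aa ** 2 * t2 ** 2))
        expr = rho_s * (eps + H)
    elif name == "pw92":
        expr = rho_s * _pw92_sym(rho_s)
    else:
        raise KeyError(name)
    drho = sp.diff(expr, rho_s)
    dsig = sp.diff(expr, sigma_s)
    fns = [sp.lambdify((rho_s, sigma_s), e, modules="numpy")
           for e in (expr, drho, dsig)]
    return fns


def _gga(name):
    fe, fr, fs = _gga_lambdified(name)

    def run(rho, sigma):
        e = fe(rho, sigma)
        vr = fr(rho, sigma)
        vs = fs(rho, sigma)
        return (np.broadcast_to(e, rho.shape).astype(float),
                np.broadcast_to(vr, rho.shape).astype(float),
                np.broadcast_to(vs, rho.shape).astype(float))

    return run


# ------------------------------------------------------------- composites

@dataclass(frozen=True)
class Functional:
    name: str
    hyb: float                      # exact-exchange fraction
    parts: tuple                    # ((weight, fn_name), ...)
    needs_sigma: bool

    @property
    def is_hf(self) -> bool:
        return not self.parts


_PRIMITIVES = {
    "slater": (_slater_x, False),
    "vwn3": (_vwn3, False),
    "vwn5": (_vwn5, False),
    "b88_gc": (None, True),
    "lyp": (None, True),
    "pbe_x": (None, True),
    "pbe_c": (None, True),
    "pw92": (None, False),
}

_FUNCTIONALS = {
    "hf": Functional("hf", 1.0, (), False),
    "lda": Functional("lda", 0.0, ((1.0, "slater"), (1.0, "vwn5")), False),
    "pbe": Functional("pbe", 0.0, ((1.0, "pbe_x"), (1.0, "pbe_c")), True),
    "pbe0": Functional("pbe0", 0.25, ((0.75, "pbe_x"), (1.0, "pbe_c")), True),
    "b3lyp": Functional("b3lyp", 0.20,
                        ((0.80, "slater"), (0.72, "b88_gc"),
                         (0.19, "vwn3"), (0.81, "lyp")), True),
    "b3lyp5": Functional("b3lyp5", 0.20,
                         ((0.80, "slater"), (0.72, "b88_gc"),
                          (0.19, "vwn5"), (0.81, "lyp")), True),
}


def get_functional(level: str) -> Functional:
    try:
        return _FUNCTIONALS[level.lower()]
    except KeyError:
        raise KeyError(f"unknown functional/level {level!r}; "
                       f"available: {sorted(_FUNCTIONALS)}") from None


def eval_xc(level: str, rho: np.ndarray, sigma: np.ndarray | None):
    """Total XC energy density and derivatives for a composite functional."""
    fn = get_functional(level)
    if fn.is_hf:
        z = np.zeros_like(rho)
        return z, z, z
    mask = rho > RHO_CUT
    r = np.where(mask, rho, 1.0)
    s = np.where(mask, sigma, 1e-20) if sigma is not None else np.full_like(r, 1e-20)
    s = np.maximum(s, 1e-24)
    e = np.zeros_like(r)
    vr = np.zeros_like(r)
    vs = np.zeros_like(r)
    for w, pname in fn.parts:
        prim, needs_sigma = _PRIMITIVES[pname]
        if prim is None:
            ep, vrp, vsp = _gga(pname)(r, s)
        else:
            ep, vrp, vsp = prim(r)
        e += w * ep
        vr += w * vrp
        vs += w * vsp
    e[~mask] = 0.0
    vr[~mask] = 0.0
    vs[~mask] = 0.0
    return e, vr, vs
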