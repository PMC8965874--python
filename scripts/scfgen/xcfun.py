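"""Closed-shell exchange-correlation functionals for the fixture engine.

Energy densities f(rho, gamma) (gamma = |grad rho|^2) are written
symbolically with sympy and the potential ingredients v_rho = df/drho and
v_gamma = df/dgamma are obtained by symbolic differentiation, so energy and
potential are consistent by construction.

B3LYP here is the VWN5-based variant:
    Exc = 0.20 Ex(HF) + 0.80 Ex(LSDA) + 0.72 DeltaEx(B88)
        + 0.19 Ec(VWN5) + 0.81 Ec(LYP)
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

RHO_FLOOR = 1e-12


@lru_cache(maxsize=None)
def _closed_shell_expr():
    rho, gam = sp.symbols("rho gamma", positive=True)

    # --- LSDA exchange (Dirac), closed shell
    cx = sp.Rational(3, 4) * (3 / sp.pi) ** sp.Rational(1, 3)
    f_lda_x = -cx * rho ** sp.Rational(4, 3)

    # --- B88 gradient correction, closed shell
    beta = sp.Float("0.0042")
    rs_ = (rho / 2) ** sp.Rational(4, 3)
    x = (sp.sqrt(gam) / 2) / rs_
    f_b88 = -2 * beta * rs_ * x**2 / (1 + 6 * beta * x * sp.asinh(x))

    # --- VWN5 correlation (paramagnetic)
    A = sp.Float("0.0310907")
    x0 = sp.Float("-0.10498")
    b = sp.Float("3.72744")
    c = sp.Float("12.9352")
    rs = (3 / (4 * sp.pi * rho)) ** sp.Rational(1, 3)
    xv = sp.sqrt(rs)
    X = xv**2 + b * xv + c
    X0 = x0**2 + b * x0 + c
    Q = sp.sqrt(4 * c - b**2)
    ec = A * (
        sp.log(xv**2 / X)
        + 2 * b / Q * sp.atan(Q / (2 * xv + b))
        - b * x0 / X0
        * (
            sp.log((xv - x0) ** 2 / X)
            + 2 * (b + 2 * x0) / Q * sp.atan(Q / (2 * xv + b))
        )
    )
    f_vwn = rho * ec

    # --- LYP correlation, closed shell (Miehlich form)
    a_l = sp.Float("0.04918")
    b_l = sp.Float("0.132")
    c_l = sp.Float("0.2533")
    d_l = sp.Float("0.349")
    CF = sp.Rational(3, 10) * (3 * sp.pi**2) ** sp.Rational(2, 3)
    ra = rho / 2
    rb = rho / 2
    gaa = gam / 4
    gbb = gam / 4
    gt = gam
    r13 = rho ** sp.Rational(-1, 3)
    omega = sp.exp(-c_l * r13) * rho ** sp.Rational(-11, 3) / (1 + d_l * r13)
    delta = c_l * r13 + d_l * r13 / (1 + d_l * r13)
    term1 = -4 * a_l * ra * rb / (rho * (1 + d_l * r13))
    inner = (
        ra * rb
        * (
            2 ** sp.Rational(11, 3) * CF * (ra ** sp.Rational(8, 3) + rb ** sp.Rational(8, 3))
            + (sp.Rational(47, 18) - 7 * delta / 18) * gt
            - (sp.Rational(5, 2) - delta / 18) * (gaa + gbb)
            - (delta - 11) / 9 * (ra * gaa + rb * gbb) / rho
        )
        - sp.Rational(2, 3) * rho**2 * gt
        + (sp.Rational(2, 3) * rho**2 - ra**2) * gbb
        + (sp.Rational(2, 3) * rho**2 - rb**2) * gaa
    )
    f_lyp = term1 - a_l * b_l * omega * inner

    return rho, gam, {
        "lda_x": f_lda_x,
        "b88": f_b88,
        "vwn5": f_vwn,
        "lyp": f_lyp,
    }


@lru_cache(maxsize=None)
def _lambdified(name: str):
    rho, gam, exprs = _closed_shell_expr()
    f = exprs[name]
    fr = sp.diff(f, rho)
    fg = sp.diff(f, gam)
    return (
        sp.lambdify((rho, gam), f, modules="numpy"),
        sp.lambdify((rho, gam), fr, modules="numpy"),
        sp.lambdify((rho, gam), fg, modules="numpy"),
    )


B3LYP_WEIGHTS = {"lda_x": 0.80, "b88": 0.72, "vwn5": 0.19, "lyp": 0.81}
B3LYP_HFX = 0.20


def eval_xc(weights: dict[str, float], rho: np.ndarray, gamma: np.ndarray):
    """Return (energy density, v_rho, v_gamma) arrays for a weighted sum."""
    rho = np.maximum(rho, RHO_FLOOR)
    gamma = np.maximum(gamma, RHO_FLOOR**2)
    e = np.zeros_like(rho)
    vr = np.zeros_like(rho)
    vg = np.zeros_like(rho)
    for name, w in weights.items():
        if w == 0.0:
            continue
        f, fr, fg = _lambdified(name)
        e += w * f(rho, gamma)
        vr += w * fr(rho, gamma)
        vg += w * fg(rho, gamma)
    return e, vr, vg
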