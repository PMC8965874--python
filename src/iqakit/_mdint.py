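"""McMurchie-Davidson expansion coefficients and analytic overlaps.

Only the overlap integrals are needed by the package itself (wavefunction
orthonormality checks, Mulliken-type charges for orbital localization);
heavier one- and two-electron integrals built on the same Hermite expansion
live with the fixture-generation tooling.
"""
from __future__ import annotations

import numpy as np


def e_table(la: int, lb: int, a: float, b: float, ab: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for a 1D Gaussian pair.

    ``i <= la``, ``j <= lb``, ``t <= i + j``; ``ab`` is (A - B) along the axis.
    """
    p = a + b
    mu = a * b / p
    E = np.zeros((la + 1, lb + 1, la + lb + 1))
    E[0, 0, 0] = np.exp(-mu * ab * ab)
    xpa = -b * ab / p  # P - A  (P = (aA + bB)/p, so P-A = -b(A-B)/p)
    xpb = a * ab / p  # P - B
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + j + 1):
                    val = 0.0
                    if t - 1 >= 0:
                        val += E[i - 1, 0, t - 1] / (2.0 * p)
                    val += xpa * E[i - 1, 0, t]
                    if t + 1 <= i - 1:
                        val += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = val
            else:
                for t in range(i + j + 1):
                    val = 0.0
                    if t - 1 >= 0:
                        val += E[i, j - 1, t - 1] / (2.0 * p)
                    val += xpb * E[i, j - 1, t]
                    if t + 1 <= i + j - 1:
                        val += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = val
    return E


def _boys(m_max: int, T: np.ndarray) -> np.ndarray:
    from scipy.special import gamma, gammainc

    T = np.asarray(T, dtype=float)
    out = np.empty((m_max + 1,) + T.shape)
    small = T < 1e-13
    Ts = np.where(small, 1.0, T)
    for m in range(m_max + 1):
        a = m + 0.5
        val = 0.5 * gamma(a) * gammainc(a, Ts) / Ts**a
        out[m] = np.where(small, 1.0 / (2 * m + 1), val)
    return out


def _hermite_coulomb(L, PQ, p):
    """R_{tuv} table (dict keyed (t,u,v) -> (N,)) for exponent p."""
    T = p * np.einsum("ij,ij->i", PQ, PQ)
    F = _boys(L, T)
    levels = [dict() for _ in range(L + 1)]
    pref = np.ones(len(PQ))
    for n in range(L + 1):
        levels[n][(0, 0, 0)] = pref * F[n]
        pref = pref * (-2.0 * p)
    for total in range(1, L + 1):
        for n in range(L - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = PQ[:, 0] * levels[n + 1][(t - 1, u, v)]
                        if t > 1:
                            val += (t - 1) * levels[n + 1][(t - 2, u, v)]
                    elif u > 0:
                        val = PQ[:, 1] * levels[n + 1][(t, u - 1, v)]
                        if u > 1:
                            val += (u - 1) * levels[n + 1][(t, u - 2, v)]
                    else:
                        val = PQ[:, 2] * levels[n + 1][(t, u, v - 1)]
                        if v > 1:
                            val += (v - 1) * levels[n + 1][(t, u, v - 2)]
                    levels[n][(t, u, v)] = val
    return levels[0]


def esp_electronic(basis, dm_cart: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Electronic potential integral of the density matrix at points (au).

    Returns +int rho(r')/|r - r'| dr' (positive magnitude; callers apply
    the electron charge sign).  ``dm_cart`` refers to the Cartesian AO set.
    """
    from .basis import cart_powers, prim_norm

    shells = basis.shells
    points = np.atleast_2d(points)
    offs = np.cumsum([0] + [s.n_cart for s in shells])
    V = np.zeros(len(points))
    for ia, sa in enumerate(shells):
        pa = cart_powers(sa.l)
        for jb, sb in enumerate(shells):
            if jb < ia:
                continue
            pb = cart_powers(sb.l)
            dblock = dm_cart[offs[ia] : offs[ia + 1], offs[jb] : offs[jb + 1]]
            sym = 1.0 if ia == jb else 2.0
            AB = sa.center - sb.center
            L = sa.l + sb.l
            for ea, ca in zip(sa.exps, sa.coefs):
                for eb, cb in zip(sb.exps, sb.coefs):
                    p = ea + eb
                    P = (ea * sa.center + eb * sb.center) / p
                    R = _hermite_coulomb(L, P[None, :] - points, p)
                    Ex = e_table(sa.l, sb.l, ea, eb, AB[0])
                    Ey = e_table(sa.l, sb.l, ea, eb, AB[1])
                    Ez = e_table(sa.l, sb.l, ea, eb, AB[2])
                    pref = 2.0 * np.pi / p * ca * cb * sym
                    for i, (ax, ay, az) in enumerate(pa):
                        na = prim_norm(ea, ax, ay, az)
                        for j, (bx, by, bz) in enumerate(pb):
                            dij = dblock[i, j]
                            if abs(dij) < 1e-14:
                                continue
                            nb = prim_norm(eb, bx, by, bz)
                            acc = np.zeros(len(points))
                            for t in range(ax + bx + 1):
                                ext = Ex[ax, bx, t]
                                if ext == 0.0:
                                    continue
                                for u in range(ay + by + 1):
                                    eyu = Ey[ay, by, u]
                                    if eyu == 0.0:
                                        continue
                                    for v in range(az + bz + 1):
                                        ezv = Ez[az, bz, v]
                                        if ezv == 0.0:
                                            continue
                                        acc += ext * eyu * ezv * R[(t, u, v)]
                            V += pref * dij * na * nb * acc
    return V


def overlap_cart(shells) -> np.ndarray:
    """Overlap matrix over normalized contracted Cartesian AOs."""
    from .basis import cart_powers, prim_norm

    nao = sum(s.n_cart for s in shells)
    S = np.zeros((nao, nao))
    offs = np.cumsum([0] + [s.n_cart for s in shells])
    for isa, sa in enumerate(shells):
        pa = cart_powers(sa.l)
        for isb, sb in enumerate(shells):
            if isb < isa:
                continue
            pb = cart_powers(sb.l)
            AB = sa.center - sb.center
            block = np.zeros((sa.n_cart, sb.n_cart))
            for ka, (aexp, acoef) in enumerate(zip(sa.exps, sa.coefs)):
                for kb, (bexp, bcoef) in enumerate(zip(sb.exps, sb.coefs)):
                    p = aexp + bexp
                    pref = (np.pi / p) ** 1.5
                    Ex = e_table(sa.l, sb.l, aexp, bexp, AB[0])
                    Ey = e_table(sa.l, sb.l, aexp, bexp, AB[1])
                    Ez = e_table(sa.l, sb.l, aexp, bexp, AB[2])
                    for ia, (ax, ay, az) in enumerate(pa):
                        na = prim_norm(aexp, ax, ay, az)
                        for ib, (bx, by, bz) in enumerate(pb):
                            nb = prim_norm(bexp, bx, by, bz)
                            block[ia, ib] += (
                                acoef
                                * bcoef
                                * na
                                * nb
                                * pref
                                * Ex[ax, bx, 0]
                                * Ey[ay, by, 0]
                                * Ez[az, bz, 0]
                            )
            S[offs[isa] : offs[isa + 1], offs[isb] : offs[isb + 1]] = block
            S[offs[isb] : offs[isb + 1], offs[isa] : offs[isa + 1]] = block.T
    return S
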