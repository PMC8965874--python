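"""One- and two-electron Gaussian integrals (McMurchie-Davidson).

Fixture-generation support code: used by the small SCF engine that
produces the packaged wavefunction fixtures.  Not part of the installed
package.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammainc, gamma

from iqakit._mdint import e_table
from iqakit.basis import GaussianBasis, cart_powers, prim_norm


def boys(m_max: int, T: np.ndarray) -> np.ndarray:
    """Boys functions F_m(T) for m = 0..m_max; T is any-shape array.

    Returns array of shape (m_max+1,) + T.shape.
    """
    T = np.asarray(T, dtype=float)
    out = np.empty((m_max + 1,) + T.shape)
    small = T < 1e-13
    Ts = np.where(small, 1.0, T)
    for m in range(m_max + 1):
        a = m + 0.5
        val = 0.5 * gamma(a) * gammainc(a, Ts) / Ts**a
        out[m] = np.where(small, 1.0 / (2 * m + 1), val)
    return out


def hermite_coulomb(L: int, PQ: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """R_{tuv}(omega, PQ) for all t+u+v <= L, vectorized over leading axis.

    PQ: (N, 3); omega: (N,).  Returns dict-backed dense array indexed by
    (t, u, v) -> (N,).
    """
    T = omega * np.einsum("ij,ij->i", PQ, PQ)
    F = boys(L, T)
    # R^n_{000} = (-2 omega)^n F_n
    Rn = {(-1): None}
    levels = [dict() for _ in range(L + 1)]
    pref = np.ones_like(omega)
    for n in range(L + 1):
        levels[n][(0, 0, 0)] = pref * F[n]
        pref = pref * (-2.0 * omega)
    # build upward in t+u+v, downward in n
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


def _herm_list(L: int) -> list[tuple[int, int, int]]:
    return [
        (t, u, v)
        for total in range(L + 1)
        for t in range(total + 1)
        for u in range(total - t + 1)
        for v in [total - t - u]
    ]


class _PairData:
    """Hermite expansion of one shell pair, all primitive pairs at once."""

    def __init__(self, sa, sb):
        self.la, self.lb = sa.l, sb.l
        self.L = sa.l + sb.l
        pa = cart_powers(sa.l)
        pb = cart_powers(sb.l)
        self.ncart = len(pa) * len(pb)
        A, B = sa.center, sb.center
        AB = A - B
        exps = [(ea, eb) for ea in sa.exps for eb in sb.exps]
        coefs = [
            (ca, cb)
            for ca in sa.coefs
            for cb in sb.coefs
        ]
        self.p = np.array([ea + eb for ea, eb in exps])
        self.P = np.array(
            [(ea * A + eb * B) / (ea + eb) for ea, eb in exps]
        )
        herms = _herm_list(self.L)
        self.herms = herms
        K = len(exps)
        self.E = np.zeros((K, self.ncart, len(herms)))
        hindex = {h: i for i, h in enumerate(herms)}
        for k, ((ea, eb), (ca, cb)) in enumerate(zip(exps, coefs)):
            Ex = e_table(sa.l, sb.l, ea, eb, AB[0])
            Ey = e_table(sa.l, sb.l, ea, eb, AB[1])
            Ez = e_table(sa.l, sb.l, ea, eb, AB[2])
            m = 0
            for ia, (ax, ay, az) in enumerate(pa):
                na = prim_norm(ea, ax, ay, az)
                for ib, (bx, by, bz) in enumerate(pb):
                    nb = prim_norm(eb, bx, by, bz)
                    cc = ca * cb * na * nb
                    for t in range(ax + bx + 1):
                        for u in range(ay + by + 1):
                            for v in range(az + bz + 1):
                                self.E[k, m, hindex[(t, u, v)]] = (
                                    cc * Ex[ax, bx, t] * Ey[ay, by, u] * Ez[az, bz, v]
                                )
                    m += 1


def overlap_kinetic(basis: GaussianBasis):
    """Cartesian overlap and kinetic matrices."""
    shells = basis.shells
    nao = basis.n_cart
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    offs = np.cumsum([0] + [s.n_cart for s in shells])
    for i, sa in enumerate(shells):
        pa = cart_powers(sa.l)
        for j, sb in enumerate(shells):
            if j < i:
                continue
            pb = cart_powers(sb.l)
            AB = sa.center - sb.center
            sblk = np.zeros((sa.n_cart, sb.n_cart))
            tblk = np.zeros((sa.n_cart, sb.n_cart))
            for ea, ca in zip(sa.exps, sa.coefs):
                for eb, cb in zip(sb.exps, sb.coefs):
                    p = ea + eb
                    pref = (np.pi / p) ** 1.5
                    # 1D overlap tables with extended b-range for kinetic
                    Es = [
                        e_table(sa.l, sb.l + 2, ea, eb, AB[ax]) for ax in range(3)
                    ]

                    def s1d(ax, ia, ib):
                        if ia < 0 or ib < 0:
                            return 0.0
                        return Es[ax][ia, ib, 0]

                    for ia, apow in enumerate(pa):
                        na = prim_norm(ea, *apow)
                        for ib, bpow in enumerate(pb):
                            nb = prim_norm(eb, *bpow)
                            cc = ca * cb * na * nb * pref
                            s3 = [s1d(ax, apow[ax], bpow[ax]) for ax in range(3)]
                            sblk[ia, ib] += cc * s3[0] * s3[1] * s3[2]
                            # kinetic: -1/2 sum_ax d2/dx2 acting on b
                            ttot = 0.0
                            for ax in range(3):
                                bx = bpow[ax]
                                t1 = eb * (2 * bx + 1) * s1d(ax, apow[ax], bx)
                                t2 = -2.0 * eb**2 * s1d(ax, apow[ax], bx + 2)
                                t3 = (
                                    -0.5 * bx * (bx - 1) * s1d(ax, apow[ax], bx - 2)
                                    if bx >= 2
                                    else 0.0
                                )
                                other = 1.0
                                for ay in range(3):
                                    if ay != ax:
                                        other *= s3[ay]
                                ttot += (t1 + t2 + t3) * other
                            tblk[ia, ib] += cc * ttot
            S[offs[i] : offs[i + 1], offs[j] : offs[j + 1]] = sblk
            S[offs[j] : offs[j + 1], offs[i] : offs[i + 1]] = sblk.T
            T[offs[i] : offs[i + 1], offs[j] : offs[j + 1]] = tblk
            T[offs[j] : offs[j + 1], offs[i] : offs[i + 1]] = tblk.T
    return S, T


def nuclear_attraction(basis: GaussianBasis, charges, positions) -> np.ndarray:
    """Matrix of sum_C -q_C <a| 1/|r-R_C| |b> (point charges at positions)."""
    shells = basis.shells
    nao = basis.n_cart
    V = np.zeros((nao, nao))
    offs = np.cumsum([0] + [s.n_cart for s in shells])
    positions = np.atleast_2d(np.asarray(positions, float))
    charges = np.asarray(charges, float)
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j < i:
                continue
            pd = _PairData(sa, sb)
            blk = np.zeros((sa.n_cart, sb.n_cart))
            for k in range(len(pd.p)):
                p = pd.p[k]
                PQ = pd.P[k][None, :] - positions  # (nC, 3)
                R = hermite_coulomb(pd.L, PQ, np.full(len(positions), p))
                Rmat = np.stack([R[h] for h in pd.herms])  # (nherm, nC)
                contrib = (2.0 * np.pi / p) * pd.E[k] @ (Rmat @ (-charges))
                blk += contrib.reshape(sa.n_cart, sb.n_cart)
            V[offs[i] : offs[i + 1], offs[j] : offs[j + 1]] = blk
            V[offs[j] : offs[j + 1], offs[i] : offs[i + 1]] = blk.T
    return V


def eri_cart(basis: GaussianBasis) -> np.ndarray:
    """Full (ab|cd) tensor over Cartesian AOs.  Fixture-scale only."""
    shells = basis.shells
    nao = basis.n_cart
    offs = np.cumsum([0] + [s.n_cart for s in shells])
    pairs = {}
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j <= i:
                pairs[(i, j)] = _PairData(sa, sb)
    eri = np.zeros((nao, nao, nao, nao))
    keys = sorted(pairs)
    for (i, j) in keys:
        ab = pairs[(i, j)]
        for (k, l) in keys:
            if (k, l) > (i, j):
                continue
            cd = pairs[(k, l)]
            L = ab.L + cd.L
            Ka, Kc = len(ab.p), len(cd.p)
            # all primitive-pair combinations
            pi = np.repeat(ab.p, Kc)
            pk = np.tile(cd.p, Ka)
            omega = pi * pk / (pi + pk)
            PQ = np.repeat(ab.P, Kc, axis=0) - np.tile(cd.P, (Ka, 1))
            R = hermite_coulomb(L, PQ, omega)
            pref = 2.0 * np.pi**2.5 / (pi * pk * np.sqrt(pi + pk))
            # build R matrix between hermite components of ab and cd
            nh_ab, nh_cd = len(ab.herms), len(cd.herms)
            Rmat = np.empty((Ka * Kc, nh_ab, nh_cd))
            for ha, (t, u, v) in enumerate(ab.herms):
                for hc, (t2, u2, v2) in enumerate(cd.herms):
                    sgn = (-1.0) ** (t2 + u2 + v2)
                    Rmat[:, ha, hc] = sgn * R[(t + t2, u + u2, v + v2)]
            Rmat *= pref[:, None, None]
            Rmat = Rmat.reshape(Ka, Kc, nh_ab, nh_cd)
            # contract: out[m, n] = E_ab[ka,m,ha] Rmat[ka,kc,ha,hc] E_cd[kc,n,hc]
            tmp = np.einsum("amh,achk->mck", ab.E, Rmat, optimize=True)
            blk = np.einsum("mck,cnk->mn", tmp, cd.E, optimize=True)
            blk = blk.reshape(
                shells[i].n_cart, shells[j].n_cart, shells[k].n_cart, shells[l].n_cart
            )
            _fill_eri(eri, blk, offs, i, j, k, l)
    return eri


def _fill_eri(eri, blk, offs, i, j, k, l):
    si, sj, sk, sl = (slice(offs[x], offs[x + 1]) for x in (i, j, k, l))
    eri[si, sj, sk, sl] = blk
    eri[sj, si, sk, sl] = blk.transpose(1, 0, 2, 3)
    eri[si, sj, sl, sk] = blk.transpose(0, 1, 3, 2)
    eri[sj, si, sl, sk] = blk.transpose(1, 0, 3, 2)
    eri[sk, sl, si, sj] = blk.transpose(2, 3, 0, 1)
    eri[sl, sk, si, sj] = blk.transpose(3, 2, 0, 1)
    eri[sk, sl, sj, si] = blk.transpose(2, 3, 1, 0)
    eri[sl, sk, sj, si] = blk.transpose(3, 2, 1, 0)
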