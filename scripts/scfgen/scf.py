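"""Minimal closed-shell RHF / RKS engine for fixture generation.

Small-molecule, fixture-scale only: full in-core ERI tensor, DIIS, Becke
quadrature for the XC term, optional external point charges (electronic
embedding).  Produces the committed wavefunction fixtures together with
manifest oracles (energies, dipoles, density samples).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from iqakit._mdint import e_table
from iqakit.basis import GaussianBasis, cart_powers, prim_norm

from .integrals import eri_cart, nuclear_attraction, overlap_kinetic
from .xcfun import B3LYP_HFX, B3LYP_WEIGHTS, eval_xc

BRAGG = {1: 0.35, 2: 0.31, 6: 0.70, 7: 0.65, 8: 0.60, 9: 0.50, 16: 1.00, 17: 1.00}
ANG = 1.0 / 0.529177


def dipole_matrices(basis: GaussianBasis) -> np.ndarray:
    """AO matrices of x, y, z about the origin; shape (3, nao, nao)."""
    shells = basis.shells
    nao = basis.n_cart
    D = np.zeros((3, nao, nao))
    offs = np.cumsum([0] + [s.n_cart for s in shells])
    for i, sa in enumerate(shells):
        pa = cart_powers(sa.l)
        for j, sb in enumerate(shells):
            if j < i:
                continue
            pb = cart_powers(sb.l)
            AB = sa.center - sb.center
            blk = np.zeros((3, sa.n_cart, sb.n_cart))
            for ea, ca in zip(sa.exps, sa.coefs):
                for eb, cb in zip(sb.exps, sb.coefs):
                    p = ea + eb
                    P = (ea * sa.center + eb * sb.center) / p
                    pref = (np.pi / p) ** 1.5
                    Es = [e_table(sa.l, sb.l, ea, eb, AB[ax]) for ax in range(3)]
                    for ia, apow in enumerate(pa):
                        na = prim_norm(ea, *apow)
                        for ib, bpow in enumerate(pb):
                            nb = prim_norm(eb, *bpow)
                            cc = ca * cb * na * nb * pref
                            s = [Es[ax][apow[ax], bpow[ax], 0] for ax in range(3)]
                            for ax in range(3):
                                e1 = Es[ax][apow[ax], bpow[ax], 1] if apow[ax] + bpow[ax] >= 1 else 0.0
                                mom = e1 / (2 * p) * (2 * p) + P[ax] * s[ax]
                                # note: int x Lambda_t dx = delta_t1 /(2p)*? see docs
                                mom = _moment1(Es[ax], apow[ax], bpow[ax], p, P[ax])
                                other = 1.0
                                for ay in range(3):
                                    if ay != ax:
                                        other *= s[ay]
                                blk[ax, ia, ib] += cc * mom * other
            D[:, offs[i] : offs[i + 1], offs[j] : offs[j + 1]] = blk
            D[:, offs[j] : offs[j + 1], offs[i] : offs[i + 1]] = blk.transpose(0, 2, 1)
    return D


def _moment1(E, ia, ib, p, Px):
    """1D first moment <x> in units of the 1D overlap prefactor sqrt(pi/p)."""
    e0 = E[ia, ib, 0]
    e1 = E[ia, ib, 1] if ia + ib >= 1 else 0.0
    # int x G dx = (P E_0 + E_1) sqrt(pi/p); here normalized to exclude sqrt(pi/p)
    return Px * e0 + e1


# ----------------------------------------------------------------------
# Becke molecular quadrature
# ----------------------------------------------------------------------

def _gauss_cheby_radial(n: int, rm: float):
    """Becke's radial map r = rm (1+x)/(1-x) on Gauss-Chebyshev-2 nodes."""
    i = np.arange(1, n + 1)
    x = np.cos(i * np.pi / (n + 1))
    w = np.pi / (n + 1) * np.sin(i * np.pi / (n + 1)) ** 2
    r = rm * (1 + x) / (1 - x)
    # dr/dx = 2 rm / (1-x)^2 ; chebyshev weight function correction
    drdx = 2 * rm / (1 - x) ** 2
    wr = w / np.sqrt(1 - x**2) * drdx * r**2
    return r, wr


def _angular_product(n_theta: int):
    """Gauss-Legendre x uniform-phi product grid on the unit sphere."""
    xt, wt = np.polynomial.legendre.leggauss(n_theta)
    n_phi = 2 * n_theta
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    wphi = 2 * np.pi / n_phi
    ct = xt
    st = np.sqrt(1 - ct**2)
    pts = []
    wts = []
    for c, s, w in zip(ct, st, wt):
        for f in phi:
            pts.append((s * np.cos(f), s * np.sin(f), c))
            wts.append(w * wphi)
    return np.array(pts), np.array(wts)


def becke_grid(numbers, coords, n_rad=80, n_theta=20):
    """Molecular integration grid with Becke fuzzy-cell weights."""
    coords = np.atleast_2d(coords)
    nat = len(numbers)
    ang_pts, ang_wts = _angular_product(n_theta)
    all_pts, all_wts = [], []
    for ia in range(nat):
        rm = BRAGG.get(int(numbers[ia]), 0.8) * ANG
        if int(numbers[ia]) != 1:
            rm *= 0.5
        r, wr = _gauss_cheby_radial(n_rad, rm)
        pts = (
            coords[ia][None, None, :]
            + r[:, None, None] * ang_pts[None, :, :]
        ).reshape(-1, 3)
        wts = (wr[:, None] * ang_wts[None, :]).reshape(-1)
        if nat > 1:
            wts = wts * _becke_weights(pts, coords, ia)
        all_pts.append(pts)
        all_wts.append(wts)
    return np.vstack(all_pts), np.concatenate(all_wts)


def _becke_weights(pts, coords, ia):
    nat = len(coords)
    d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)  # (N, nat)
    P = np.ones((len(pts), nat))
    for i in range(nat):
        for j in range(nat):
            if i == j:
                continue
            Rij = np.linalg.norm(coords[i] - coords[j])
            mu = (d[:, i] - d[:, j]) / Rij
            f = mu
            for _ in range(3):
                f = 1.5 * f - 0.5 * f**3
            P[:, i] *= 0.5 * (1 - f)
    return P[:, ia] / P.sum(axis=1)


# ----------------------------------------------------------------------
# SCF
# ----------------------------------------------------------------------

@dataclass
class SCFResult:
    energy: float
    mo_coeff: np.ndarray       # in the AO representation of `basis` (sph if requested)
    mo_energy: np.ndarray
    mo_occ: np.ndarray
    components: dict
    converged: bool


def run_scf(
    numbers,
    coords,
    basis: GaussianBasis,
    method: str = "HF",
    charge: int = 0,
    point_charges=None,  # (q, xyz bohr) tuple of arrays
    grid_level=(80, 20),
    conv_tol: float = 1e-9,
    max_cycle: int = 80,
    verbose: bool = False,
) -> SCFResult:
    numbers = np.asarray(numbers, float)
    coords = np.atleast_2d(np.asarray(coords, float))
    nelec = int(round(numbers.sum())) - charge
    if nelec % 2:
        raise ValueError("closed-shell engine: even electron count required")
    nocc = nelec // 2

    S_c, T_c = overlap_kinetic(basis)
    V_c = nuclear_attraction(basis, numbers, coords)
    if point_charges is not None:
        qmm, rmm = point_charges
        V_c = V_c + nuclear_attraction(basis, np.asarray(qmm, float), rmm)
    eri = eri_cart(basis)

    if basis.spherical:
        Tr = basis.sph_transform()
        S = Tr @ S_c @ Tr.T
        Tmat = Tr @ T_c @ Tr.T
        V = Tr @ V_c @ Tr.T
        eri = np.einsum("pi,ijkl->pjkl", Tr, eri, optimize=True)
        eri = np.einsum("qj,pjkl->pqkl", Tr, eri, optimize=True)
        eri = np.einsum("rk,pqkl->pqrl", Tr, eri, optimize=True)
        eri = np.einsum("sl,pqrl->pqrs", Tr, eri, optimize=True)
    else:
        S, Tmat, V = S_c, T_c, V_c

    hcore = Tmat + V
    enuc = 0.0
    for i in range(len(numbers)):
        for j in range(i + 1, len(numbers)):
            enuc += numbers[i] * numbers[j] / np.linalg.norm(coords[i] - coords[j])
    e_nuc_pc = 0.0
    if point_charges is not None:
        qmm, rmm = point_charges
        for i in range(len(numbers)):
            for q, r in zip(qmm, np.atleast_2d(rmm)):
                e_nuc_pc += numbers[i] * q / np.linalg.norm(coords[i] - r)

    is_dft = method.upper() != "HF"
    hfx = B3LYP_HFX if is_dft else 1.0
    weights = B3LYP_WEIGHTS if is_dft else {}

    if is_dft:
        gpts, gwts = becke_grid(numbers, coords, *grid_level)

    # symmetric orthogonalization
    ev, U = np.linalg.eigh(S)
    keep = ev > 1e-9
    X = U[:, keep] / np.sqrt(ev[keep])

    # core guess
    F = hcore.copy()
    D = None
    diis_F, diis_err = [], []
    e_old = 0.0
    converged = False
    for cycle in range(max_cycle):
        Fp = X.T @ F @ X
        mo_e, Cp = np.linalg.eigh(Fp)
        C = X @ Cp
        Cocc = C[:, :nocc]
        D = 2.0 * Cocc @ Cocc.T

        J = np.einsum("ijkl,kl->ij", eri, D, optimize=True)
        K = np.einsum("ikjl,kl->ij", eri, D, optimize=True)
        F = hcore + J - 0.5 * hfx * K
        exc = 0.0
        if is_dft:
            Vxc, exc = _xc_matrix(basis, C[:, :nocc], weights, gpts, gwts)
            F = F + Vxc
        e_elec = np.sum(D * hcore) + 0.5 * np.sum(D * J) - 0.25 * hfx * np.sum(D * K) + exc
        e_tot = e_elec + enuc + e_nuc_pc

        err = F @ D @ S - S @ D @ F
        diis_F.append(F.copy())
        diis_err.append(err.copy())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if cycle > 0:
            F = _diis_extrapolate(diis_F, diis_err)
        if verbose:
            print(f"  cycle {cycle:3d}  E = {e_tot:.10f}  dE = {e_tot - e_old:.2e}")
        if abs(e_tot - e_old) < conv_tol and cycle > 2:
            converged = True
            break
        e_old = e_tot

    mo_occ = np.zeros(C.shape[1])
    mo_occ[:nocc] = 2.0
    comps = {
        "e_kinetic": float(np.sum(D * Tmat)),
        "e_nuc_attraction": float(np.sum(D * V)),
        "e_coulomb": float(0.5 * np.sum(D * J)),
        "e_hfx": float(-0.25 * hfx * np.sum(D * K)),
        "e_xc_grid": float(exc),
        "e_nuclear_repulsion": float(enuc),
        "e_nuc_point_charges": float(e_nuc_pc),
    }
    return SCFResult(float(e_tot), C, mo_e, mo_occ, comps, converged)


def _xc_matrix(basis, Cocc, weights, pts, wts, chunk=40000):
    nao = Cocc.shape[0]
    Vxc = np.zeros((nao, nao))
    exc = 0.0
    Tr = basis.sph_transform() if basis.spherical else None
    for i0 in range(0, len(pts), chunk):
        p = pts[i0 : i0 + chunk]
        w = wts[i0 : i0 + chunk]
        out = basis.eval_ao(p, deriv=1)
        ao, dao = out
        phi = Cocc.T @ ao                       # (nocc, N)
        dphi = np.einsum("um,aun->amn", Cocc, dao)
        rho = 2.0 * np.einsum("mn,mn->n", phi, phi)
        grad = 2.0 * 2.0 * np.einsum("mn,amn->an", phi, dphi)
        gamma = np.einsum("an,an->n", grad, grad)
        e, vr, vg = eval_xc(weights, rho, gamma)
        exc += np.dot(w, e)
        # GGA potential: sum_n w [ vr phi_u phi_v + 2 vg grad_rho . (phi_u d phi_v + phi_v d phi_u)]
        wvr = w * vr
        Vxc += (ao * wvr) @ ao.T
        wvg = 2.0 * w * vg
        gvec = grad * wvg  # (3, N)
        tmp = np.einsum("an,aun->un", gvec, dao)
        Vxc += tmp @ ao.T + ao @ tmp.T
    return Vxc, exc


def _diis_extrapolate(Fs, errs):
    n = len(Fs)
    B = np.empty((n + 1, n + 1))
    B[-1, :] = -1.0
    B[:, -1] = -1.0
    B[-1, -1] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = np.sum(errs[i] * errs[j])
    rhs = np.zeros(n + 1)
    rhs[-1] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return Fs[-1]
    return sum(ci * Fi for ci, Fi in zip(c, Fs))
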