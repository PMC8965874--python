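"""IQA atomic net energies and diatomic interaction terms.

The quantum energy of a closed-shell determinant is decomposed over QTAIM
basins as

    E = sum_I E_net^I + sum_{I<J} E_int^IJ

with E_net^I = T_I + V_ne^II + V_ee^II (kinetic, own-nucleus attraction and
intra-basin electron repulsion) and E_int^IJ split into a classical
electrostatic part and an exchange(-correlation) part,
E_int^IJ = E_ele^IJ + E_xc^IJ.  The pair density uses the closed-shell
prescription rho2(1,2) = rho(1) rho(2) - 1/2 rho1(1,2)^2; for DFT densities
the same HF-like exchange is built from the KS rho1 and subsequently scaled
by one global factor so that the SCF total energy is recovered exactly.

Numerics: intra-basin double integrals use the Laplace (single-center)
expansion of 1/r12 up to the preset's lambda_max with radius-sorted prefix
sums; two-basin integrals are direct six-dimensional double-grid sums on
the coarser pair node set, with an optional multipolar electrostatic mode
beyond 5 au and E_xc zeroed beyond 17 au.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .qtaim import BasinGrid
from .wavefunction import Wavefunction

logger = logging.getLogger(__name__)

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


MULTIPOLAR_RMIN = 5.0   # au; below this the bipolar expansion is refused
XC_CUTOFF = 17.0        # au; E_xc neglected beyond this separation


# ----------------------------------------------------------------------
# term matrix
# ----------------------------------------------------------------------

@dataclass
class IQATermMatrix:
    """All atomic and pairwise IQA terms of one system (hartree).

    Pairwise matrices are symmetric; the electrostatic/xc split satisfies
    E_int = E_ele + E_xc exactly by construction.  The reconstruction
    residual against the SCF reference is recorded, never absorbed.
    """

    n_atoms: int
    kinetic: np.ndarray               # (n,) T_I
    v_ne_own: np.ndarray              # (n,) own-nucleus attraction
    vee_intra_coul: np.ndarray        # (n,)
    vee_intra_xc: np.ndarray          # (n,) unscaled HF-like xc
    v_nn: np.ndarray                  # (n, n)
    v_en_cross: np.ndarray            # (n, n) nucleus I with electrons in J
    vee_coul: np.ndarray              # (n, n)
    vee_xc: np.ndarray                # (n, n) unscaled
    xc_scale: float = 1.0
    scf_reference: float | None = None
    qmmm_ele: np.ndarray | None = None   # (n_qm, n_mm)
    qmmm_vdw: np.ndarray | None = None   # (n_qm, n_mm), hartree
    disp: np.ndarray | None = None       # (n, n) pairwise dispersion
    mm_site_index: np.ndarray | None = None  # map of qmmm columns to site ids
    meta: dict = field(default_factory=dict)

    # -- derived ----------------------------------------------------------
    @property
    def e_net(self) -> np.ndarray:
        return (
            self.kinetic
            + self.v_ne_own
            + self.vee_intra_coul
            + self.xc_scale * self.vee_intra_xc
        )

    @property
    def e_ele(self) -> np.ndarray:
        return self.v_nn + self.v_en_cross + self.v_en_cross.T + self.vee_coul

    @property
    def e_xc(self) -> np.ndarray:
        return self.xc_scale * self.vee_xc

    @property
    def e_int(self) -> np.ndarray:
        out = self.e_ele + self.e_xc
        if self.disp is not None:
            out = out + self.disp
        return out

    def qmmm_total(self) -> float:
        tot = 0.0
        if self.qmmm_ele is not None:
            tot += float(self.qmmm_ele.sum())
        if self.qmmm_vdw is not None:
            tot += float(self.qmmm_vdw.sum())
        return tot

    def reconstructed_total(self) -> float:
        iu = np.triu_indices(self.n_atoms, 1)
        return float(self.e_net.sum() + self.e_int[iu].sum() + self.qmmm_total())

    @property
    def residual(self) -> float | None:
        if self.scf_reference is None:
            return None
        return self.reconstructed_total() - self.scf_reference


# ----------------------------------------------------------------------
# real solid harmonics
# ----------------------------------------------------------------------

def real_sph_table(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Racah-normalized real spherical harmonics, ((lmax+1)^2, N)."""
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty(((lmax + 1) ** 2, len(dirs)))
    k = 0
    for l in range(lmax + 1):
        racah = np.sqrt(4.0 * np.pi / (2 * l + 1))
        for m in range(-l, l + 1):
            if m == 0:
                v = np.real(sph_harm_y(l, 0, theta, phi))
            elif m > 0:
                v = np.sqrt(2.0) * (-1.0) ** m * np.real(
                    sph_harm_y(l, m, theta, phi)
                )
            else:
                v = np.sqrt(2.0) * (-1.0) ** (-m) * np.imag(
                    sph_harm_y(l, -m, theta, phi)
                )
            out[k] = racah * v
            k += 1
    return out


# ----------------------------------------------------------------------
# Laplace expansion with radius-sorted prefix sums
# ----------------------------------------------------------------------

def _spline_cumint_matrix(r: np.ndarray) -> np.ndarray:
    """M with (M f)[k] ~ integral_0^{r_k} f(r') dr' by cubic-spline quadrature."""
    from scipy.interpolate import CubicSpline

    n = len(r)
    M = np.empty((n, n))
    eye = np.eye(n)
    for j in range(n):
        anti = CubicSpline(r, eye[j]).antiderivative()
        M[:, j] = anti(r) - anti(r[0])
    return M


class IntraBasinIntegrator:
    """Expansion potentials of basin-restricted charge distributions.

    The basin sources are sampled on a product mesh: a dense common radial
    mesh times the basin's fine angular rays.  For every spherical-harmonic
    channel the radial potential pieces

        V(r, Omega) = sum_lm Z_lm(Omega) [ r^-(l+1) U_lm(r) + r^l W_lm(r) ]

    are assembled from per-ray cumulative integrals evaluated *exactly* at
    each ray's basin-boundary cap (cubic-spline cumulative quadrature plus
    a local end correction), so the sharp basin boundary never meets the
    radial interpolation.  Intra-basin 1/r12 double integrals are then
    smooth single-center field integrals of these potentials over the
    basin's own exact-cap node set, and the same kernels serve the
    two-basin (cross) terms.
    """

    def __init__(self, wfn, grid_atom, lmax: int, n_rad: int = 240):
        self.lmax = lmax
        self.ag = grid_atom
        t = (np.arange(1, n_rad + 1)) / (n_rad + 1.0)
        self.r = grid_atom.rmax * t**2
        self.M = _spline_cumint_matrix(self.r)
        self.omega = self.M[-1]
        dirs = grid_atom.ang_dirs
        self.na = len(dirs)
        self.nr = n_rad
        self.Y = real_sph_table(lmax, dirs)            # (nlm, na)
        self.wa = grid_atom.ang_wts
        caps = np.minimum(grid_atom.ray_caps, self.r[-1])
        self.caps = caps
        self.mask = self.r[:, None] <= caps[None, :]   # (nr, na)
        self.ic = np.clip(np.searchsorted(self.r, caps) - 1, 0, n_rad - 2)
        pts = (
            grid_atom.center[None, None, :]
            + self.r[:, None, None] * dirs[None, :, :]
        ).reshape(-1, 3)
        self.phi = wfn.mo_values(pts)                  # (nocc, nr*na)
        self.l_of = np.concatenate(
            [np.full(2 * l + 1, l) for l in range(lmax + 1)]
        )

    # ------------------------------------------------------------------
    def _cum_with_cap(self, V: np.ndarray):
        """Per-ray cumulative integrals of smooth radial integrands.

        V has shape (nr, na*nfun-ish); returns (Cnode, Ccap): cumulative at
        every mesh radius and, per column, the cumulative at that ray's
        exact cap radius (local linear end-correction).
        """
        Cnode = self.M @ V
        ic = self._col_ic
        cols = np.arange(V.shape[1])
        r = self.r
        dr_seg = r[ic + 1] - r[ic]
        d = self._col_caps - r[ic]
        f0 = V[ic, cols]
        f1 = V[ic + 1, cols]
        slope = (f1 - f0) / dr_seg
        Ccap = Cnode[ic, cols] + f0 * d + 0.5 * slope * d**2
        return Cnode, Ccap

    def kernels_for(self, fvals: np.ndarray):
        """Vector potential kernels for stacked sources (nfun, nr*na).

        Returns per-(l,m) pairs of vector-valued cubic splines (U, W).
        Source 0 is expected to be the density; its channel magnitudes set
        the roundoff guard for all sources.
        """
        from scipy.interpolate import CubicSpline

        fvals = np.asarray(fvals)
        if fvals.ndim == 1:
            fvals = fvals[None]
        nfun = fvals.shape[0]
        F = fvals.reshape(nfun, self.nr, self.na)
        # column layout for the cumulative helper: (na * nfun)
        self._col_ic = np.tile(self.ic, nfun)
        self._col_caps = np.tile(self.caps, nfun)
        r = self.r
        waY = self.Y * self.wa[None, :]                # (nlm, na)
        kernels = [None] * len(self.l_of)
        k0 = 0
        for l in range(self.lmax + 1):
            nm = 2 * l + 1
            # --- U: integrand f * s^(l+2)
            VU = (F * r[None, :, None] ** (l + 2)).transpose(1, 0, 2).reshape(
                self.nr, nfun * self.na
            )
            # reorder columns as (nfun, na) blocks to match _col arrays
            CnodeU, CcapU = self._cum_with_cap(VU)
            CnodeU = CnodeU.reshape(self.nr, nfun, self.na)
            CcapU = CcapU.reshape(nfun, self.na)
            TU = np.where(
                self.mask[:, None, :], CnodeU, CcapU[None, :, :]
            )
            # --- W: integrand f * s^(1-l), clipped where the negative
            # power would amplify roundoff (the r^l prefactor kills the
            # genuine contribution there)
            s_clip = 10.0 ** (-12.0 / max(l - 1, 1)) if l >= 2 else 0.0
            rw = np.where(r >= s_clip, r ** (1 - l), 0.0)
            VW = (F * rw[None, :, None]).transpose(1, 0, 2).reshape(
                self.nr, nfun * self.na
            )
            CnodeW, CcapW = self._cum_with_cap(VW)
            CnodeW = CnodeW.reshape(self.nr, nfun, self.na)
            CcapW = CcapW.reshape(nfun, self.na)
            TW = self.mask[:, None, :] * (CcapW[None, :, :] - CnodeW)
            for m in range(nm):
                Zl = waY[k0 + m]
                U = TU @ Zl                            # (nr, nfun)
                W = TW @ Zl
                if l > 0:
                    # zero the leading small-radius run of each U column:
                    # genuine U ~ r^(l+3) there and utterly negligible,
                    # while cumulative-quadrature roundoff in that region
                    # would contaminate the premultiplied spline
                    lead = np.maximum.accumulate(np.abs(U), axis=0)
                    U[lead < 1e-13 * np.abs(U).max(axis=0)[None, :]] = 0.0
                # spline the *premultiplied* radial factors: both are
                # bounded, so spline leakage into small-radius regions is
                # never amplified by negative powers at evaluation time
                Uh = U * (r ** -(l + 1.0))[:, None]
                Wh = W * (r ** float(l))[:, None]
                kernels[k0 + m] = (CubicSpline(r, Uh), CubicSpline(r, Wh))
            k0 += nm
        return kernels

    def potential_at(self, kernels, points: np.ndarray,
                     chunk: int = 60000) -> np.ndarray:
        """Expansion potentials (nfun, N) of the stacked sources at points."""
        pts = np.atleast_2d(points)
        nfun = kernels[0][0](self.r[0]).shape[-1]
        V = np.empty((nfun, len(pts)))
        rmax = self.r[-1]
        rmin = self.r[0]
        for i0 in range(0, len(pts), chunk):
            rel = pts[i0 : i0 + chunk] - self.ag.center
            rr = np.linalg.norm(rel, axis=1)
            dirs = rel / np.maximum(rr[:, None], 1e-300)
            Y = real_sph_table(self.lmax, dirs)
            rc = np.clip(rr, rmin, rmax)
            inside = rr < rmax
            ratio = rc / np.maximum(rr, rmin)  # <= 1; != 1 only beyond rmax
            ratio_in = np.minimum(rr / rc, 1.0)
            v = np.zeros((nfun, len(rr)))
            for k, l in enumerate(self.l_of):
                Uk, Wk = kernels[k]
                term = ratio ** (l + 1) * Uk(rc).T
                term += ratio_in**l * (Wk(rc).T * inside)
                v += Y[k][None, :] * term
            V[:, i0 : i0 + len(rr)] = v
        return V


# ----------------------------------------------------------------------
# pair kernels (direct 6D sums)
# ----------------------------------------------------------------------

@njit(cache=True)
def _coulomb_kernel(p1, w1, f1, p2, w2, f2):
    tot = 0.0
    for i in range(p1.shape[0]):
        xi, yi, zi = p1[i, 0], p1[i, 1], p1[i, 2]
        a = w1[i] * f1[i]
        if a == 0.0:
            continue
        acc = 0.0
        for j in range(p2.shape[0]):
            dx = xi - p2[j, 0]
            dy = yi - p2[j, 1]
            dz = zi - p2[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-10:
                continue
            acc += w2[j] * f2[j] / r
        tot += a * acc
    return tot


@njit(cache=True)
def _exchange_kernel(p1, w1, phi1, p2, w2, phi2):
    # integral of -1/2 rho1(1,2)^2 / r12 over basin1 x basin2
    nocc = phi1.shape[0]
    tot = 0.0
    for i in range(p1.shape[0]):
        xi, yi, zi = p1[i, 0], p1[i, 1], p1[i, 2]
        for j in range(p2.shape[0]):
            dx = xi - p2[j, 0]
            dy = yi - p2[j, 1]
            dz = zi - p2[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < 1e-10:
                continue
            s = 0.0
            for m in range(nocc):
                s += phi1[m, i] * phi2[m, j]
            rho1 = 2.0 * s
            tot += -0.5 * w1[i] * w2[j] * rho1 * rho1 / r
    return tot


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

class _AtomWork:
    """Cached per-basin machinery shared by net and diatomic terms.

    Sources: spherical-harmonic radial profiles of the basin-restricted
    density and of every kept MO-pair product, with their expansion
    potentials bundled into vector splines (index 0 = density, then
    ``pair_keys`` order).  Field side: samples on the basin's own coarse
    pair nodes (the cross integrals are smooth single-center quadratures).
    """

    def __init__(self, wfn, ag, lmax, mos):
        self.ag = ag
        self.mos = list(mos)
        self.lap = IntraBasinIntegrator(wfn, ag, lmax)
        _, occ = wfn.occupied()
        rho_mesh = occ @ (self.lap.phi * self.lap.phi)
        self.pair_keys = [
            (mi, mj) for mi in self.mos for mj in self.mos if mj >= mi
        ]
        stack = np.vstack(
            [rho_mesh[None]]
            + [
                (self.lap.phi[mi] * self.lap.phi[mj])[None]
                for (mi, mj) in self.pair_keys
            ]
        )
        self.kernels = self.lap.kernels_for(stack)
        # samples for field-side integrals
        self.rho_fine = wfn.density(ag.points)
        self.phi_fine = wfn.mo_values(ag.points)
        self.rho_field = wfn.density(ag.pair_points)
        self.phi_field = wfn.mo_values(ag.pair_points)
        # expansion potentials of all sources on the basin's own fine nodes
        self.V_fine = self.lap.potential_at(self.kernels, ag.points)
        # unhalved self-integrals S = int int_X f f / r12
        self.S_self = float(
            np.dot(ag.weights * self.rho_fine, self.V_fine[0])
        )
        self.T_self = {}
        for idx, key in enumerate(self.pair_keys):
            f = self.phi_fine[key[0]] * self.phi_fine[key[1]]
            self.T_self[key] = float(
                np.dot(ag.weights * f, self.V_fine[1 + idx])
            )

    def intra_coulomb(self) -> float:
        return 0.5 * self.S_self

    def intra_exchange(self) -> float:
        xc = 0.0
        for (mi, mj), T in self.T_self.items():
            xc += -1.0 * T * (1.0 if mi == mj else 2.0)
        return float(xc)


def _atom_works(wfn, grid, orbital_subsets=None):
    _, occ = wfn.occupied()
    lmax = grid.preset.lmax_out
    works = {}
    for ag in grid.atoms:
        if ag.n_owned == 0:
            continue
        mos = (
            orbital_subsets[ag.atom]
            if orbital_subsets is not None
            else range(len(occ))
        )
        works[ag.atom] = _AtomWork(wfn, ag, lmax, mos)
    return works


def net_energies(
    wfn: Wavefunction,
    grid: BasinGrid,
    orbital_subsets: list | None = None,
    works: dict | None = None,
) -> dict:
    """Per-atom net-energy components T_I, V_ne^II, V_ee^II(coul/xc)."""
    if wfn is None:
        raise ValueError("net energies require a wavefunction")
    if not wfn.is_closed_shell:
        raise ValueError("closed-shell wavefunctions only")
    n = len(grid.atoms)
    T = np.zeros(n)
    Vne = np.zeros(n)
    Jintra = np.zeros(n)
    Xintra = np.zeros(n)
    if works is None:
        works = _atom_works(wfn, grid, orbital_subsets)
    for ag in grid.atoms:
        ia = ag.atom
        if ag.n_owned == 0:
            continue
        wk = works[ia]
        pts, wts = ag.points, ag.weights
        T[ia] = np.dot(wts, wfn.ked(pts))
        d = np.linalg.norm(pts - wfn.coords[ia], axis=1)
        Vne[ia] = -wfn.numbers[ia] * np.dot(wts, wk.rho_fine / np.maximum(d, 1e-12))
        Jintra[ia] = wk.intra_coulomb()
        Xintra[ia] = wk.intra_exchange()
    return {
        "kinetic": T,
        "v_ne_own": Vne,
        "vee_intra_coul": Jintra,
        "vee_intra_xc": Xintra,
    }


def diatomic_terms(
    wfn: Wavefunction,
    grid: BasinGrid,
    pair: tuple[int, int],
    mode: str = "exact",
    orbital_subsets: list | None = None,
    works: dict | None = None,
) -> dict:
    """Interaction components of one atom pair (hartree).

    mode "exact": electron-electron terms by the single-center expansion
    potentials of each basin evaluated on the partner basin, symmetrized.
    mode "multipolar": classical term from basin multipole moments (valid
    beyond 5 au only); E_xc is zeroed beyond 17 au in either mode.
    """
    i, j = pair
    agi, agj = grid.atoms[i], grid.atoms[j]
    Ri, Rj = wfn.coords[i], wfn.coords[j]
    Rij = float(np.linalg.norm(Ri - Rj))
    Zi, Zj = wfn.numbers[i], wfn.numbers[j]
    out = {"v_nn": Zi * Zj / Rij if Rij > 0 else 0.0}

    if mode == "multipolar" and Rij < MULTIPOLAR_RMIN:
        logger.warning(
            "multipolar mode refused at R=%.2f au (< %.1f); falling back to exact",
            Rij, MULTIPOLAR_RMIN,
        )
        mode = "exact"

    if works is None:
        works = {}
        for ia in (i, j):
            if grid.atoms[ia].n_owned:
                _, occ = wfn.occupied()
                mos = (
                    orbital_subsets[ia]
                    if orbital_subsets is not None
                    else range(len(occ))
                )
                works[ia] = _AtomWork(wfn, grid.atoms[ia], grid.preset.lmax_out, mos)

    def v_nuc(ag, wk, Z, Rnuc, nuc_in_basin=False):
        if ag.n_owned == 0:
            return 0.0
        if nuc_in_basin:
            # the attracting nucleus lies inside this basin (its own basin
            # is empty): integrate the singular kernel on a grid centered
            # at the nucleus, subtracting the other basins' contributions
            total = _full_space_nuclear(wfn, Rnuc)
            other = 0.0
            for agk in grid.atoms:
                if agk.atom == ag.atom or agk.n_owned == 0:
                    continue
                dk = np.linalg.norm(agk.points - Rnuc, axis=1)
                rhok = wfn.density(agk.points)
                other += np.dot(agk.weights, rhok / np.maximum(dk, 1e-12))
            return -Z * (total - other)
        d = np.linalg.norm(ag.points - Rnuc, axis=1)
        return -Z * np.dot(ag.weights, wk.rho_fine / np.maximum(d, 1e-12))

    empty = agi.n_owned == 0 or agj.n_owned == 0
    bonded = any(
        set(cp.atoms) == {i, j} for cp in grid.critical_points.bonds()
    )
    if mode == "exact":
        out["v_en"] = (
            v_nuc(agj, works.get(j), Zi, Ri, nuc_in_basin=agi.n_owned == 0)
            if agj.n_owned else 0.0
        )
        out["v_ne"] = (
            v_nuc(agi, works.get(i), Zj, Rj, nuc_in_basin=agj.n_owned == 0)
            if agi.n_owned else 0.0
        )
        if empty:
            coul, xc = 0.0, 0.0
        elif bonded and Rij < MULTIPOLAR_RMIN and grid.assigner is not None:
            # close basins sharing an interatomic surface: difference of
            # self-integrals over I, J and their union, whose expansion
            # potentials are only ever evaluated interior to their source.
            # (For well-separated pairs the direct expansion route below is
            # already essentially exact and resolves a compact far partner
            # better than a single-center union grid.)
            coul, xc = _cross_ee_union(
                wfn, grid, (i, j), works, want_xc=Rij <= XC_CUTOFF
            )
        else:
            coul, xc = _cross_ee(
                works[i], works[j], want_xc=Rij <= XC_CUTOFF
            )
        out["vee_coul"] = coul
        out["vee_xc"] = xc
    else:
        ele = _multipolar_electrostatics(wfn, grid, i, j)
        # report the whole classical term through vee_coul bookkeeping
        out["v_en"] = 0.0
        out["v_ne"] = 0.0
        out["vee_coul"] = ele - out["v_nn"]
        if Rij > XC_CUTOFF or empty:
            out["vee_xc"] = 0.0
        else:
            _, out["vee_xc"] = _cross_ee(works[i], works[j], want_coul=False)
    out["e_ele"] = out["v_nn"] + out["v_en"] + out["v_ne"] + out["vee_coul"]
    out["e_xc"] = out["vee_xc"]
    out["e_int"] = out["e_ele"] + out["e_xc"]
    return out


def _full_space_nuclear(wfn, Rnuc, n_rad=180, n_ang=590, rmax=20.0):
    """integral of rho(r)/|r - Rnuc| over all space, nucleus-centered grid."""
    from .qtaim import angular_product_grid, radial_segment

    r, wr = radial_segment(n_rad, 0.0, rmax, cusp=True)
    ang, wa = angular_product_grid(n_ang)
    pts = (Rnuc[None, None, :] + r[:, None, None] * ang[None, :, :]).reshape(-1, 3)
    wts = (wr[:, None] * wa[None, :]).ravel()
    rr = np.repeat(r, len(ang))
    rho = wfn.density(pts)
    return float(np.dot(wts, rho / np.maximum(rr, 1e-12)))


def _cross_ee_union(wfn, grid, pair, works, want_xc=True):
    """Two-basin ee terms as differences of self-integrals.

    S_IJ = 1/2 (S_{I u J} - S_I - S_J); exact for disjoint basins and
    numerically robust because every expansion potential is evaluated
    inside its own source region.
    """
    i, j = pair
    wk_i, wk_j = works[i], works[j]
    ug = grid.union_grid(wfn, (i, j))
    lap = IntraBasinIntegrator(wfn, ug, grid.preset.lmax_out)
    _, occ = wfn.occupied()
    rho_mesh = occ @ (lap.phi * lap.phi)
    common = [k for k in wk_i.pair_keys if k in wk_j.T_self]
    funs = [rho_mesh]
    if want_xc:
        funs += [lap.phi[mi] * lap.phi[mj] for (mi, mj) in common]
    kernels = lap.kernels_for(np.vstack([f[None] for f in funs]))
    V = lap.potential_at(kernels, ug.points)
    rho_u = wfn.density(ug.points)
    S_uu = float(np.dot(ug.weights * rho_u, V[0]))
    coul = 0.5 * (S_uu - wk_i.S_self - wk_j.S_self)
    xc = 0.0
    if want_xc:
        phi_u = wfn.mo_values(ug.points)
        for idx, key in enumerate(common):
            f = phi_u[key[0]] * phi_u[key[1]]
            T_uu = float(np.dot(ug.weights * f, V[1 + idx]))
            t_cross = 0.5 * (T_uu - wk_i.T_self[key] - wk_j.T_self[key])
            xc += -2.0 * t_cross * (1.0 if key[0] == key[1] else 2.0)
    return float(coul), float(xc)


def _cross_ee(wk_i, wk_j, want_coul=True, want_xc=True):
    """Symmetrized inter-basin Coulomb and exchange energies."""
    V_at_j = wk_i.lap.potential_at(wk_i.kernels, wk_j.ag.pair_points)
    V_at_i = wk_j.lap.potential_at(wk_j.kernels, wk_i.ag.pair_points)
    wj = wk_j.ag.pair_weights
    wi = wk_i.ag.pair_weights
    coul = 0.0
    if want_coul:
        coul = 0.5 * (
            np.dot(wj * wk_j.rho_field, V_at_j[0])
            + np.dot(wi * wk_i.rho_field, V_at_i[0])
        )
    xc = 0.0
    if want_xc:
        common = sorted(set(wk_i.mos) & set(wk_j.mos))
        for key_idx, (mi, mj) in enumerate(wk_i.pair_keys):
            if mi not in common or mj not in common:
                continue
            # position of the same pair in wk_j's stack
            try:
                kj = wk_j.pair_keys.index((mi, mj))
            except ValueError:
                continue
            f_j = wk_j.phi_field[mi] * wk_j.phi_field[mj]
            f_i = wk_i.phi_field[mi] * wk_i.phi_field[mj]
            e = 0.5 * (
                np.dot(wj * f_j, V_at_j[1 + key_idx])
                + np.dot(wi * f_i, V_at_i[1 + kj])
            )
            xc += -2.0 * e * (1.0 if mi == mj else 2.0)
    return float(coul), float(xc)


# ----------------------------------------------------------------------
# brute-force six-dimensional pair sums (independent oracle route)
# ----------------------------------------------------------------------

def pair_coulomb_direct(wfn, agi, agj) -> float:
    """Direct double-grid sum of rho(1) rho(2)/r12 on the pair node sets."""
    if agi.n_owned == 0 or agj.n_owned == 0:
        return 0.0
    rho_i = wfn.density(agi.pair_points)
    rho_j = wfn.density(agj.pair_points)
    return float(
        _coulomb_kernel(
            agi.pair_points, agi.pair_weights, rho_i,
            agj.pair_points, agj.pair_weights, rho_j,
        )
    )


def pair_exchange_direct(wfn, agi, agj) -> float:
    """Direct double-grid sum of -1/2 rho1(1,2)^2 / r12."""
    if agi.n_owned == 0 or agj.n_owned == 0:
        return 0.0
    phi_i = wfn.mo_values(agi.pair_points)
    phi_j = wfn.mo_values(agj.pair_points)
    return float(
        _exchange_kernel(
            agi.pair_points, agi.pair_weights, np.ascontiguousarray(phi_i),
            agj.pair_points, agj.pair_weights, np.ascontiguousarray(phi_j),
        )
    )


def _multipolar_electrostatics(wfn, grid, i, j, lmax=None):
    """Classical interaction of two basins via single-center multipoles.

    The potential of basin J (nucleus + electronic multipoles about its
    nucleus) is evaluated on basin I's nodes and vice versa; the average
    of the two one-sided results is returned.
    """
    if lmax is None:
        lmax = grid.preset.lmax_out

    def one_side(src, dst):
        ag_s, ag_d = grid.atoms[src], grid.atoms[dst]
        Rs = wfn.coords[src]
        Zs = wfn.numbers[src]
        d_rel = ag_s.points - Rs
        r = np.linalg.norm(d_rel, axis=1)
        dirs = d_rel / np.maximum(r[:, None], 1e-300)
        Y = real_sph_table(lmax, dirs)
        rho_s = wfn.density(ag_s.points) * ag_s.weights
        lof = np.concatenate([np.full(2 * l + 1, l) for l in range(lmax + 1)])
        Q = np.array(
            [np.dot(rho_s * r ** lof[k], Y[k]) for k in range(len(lof))]
        ) * -1.0  # electrons carry negative charge
        # evaluate at destination nodes + destination nucleus
        def potential(points):
            rel = points - Rs
            rr = np.linalg.norm(rel, axis=1)
            dd = rel / np.maximum(rr[:, None], 1e-300)
            Yd = real_sph_table(lmax, dd)
            V = Zs / rr
            for k in range(len(lof)):
                V = V + Q[k] * Yd[k] / rr ** (lof[k] + 1)
            return V
        rho_d = wfn.density(ag_d.points) * ag_d.weights
        e = -np.dot(rho_d, potential(ag_d.points))
        e += wfn.numbers[dst] * potential(wfn.coords[dst][None])[0]
        return e

    return 0.5 * (one_side(i, j) + one_side(j, i))


def build_term_matrix(
    wfn: Wavefunction,
    grid: BasinGrid,
    mode: str = "exact",
    screen_threshold: float | None = None,
    scf_reference: float | None = None,
) -> IQATermMatrix:
    """Full IQA term matrix: net energies plus all pairs."""
    n = len(grid.atoms)
    subsets = None
    if screen_threshold is not None:
        overlaps = [
            atomic_overlap_diag(wfn, grid, a) for a in range(n)
        ]
        subsets = screen_orbitals(grid, overlaps, screen_threshold)
    works = _atom_works(wfn, grid, subsets)
    comps = net_energies(wfn, grid, orbital_subsets=subsets, works=works)
    v_nn = np.zeros((n, n))
    v_en = np.zeros((n, n))
    vee_c = np.zeros((n, n))
    vee_x = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            Rij = np.linalg.norm(wfn.coords[i] - wfn.coords[j])
            pair_mode = mode
            if mode == "auto":
                pair_mode = "multipolar" if Rij > MULTIPOLAR_RMIN else "exact"
            t = diatomic_terms(wfn, grid, (i, j), mode=pair_mode,
                               orbital_subsets=subsets, works=works)
            v_nn[i, j] = v_nn[j, i] = t["v_nn"]
            v_en[i, j] = t["v_en"]
            v_en[j, i] = t["v_ne"]
            vee_c[i, j] = vee_c[j, i] = t["vee_coul"]
            vee_x[i, j] = vee_x[j, i] = t["vee_xc"]
    tm = IQATermMatrix(
        n_atoms=n,
        kinetic=comps["kinetic"],
        v_ne_own=comps["v_ne_own"],
        vee_intra_coul=comps["vee_intra_coul"],
        vee_intra_xc=comps["vee_intra_xc"],
        v_nn=v_nn,
        v_en_cross=v_en,
        vee_coul=vee_c,
        vee_xc=vee_x,
        scf_reference=scf_reference if scf_reference is not None else wfn.energy,
        meta={"preset": grid.preset.name, "mode": mode,
              "screen_threshold": screen_threshold},
    )
    return tm


# ----------------------------------------------------------------------
# orbital localization and screening
# ----------------------------------------------------------------------

def localize_orbitals(wfn: Wavefunction, method: str = "pipek-mezey",
                      max_sweeps: int = 60, tol: float = 1e-10) -> Wavefunction:
    """Pipek-Mezey localization of the occupied space (Mulliken charges).

    Returns a new wavefunction whose occupied MOs span the same space
    (orthogonal transform); the total density is unchanged.
    """
    if method != "pipek-mezey":
        raise ValueError(f"unknown localization method {method!r}")
    if not wfn.is_closed_shell:
        raise ValueError("closed-shell wavefunctions only")
    S = wfn.basis.overlap()
    occ_mask = wfn.mo_occ > 1e-12
    C = wfn.mo_coeff[:, occ_mask].copy()
    nocc = C.shape[1]
    if nocc == 1:
        return wfn
    ao_atom = _ao_atoms(wfn.basis)
    atoms = sorted(set(ao_atom))

    def mull(Ci, Cj):
        """Per-atom Mulliken transition charges Q_A^(ij)."""
        SCj = S @ Cj
        SCi = S @ Ci
        contrib = 0.5 * (Ci * SCj + Cj * SCi)
        return np.array([contrib[ao_atom == A].sum() for A in atoms])

    def functional():
        SC = S @ C
        val = 0.0
        for A in atoms:
            qa = np.einsum("ui,ui->i", C[ao_atom == A], SC[ao_atom == A])
            val += np.sum(qa**2)
        return val

    p_old = functional()
    for sweep in range(max_sweeps):
        for i in range(nocc):
            for j in range(i + 1, nocc):
                Qii = mull(C[:, i], C[:, i])
                Qjj = mull(C[:, j], C[:, j])
                Qij = mull(C[:, i], C[:, j])
                A = float(np.sum(Qij**2 - 0.25 * (Qii - Qjj) ** 2))
                B = float(np.sum(Qij * (Qii - Qjj)))
                if abs(A) < 1e-14 and abs(B) < 1e-14:
                    continue
                gamma = 0.25 * np.arctan2(B, -A)
                c, s = np.cos(gamma), np.sin(gamma)
                ci = C[:, i].copy()
                C[:, i] = c * ci + s * C[:, j]
                C[:, j] = -s * ci + c * C[:, j]
        p_new = functional()
        if p_new < p_old - 1e-9:
            logger.warning("PM functional decreased in sweep %d", sweep)
        if abs(p_new - p_old) < tol:
            break
        p_old = p_new
    else:
        logger.warning("PM localization not converged in %d sweeps", max_sweeps)
    newC = wfn.mo_coeff.copy()
    newC[:, occ_mask] = C
    out = Wavefunction(
        numbers=wfn.numbers, coords=wfn.coords, basis=wfn.basis,
        mo_coeff=newC, mo_occ=wfn.mo_occ.copy(), energy=wfn.energy,
        method=wfn.method, functional=wfn.functional,
        n_electrons_declared=wfn.n_electrons_declared,
        source=wfn.source, meta={**wfn.meta, "localized": "pipek-mezey"},
    )
    return out


def _ao_atoms(basis) -> np.ndarray:
    out = []
    for sh in basis.shells:
        n = sh.n_sph if basis.spherical else sh.n_cart
        out += [sh.atom] * n
    return np.array(out)


def atomic_overlap_diag(wfn, grid, atom) -> np.ndarray:
    ag = grid.atoms[atom]
    if ag.n_owned == 0:
        _, occ = wfn.occupied()
        return np.zeros(len(occ))
    phi = wfn.mo_values(ag.points)
    return np.einsum("mn,n,mn->m", phi, ag.weights, phi)


def screen_orbitals(grid, overlaps, threshold: float = 1e-6) -> list:
    """Per-basin occupied-orbital subsets by diagonal basin overlap."""
    subsets = []
    for diag in overlaps:
        subsets.append([int(i) for i in np.where(diag > threshold)[0]])
    union = set().union(*[set(s) for s in subsets]) if subsets else set()
    nmo = len(overlaps[0]) if overlaps else 0
    missing = set(range(nmo)) - union
    for m in missing:
        # never drop an orbital entirely: attach to its largest basin
        best = int(np.argmax([o[m] for o in overlaps]))
        subsets[best].append(m)
        subsets[best].sort()
    return subsets


# ----------------------------------------------------------------------
# DFT xc scaling, additivity, reconstruction
# ----------------------------------------------------------------------

def scale_dft_xc(terms: IQATermMatrix, scf_total: float) -> IQATermMatrix:
    """One global factor on all xc terms so the SCF total is recovered."""
    iu = np.triu_indices(terms.n_atoms, 1)
    xc_sum = terms.vee_intra_xc.sum() + terms.vee_xc[iu].sum()
    if abs(xc_sum) < 1e-8:
        logger.warning("total xc ~ 0; scaling impossible, residual retained")
        terms.meta["xc_scaling"] = "impossible"
        return terms
    non_xc = (
        terms.kinetic.sum()
        + terms.v_ne_own.sum()
        + terms.vee_intra_coul.sum()
        + terms.v_nn[iu].sum()
        + (terms.v_en_cross + terms.v_en_cross.T)[iu].sum()
        + terms.vee_coul[iu].sum()
        + terms.qmmm_total()
    )
    if terms.disp is not None:
        non_xc += terms.disp[iu].sum()
    kappa = (scf_total - non_xc) / xc_sum
    terms.xc_scale = float(kappa)
    terms.scf_reference = scf_total
    terms.meta["xc_scaling"] = "global"
    return terms


def additive_energies(terms: IQATermMatrix, convention: str = "half_share"):
    """Per-atom additive energies; their sum reproduces the total exactly.

    half_share: E_add^I = E_net^I + 1/2 sum_J E_int^IJ + 1/2 sum_J' E^IJ'
    qm_full_qmmm: the QM-MM pair terms are ascribed wholly to the QM atom.
    """
    if convention not in ("half_share", "qm_full_qmmm"):
        raise ValueError(f"unknown convention {convention!r}")
    e_add = terms.e_net.copy()
    e_int = terms.e_int
    e_add += 0.5 * (e_int.sum(axis=1) - np.diag(e_int))
    qm_share = np.zeros(terms.n_atoms)
    mm_share = 0.0
    if terms.qmmm_ele is not None or terms.qmmm_vdw is not None:
        per_qm = np.zeros(terms.n_atoms)
        if terms.qmmm_ele is not None:
            per_qm += terms.qmmm_ele.sum(axis=1)
        if terms.qmmm_vdw is not None:
            per_qm += terms.qmmm_vdw.sum(axis=1)
        if convention == "half_share":
            qm_share = 0.5 * per_qm
            mm_share = 0.5 * per_qm.sum()
        else:
            qm_share = per_qm
    e_add += qm_share
    return e_add, mm_share


def reconstruct_total(terms: IQATermMatrix):
    """(total, residual vs the SCF reference)."""
    total = terms.reconstructed_total()
    residual = None if terms.scf_reference is None else total - terms.scf_reference
    return total, residual
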