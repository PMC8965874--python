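"""Implicit-solvent energies decomposed to atoms (PB + nonpolar terms).

Polar part: finite-difference Poisson solves on a cubic lattice with a
sharp dielectric boundary at the (optionally probe-inflated) atomic radii;
the reaction-field potential is the difference between the solvated and
uniform-dielectric solves on the same grid (which cancels the grid
self-energy), and the polar energy is 1/2 sum q_I Phi_RF(R_I)
(linear-response convention, recorded in output metadata).

Nonpolar part: cavity term p * V_I over solvent-accessible volumes, and an
attractive dispersion term obtained from the divergence-theorem surface
form of the exterior volume integral of the solute-solvent r^-6
interaction over the solvent-accessible surface (SAS), pairwise in (atom
providing the potential, atom owning the surface patch) and symmetrized.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg

from .sites import SiteSet
from .units import BOHR_TO_ANGSTROM, COULOMB_KCAL
from .wavefunction import Wavefunction

logger = logging.getLogger(__name__)

__all__ = [
    "PBSpec", "ReactionField", "solve_reaction_field", "polar_atomic_terms",
    "chelpg_charges", "SurfaceMesh", "sas_surface", "sav_volumes",
    "cavity_energy", "dispersion_surface_terms", "atomic_solvation",
    "SolvationTerms",
]

WATER_NUMBER_DENSITY = 0.03343       # A^-3
WATER_LJ_EPS = 0.1520                # kcal/mol (three-site water oxygen)
WATER_LJ_RMIN2 = 1.7683              # A


@dataclass
class PBSpec:
    """Finite-difference Poisson settings."""

    spacing: float = 0.33            # A
    eps_solute: float = 1.0
    eps_solvent: float = 80.0
    ionic_strength: float = 0.0      # only 0 (pure Poisson) supported
    probe_radius: float = 1.4        # A; inflates the dielectric boundary
    padding: float = 9.0             # A of box margin around the solute
    tol: float = 1e-8
    max_iter: int = 4000

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if not self.eps_solvent > self.eps_solute >= 1.0:
            raise ValueError("need eps_solvent > eps_solute >= 1")
        if self.ionic_strength != 0.0:
            raise ValueError("only null ionic strength (pure Poisson) supported")


@dataclass
class ReactionField:
    phi_rf: np.ndarray               # kcal/(mol e) at atomic positions
    iterations: tuple
    residuals: tuple
    spec: PBSpec


def _dielectric_faces(origin, shape, h, centers, radii, eps_in, eps_out):
    """Face dielectrics along each axis from the sharp sphere-union boundary."""
    eps_faces = []
    for axis in range(3):
        sh = list(shape)
        sh[axis] += 1
        ax = [np.arange(s) for s in sh]
        shift = np.zeros(3)
        shift[axis] -= 0.5 * h
        pts_axes = np.meshgrid(*ax, indexing="ij")
        coords = [origin[k] + pts_axes[k] * h for k in range(3)]
        coords[axis] = coords[axis] - 0.5 * h + 0.5 * h  # face centers offset
        # face midpoint sits between cell centers along `axis`
        coords[axis] = origin[axis] + (pts_axes[axis] - 0.5) * h
        inside = np.zeros(sh, dtype=bool)
        for c, R in zip(centers, radii):
            d2 = (
                (coords[0] - c[0]) ** 2
                + (coords[1] - c[1]) ** 2
                + (coords[2] - c[2]) ** 2
            )
            inside |= d2 < R * R
        eps_faces.append(np.where(inside, eps_in, eps_out))
    return eps_faces


def _solve_poisson(origin, shape, h, q_grid, eps_faces, boundary, tol, max_iter):
    """CG solve of the 7-point variable-dielectric Poisson equation.

    ``eps_faces[axis]`` has one extra entry along ``axis``: the face
    between cells i-1 and i sits at index i.  Dirichlet ghost values from
    ``boundary`` (per axis, (lo_plane, hi_plane)) enter the right side.
    """
    n = int(np.prod(shape))
    lin = np.arange(n).reshape(shape)
    rhs = 4.0 * np.pi * q_grid / h
    diag = np.zeros(shape)
    rows, cols, vals = [], [], []
    for axis in range(3):
        e = eps_faces[axis]
        sl_cells = lambda s: tuple(
            s if a == axis else slice(None) for a in range(3)
        )
        elo = e[sl_cells(slice(0, shape[axis]))]
        ehi = e[sl_cells(slice(1, shape[axis] + 1))]
        diag += elo + ehi
        # couplings between cell i and i+1 through the shared face
        c_lo = lin[sl_cells(slice(0, -1))].ravel()
        c_hi = lin[sl_cells(slice(1, None))].ravel()
        e_int = ehi[sl_cells(slice(0, -1))].ravel()
        rows += [c_lo, c_hi]
        cols += [c_hi, c_lo]
        vals += [-e_int, -e_int]
        # Dirichlet ghost planes
        lo_plane, hi_plane = boundary[axis]
        rhs[sl_cells(slice(0, 1))] += (
            elo[sl_cells(slice(0, 1))] * lo_plane[None, ...].reshape(
                rhs[sl_cells(slice(0, 1))].shape
            )
        )
        rhs[sl_cells(slice(-1, None))] += (
            ehi[sl_cells(slice(-1, None))] * hi_plane[None, ...].reshape(
                rhs[sl_cells(slice(-1, None))].shape
            )
        )
    A = sparse.csr_matrix(
        (
            np.concatenate(vals + [diag.ravel()]),
            (
                np.concatenate(rows + [np.arange(n)]),
                np.concatenate(cols + [np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )
    M = sparse.diags(1.0 / diag.ravel())
    u, info = cg(A, rhs.ravel(), rtol=tol, maxiter=max_iter, M=M)
    scale = max(np.linalg.norm(rhs), 1e-300)
    res = float(np.linalg.norm(A @ u - rhs.ravel()) / scale)
    if info != 0:
        raise RuntimeError(
            f"Poisson solver did not converge (info={info}, residual={res:.2e})"
        )
    return u.reshape(shape), res


def _coulomb_boundary(origin, shape, h, charges, centers, eps):
    """Dirichlet ghost-plane values q/(eps r) outside the six box faces."""
    out = []
    for axis in range(3):
        other = [a for a in range(3) if a != axis]
        g1, g2 = np.meshgrid(
            origin[other[0]] + np.arange(shape[other[0]]) * h,
            origin[other[1]] + np.arange(shape[other[1]]) * h,
            indexing="ij",
        )
        planes = []
        for side in (0, 1):
            coord_axis = origin[axis] + (-1 if side == 0 else shape[axis]) * h
            v = np.zeros_like(g1)
            for q, c in zip(charges, centers):
                d2 = (coord_axis - c[axis]) ** 2
                d2 = d2 + (g1 - c[other[0]]) ** 2 + (g2 - c[other[1]]) ** 2
                v += q / (eps * np.maximum(np.sqrt(d2), 1e-6))
            planes.append(v)
        out.append(planes)
    return out


def solve_reaction_field(sites: SiteSet, spec: PBSpec | None = None) -> ReactionField:
    """Reaction-field potential at the atomic positions.

    Two finite-difference solves on the same grid and charges (solvated
    dielectric map and uniform solute dielectric); their difference at the
    atoms removes the grid self-energy.
    """
    if spec is None:
        spec = PBSpec()
    charges = sites.require_charges()
    radii = sites.require_radii() + spec.probe_radius
    xyz = sites.coords * BOHR_TO_ANGSTROM
    h = spec.spacing
    lo = xyz.min(axis=0) - spec.padding
    hi = xyz.max(axis=0) + spec.padding
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / h)) + 1 for k in range(3))
    origin = lo
    for k in range(3):
        if np.any(xyz[:, k] < origin[k]) or np.any(
            xyz[:, k] > origin[k] + (shape[k] - 1) * h
        ):
            raise ValueError("atom outside the finite-difference box")

    # trilinear charge spreading
    q_grid = np.zeros(shape)
    frac = (xyz - origin) / h
    i0 = np.floor(frac).astype(int)
    t = frac - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                np.add.at(
                    q_grid,
                    (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz),
                    w * charges,
                )
    # q_grid holds charge per cell; the discrete equation is
    # sum_faces eps (u_c - u_nb) = 4 pi q_cell / h

    eps_faces_solv = _dielectric_faces(
        origin, shape, h, xyz, radii, spec.eps_solute, spec.eps_solvent
    )
    eps_faces_vac = [np.full_like(e, spec.eps_solute) for e in eps_faces_solv]
    bc_solv = _coulomb_boundary(origin, shape, h, charges, xyz, spec.eps_solvent)
    bc_vac = _coulomb_boundary(origin, shape, h, charges, xyz, spec.eps_solute)
    u_solv, r1 = _solve_poisson(
        origin, shape, h, q_grid, eps_faces_solv, bc_solv, spec.tol, spec.max_iter
    )
    u_vac, r2 = _solve_poisson(
        origin, shape, h, q_grid, eps_faces_vac, bc_vac, spec.tol, spec.max_iter
    )

    # trilinear readback of the difference
    du = u_solv - u_vac
    phi = np.zeros(len(xyz))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[:, 0] if dx else 1 - t[:, 0])
                    * (t[:, 1] if dy else 1 - t[:, 1])
                    * (t[:, 2] if dz else 1 - t[:, 2])
                )
                phi += w * du[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    phi *= COULOMB_KCAL
    if not np.all(np.isfinite(phi)):
        raise RuntimeError("non-finite reaction-field potential")
    return ReactionField(phi_rf=phi, iterations=(None, None),
                         residuals=(r1, r2), spec=spec)


def polar_atomic_terms(sites: SiteSet, rf: ReactionField) -> np.ndarray:
    """Per-atom polar solvation energies 1/2 q_I Phi_RF(R_I), kcal/mol."""
    q = sites.require_charges()
    return 0.5 * q * rf.phi_rf


# ----------------------------------------------------------------------
# ESP-fitted charges
# ----------------------------------------------------------------------

_VDW_EXCLUSION = {
    "H": 1.45, "He": 1.45, "C": 1.5, "N": 1.7, "O": 1.7, "F": 1.7,
    "S": 1.8, "P": 1.8, "Cl": 1.8, "Zn": 1.6, "Mg": 1.6,
}


def chelpg_charges(
    wfn: Wavefunction,
    mm_sites: SiteSet | None = None,
    total_charge: float | None = None,
    spacing: float = 0.4,
    shell_max: float = 2.8,
    exclusion: dict | None = None,
) -> np.ndarray:
    """Grid-based ESP-fitted atomic charges with a total-charge constraint.

    ESP points live on a cubic lattice in the shell between the element
    exclusion radii and ``shell_max`` (A) from the nearest atom; points
    inside the exclusion radius of an MM site (if given) are dropped too.
    The electronic ESP is the analytic one-electron potential integral of
    the density.  Least squares with a Lagrange total-charge constraint;
    the constraint holds to machine precision.
    """
    from .units import element_symbol

    excl = dict(_VDW_EXCLUSION)
    if exclusion:
        excl.update(exclusion)
    xyz = wfn.coords * BOHR_TO_ANGSTROM
    syms = [element_symbol(int(z)) for z in wfn.numbers]
    rex = np.array([excl.get(s, 1.6) for s in syms])
    lo = xyz.min(axis=0) - shell_max
    hi = xyz.max(axis=0) + shell_max
    axes = [np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(G[:, None, :] - xyz[None, :, :], axis=2)  # (P, nat) A
    keep = (d > rex[None, :]).all(axis=1) & (d.min(axis=1) <= shell_max)
    if mm_sites is not None and len(mm_sites):
        mm_xyz = mm_sites.coords * BOHR_TO_ANGSTROM
        dmm = np.linalg.norm(G[:, None, :] - mm_xyz[None, :, :], axis=2)
        keep &= (dmm > 1.6).all(axis=1)
    G = G[keep]
    d = d[keep]
    if len(G) < wfn.n_atoms + 1:
        raise ValueError("ESP grid too sparse for a stable fit")

    # molecular ESP in e/A units (kcal factor cancels in the fit);
    # electronic part from the analytic one-electron potential integral
    from ._mdint import esp_electronic

    pts_bohr = G / BOHR_TO_ANGSTROM
    v_nuc = (wfn.numbers[None, :] / d).sum(axis=1)  # e/A
    C, occ = wfn.occupied()
    dm = (C * occ) @ C.T
    if wfn.basis.spherical:
        T = wfn.basis.sph_transform()
        dm = T.T @ dm @ T
    v_el = -esp_electronic(wfn.basis, dm, pts_bohr)   # e/bohr
    v_el = v_el / BOHR_TO_ANGSTROM                    # -> e/A
    esp = v_nuc + v_el

    A = 1.0 / d                       # (P, nat), e/A per unit charge
    if total_charge is None:
        total_charge = float(round(wfn.numbers.sum() - wfn.n_electrons))
    nat = wfn.n_atoms
    kkt = np.zeros((nat + 1, nat + 1))
    kkt[:nat, :nat] = 2.0 * A.T @ A
    kkt[:nat, nat] = 1.0
    kkt[nat, :nat] = 1.0
    rhs = np.concatenate([2.0 * A.T @ esp, [total_charge]])
    try:
        sol = np.linalg.solve(kkt, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("rank-deficient ESP design matrix") from exc
    return sol[:nat]


# ----------------------------------------------------------------------
# solvent-accessible surface and volume
# ----------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Per-atom SAS point sets with element areas and outward normals."""

    points: list           # per atom: (n_s, 3) A
    normals: list          # per atom: (n_s, 3)
    areas: list            # per atom: (n_s,) A^2
    exposed_area: np.ndarray
    radii: np.ndarray      # inflated radii, A
    volumes: np.ndarray | None = None


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sas_surface(sites: SiteSet, probe: float = 1.4, n_points: int = 960) -> SurfaceMesh:
    """Shrake-Rupley-style exposed surface on a deterministic lattice."""
    radii = sites.require_radii() + probe
    xyz = sites.coords * BOHR_TO_ANGSTROM
    unit = _fibonacci_sphere(n_points)
    pts, nrm, areas = [], [], []
    exposed = np.zeros(len(sites))
    for i in range(len(sites)):
        p = xyz[i] + radii[i] * unit
        keep = np.ones(len(p), dtype=bool)
        for j in range(len(sites)):
            if j == i:
                continue
            keep &= np.linalg.norm(p - xyz[j], axis=1) >= radii[j]
        a = 4.0 * np.pi * radii[i] ** 2 / n_points
        pts.append(p[keep])
        nrm.append(unit[keep])
        areas.append(np.full(int(keep.sum()), a))
        exposed[i] = a * keep.sum()
    return SurfaceMesh(points=pts, normals=nrm, areas=areas,
                       exposed_area=exposed, radii=radii)


def sav_volumes(sites: SiteSet, probe: float = 1.4, resolution: float = 0.4) -> np.ndarray:
    """Per-atom solvent-accessible volumes by voxel assignment.

    Voxels inside the union of inflated spheres are assigned to the atom
    whose inflated surface is nearest (deepest burial); the per-atom
    volumes sum to the total union volume exactly.
    """
    radii = sites.require_radii() + probe
    xyz = sites.coords * BOHR_TO_ANGSTROM
    lo = (xyz - radii[:, None]).min(axis=0) - resolution
    hi = (xyz + radii[:, None]).max(axis=0) + resolution
    axes = [np.arange(lo[k] + resolution / 2, hi[k], resolution) for k in range(3)]
    out = np.zeros(len(sites))
    vox = resolution**3
    # chunk along x to bound memory
    yz = np.stack(np.meshgrid(axes[1], axes[2], indexing="ij"), axis=-1).reshape(-1, 2)
    for x in axes[0]:
        pts = np.column_stack([np.full(len(yz), x), yz])
        depth = radii[None, :] - np.linalg.norm(
            pts[:, None, :] - xyz[None, :, :], axis=2
        )
        owner = np.argmax(depth, axis=1)
        inside = depth[np.arange(len(pts)), owner] > 0
        np.add.at(out, owner[inside], vox)
    return out


def cavity_energy(p: float, volumes: np.ndarray):
    """Per-atom p*V_I terms and their total (units follow p, volumes)."""
    if p < 0:
        raise ValueError("pressure parameter must be >= 0")
    per_atom = p * np.asarray(volumes, float)
    return per_atom, float(per_atom.sum())


def dispersion_surface_terms(
    sites: SiteSet,
    mesh: SurfaceMesh,
    rho_w: float = WATER_NUMBER_DENSITY,
    solvent_eps: float = WATER_LJ_EPS,
    solvent_rmin2: float = WATER_LJ_RMIN2,
):
    """Pairwise surface-dispersion terms G^IJ and symmetrized G'^IJ.

    G^IJ collects, via the divergence-theorem surface form over atom J's
    SAS elements, atom I's attractive r^-6 interaction with the solvent:

        G^IJ = -C_I rho_w sum_{s in SAS_J} sigma_s (rhat_Is . n_s) / (3 r_Is^5)

    with C_I = 2 eps_Iw rmin_Iw^6 the attractive LJ coefficient against
    the solvent (water-oxygen) site.  kcal/mol.
    """
    sites.require_lj()
    xyz = sites.coords * BOHR_TO_ANGSTROM
    n = len(sites)
    total_area = sum(len(a) for a in mesh.areas)
    G = np.zeros((n, n))
    if total_area == 0:
        logger.warning("zero-area surface mesh; dispersion terms are zero")
        return G, G.copy()
    eps_iw = np.sqrt(sites.lj_eps * solvent_eps)
    rmin_iw = sites.lj_rmin2 + solvent_rmin2
    C = 2.0 * eps_iw * rmin_iw**6
    for j in range(n):
        if len(mesh.points[j]) == 0:
            continue
        p = mesh.points[j]
        nrm = mesh.normals[j]
        sig = mesh.areas[j]
        for i in range(n):
            rel = p - xyz[i]
            r = np.linalg.norm(rel, axis=1)
            flux = np.einsum("sa,sa->s", rel / r[:, None], nrm) / (3.0 * r**5)
            G[i, j] = -C[i] * rho_w * float(np.dot(sig, flux))
    Gsym = 0.5 * (G + G.T)
    return G, Gsym


@dataclass
class SolvationTerms:
    """Atom-resolved implicit-solvation energies (kcal/mol)."""

    polar: np.ndarray
    cavity: np.ndarray
    disp_pair: np.ndarray       # symmetrized G'^IJ
    parameters: dict = field(default_factory=dict)

    @property
    def g_solv(self) -> np.ndarray:
        return self.polar + self.cavity + self.disp_pair.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.g_solv.sum())


def atomic_solvation(polar, cavity, disp_sym, parameters=None) -> SolvationTerms:
    """Combine per-atom polar, cavity and symmetrized dispersion terms.

    G_solv^I = polar_I + cavity_I + sum_J G'^IJ; the per-atom terms sum to
    the total solvation energy exactly.
    """
    polar = np.asarray(polar, float)
    cavity = np.asarray(cavity, float)
    disp_sym = np.asarray(disp_sym, float)
    if not (len(polar) == len(cavity) == len(disp_sym)):
        raise ValueError("component atom sets differ")
    return SolvationTerms(
        polar=polar, cavity=cavity, disp_pair=disp_sym,
        parameters=dict(parameters or {}, polar_convention="half_q_phi"),
    )
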