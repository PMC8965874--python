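"""Topological partitioning of the electron density into atomic basins.

The density is partitioned by steepest-ascent assignment of quadrature
nodes built on atom-centered spherical grids: every atom carries a
beta-sphere (fully contained in its basin, no assignment needed) plus an
outer shell whose nodes are traced uphill along grad(rho) to their
attractor.  Basin integrals for atom I use only atom I's own grid nodes
retained by the assignment, so the union of basins tiles space exactly
once.

Angular quadrature is a Gauss-Legendre x uniform-phi product grid of the
degree implied by the preset's angular point count; radial quadrature is
Gauss-Legendre on a cusp-adapted map per beta-segment.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .wavefunction import Wavefunction

logger = logging.getLogger(__name__)

__all__ = [
    "GridPreset", "PRESETS", "CriticalPoint", "CriticalPointSet",
    "find_critical_points", "beta_sphere_radii", "assign_attractor",
    "BasinGrid", "build_basin_grid", "atomic_populations",
    "atomic_overlap_matrix",
]

DENSITY_FLOOR = 1e-12


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GridPreset:
    """Named quadrature settings (angular counts, radial counts, cutoffs).

    Angular counts are realized as the product grid with at least the
    requested number of points.  The primary (fine) counts drive all
    single-center basin integrals; the ``pair_*`` counts build the coarser
    node set used for six-dimensional two-basin sums, whose cost is
    quadratic in the node count.
    """

    name: str
    ang_out_heavy: int
    ang_in_heavy: int
    ang_out_h: int
    ang_in_h: int
    rad_out_heavy: int
    rad_in_heavy: int
    rad_out_h: int
    rad_in_h: int
    rmax_heavy: float
    rmax_h: float
    lmax_out: int
    lmax_in: int
    pair_ang_heavy: int = 194
    pair_ang_h: int = 110
    pair_rad_heavy: int = 48
    pair_rad_h: int = 40

    def scaled(self, factor: float) -> "GridPreset":
        """A refined copy with ~factor x the 1D point counts."""
        f = float(factor)
        return replace(
            self,
            name=f"{self.name}x{factor}",
            ang_out_heavy=int(self.ang_out_heavy * f * f),
            ang_in_heavy=int(self.ang_in_heavy * f * f),
            ang_out_h=int(self.ang_out_h * f * f),
            ang_in_h=int(self.ang_in_h * f * f),
            rad_out_heavy=int(self.rad_out_heavy * f),
            rad_in_heavy=int(self.rad_in_heavy * f),
            rad_out_h=int(self.rad_out_h * f),
            rad_in_h=int(self.rad_in_h * f),
            pair_ang_heavy=int(self.pair_ang_heavy * f * f),
            pair_ang_h=int(self.pair_ang_h * f * f),
            pair_rad_heavy=int(self.pair_rad_heavy * f),
            pair_rad_h=int(self.pair_rad_h * f),
        )


PRESETS = {
    # settings used for the published protocol
    "paper": GridPreset("paper", 5810, 974, 3890, 590, 512, 384, 384, 256,
                        15.0, 10.0, 10, 6,
                        pair_ang_heavy=5810, pair_ang_h=3890,
                        pair_rad_heavy=512, pair_rad_h=384),
    # fixture-scale settings
    "desk": GridPreset("desk", 974, 194, 590, 110, 96, 96, 64, 64,
                       12.0, 9.0, 12, 6,
                       pair_ang_heavy=194, pair_ang_h=110,
                       pair_rad_heavy=48, pair_rad_h=40),
    # quick settings for smoke tests
    "mini": GridPreset("mini", 302, 110, 194, 74, 48, 48, 36, 36,
                       10.0, 8.0, 6, 4,
                       pair_ang_heavy=110, pair_ang_h=74,
                       pair_rad_heavy=32, pair_rad_h=28),
}


def get_preset(preset) -> GridPreset:
    if isinstance(preset, GridPreset):
        return preset
    return PRESETS[preset]


# ----------------------------------------------------------------------
# quadrature building blocks
# ----------------------------------------------------------------------

def angular_product_grid(n_points: int):
    """Unit-sphere product grid with >= n_points nodes; weights sum to 4 pi."""
    n_theta = max(2, math.ceil(math.sqrt(n_points / 2.0)))
    n_phi = 2 * n_theta
    ct, wt = np.polynomial.legendre.leggauss(n_theta)
    st = np.sqrt(1.0 - ct**2)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    wphi = 2.0 * np.pi / n_phi
    cp, sp = np.cos(phi), np.sin(phi)
    pts = np.empty((n_theta * n_phi, 3))
    pts[:, 0] = np.outer(st, cp).ravel()
    pts[:, 1] = np.outer(st, sp).ravel()
    pts[:, 2] = np.repeat(ct, n_phi)
    wts = np.repeat(wt * wphi, n_phi)
    return pts, wts


def radial_segment(n: int, r_lo: float, r_hi: float, cusp: bool):
    """Radial nodes/weights on [r_lo, r_hi]; weights include r^2 dr.

    ``cusp=True`` uses the quadratic map r = r_hi * t^2 that clusters
    points toward the nucleus (used for the beta-sphere segment).
    """
    x, w = np.polynomial.legendre.leggauss(n)
    if cusp:
        t = 0.5 * (x + 1.0)
        r = r_lo + (r_hi - r_lo) * t**2
        dr = (r_hi - r_lo) * t  # dt jacobian 0.5 folded below
        wr = w * dr * r**2
    else:
        r = r_lo + (r_hi - r_lo) * 0.5 * (x + 1.0)
        wr = w * 0.5 * (r_hi - r_lo) * r**2
    return r, wr


# ----------------------------------------------------------------------
# critical points
# ----------------------------------------------------------------------

@dataclass
class CriticalPoint:
    position: np.ndarray
    kind: str          # "nuclear" | "bond" | "ring" | "cage" | "nna"
    rho: float
    signature: int     # sum of Hessian eigenvalue signs
    atoms: tuple = ()  # attractors linked through a bond CP


@dataclass
class CriticalPointSet:
    points: list[CriticalPoint] = field(default_factory=list)

    def bonds(self):
        return [cp for cp in self.points if cp.kind == "bond"]

    def nearest_bond_distance(self, position) -> float:
        ds = [np.linalg.norm(cp.position - position) for cp in self.bonds()]
        return min(ds) if ds else math.inf


def _classify(signature: int, near_nucleus: bool) -> str:
    if signature == -3:
        return "nuclear" if near_nucleus else "nna"
    return {-1: "bond", 1: "ring", 3: "cage"}.get(signature, "degenerate")


def find_critical_points(
    wfn: Wavefunction,
    candidate_pairs=None,
    grad_tol: float = 1e-8,
    max_iter: int = 80,
) -> CriticalPointSet:
    """Newton search for density critical points seeded at pair midpoints.

    ``candidate_pairs`` defaults to all atom pairs within 8 bohr.  A pair
    whose search does not converge is reported CP-free (logged), not fatal.
    """
    coords = wfn.coords
    nat = len(coords)
    if candidate_pairs is None:
        candidate_pairs = [
            (i, j)
            for i in range(nat)
            for j in range(i + 1, nat)
            if np.linalg.norm(coords[i] - coords[j]) < 8.0
        ]
    cps = CriticalPointSet()
    # nuclear attractors (Newton from the nucleus itself is ill-conditioned
    # at the cusp; report the nuclear position).  Nuclei that are not
    # density attractors -- possible in a Gaussian basis for strongly
    # charge-depleted atoms -- carry no basin and get no nuclear CP.
    attractors = detect_attractors(wfn)
    rho_nuc = wfn.density(coords)
    for i in attractors:
        cps.points.append(
            CriticalPoint(coords[i].copy(), "nuclear", float(rho_nuc[i]), -3, (i,))
        )
    seen = []
    for (i, j) in candidate_pairs:
        x = 0.5 * (coords[i] + coords[j])
        ok = False
        for _ in range(max_iter):
            rho, grad, hess = wfn.density(x[None], deriv=2)
            g = grad[0]
            H = hess[0]
            if np.linalg.norm(g) < grad_tol:
                ok = True
                break
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                break
            norm = np.linalg.norm(step)
            if norm > 0.5:
                step *= 0.5 / norm
            x = x + step
        if not ok:
            logger.info("no critical point converged for pair (%d, %d)", i, j)
            continue
        if any(np.linalg.norm(x - s) < 1e-4 for s in seen):
            continue
        if np.min(np.linalg.norm(coords - x, axis=1)) < 0.2:
            continue  # ended on a nuclear attractor
        seen.append(x.copy())
        rho, grad, hess = wfn.density(x[None], deriv=2)
        ev, evec = np.linalg.eigh(hess[0])
        signature = int(np.sign(ev).sum())
        kind = _classify(signature, False)
        atoms = ()
        if kind == "bond":
            # trace the two steepest-ascent paths from the CP
            vpos = evec[:, np.argmax(ev)]
            assigner = BasinAssigner(wfn, attractors=attractors)
            ends = []
            for sgn in (+1.0, -1.0):
                seed = x + 0.05 * sgn * vpos
                a = assigner(seed[None])[0]
                ends.append(int(a))
            atoms = tuple(sorted(ends))
        cps.points.append(CriticalPoint(x.copy(), kind, float(rho[0]), signature, atoms))
    return cps


def beta_sphere_radii(
    wfn: Wavefunction,
    cps: CriticalPointSet,
    fraction: float = 0.6,
    fallback_cap: float = 1.5,
) -> np.ndarray:
    """Beta-sphere radius per atom: fraction x distance to the closest bond CP.

    Atoms with no bond CP fall back to fraction x half the nearest-neighbor
    internuclear distance, capped at ``fallback_cap`` bohr (isolated atom).
    """
    coords = wfn.coords
    nat = len(coords)
    radii = np.empty(nat)
    for i in range(nat):
        d = cps.nearest_bond_distance(coords[i])
        if not math.isfinite(d):
            others = [
                np.linalg.norm(coords[i] - coords[j]) for j in range(nat) if j != i
            ]
            d = 0.5 * min(others) if others else math.inf
            radii[i] = min(fraction * d, fallback_cap)
        else:
            radii[i] = fraction * d
    return radii


# ----------------------------------------------------------------------
# basin assignment
# ----------------------------------------------------------------------

def detect_attractors(wfn: Wavefunction, radius: float = 0.25) -> np.ndarray:
    """Indices of nuclei that carry a density attractor.

    In a Gaussian basis a nucleus need not be a maximum of rho (strongly
    charge-depleted atoms can lose their basin entirely); a nucleus counts
    as an attractor when short gradient ascent started just off the
    nucleus stays within ``radius`` of it.
    """
    coords = wfn.coords
    keep = []
    for ia in range(len(coords)):
        offs = 0.05 * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        )
        x = coords[ia] + offs
        stays = True
        for _ in range(80):
            rho, grad = wfn.density(x, deriv=1)
            gn = np.linalg.norm(grad, axis=1)
            ok = gn > 1e-14
            x[ok] += grad[ok] * (0.02 / gn[ok])[:, None]
            d = np.linalg.norm(x - coords[ia], axis=1)
            if np.any(d > radius):
                stays = False
                break
        if stays:
            keep.append(ia)
    if not keep:  # pathological; keep the global density maximum's nucleus
        rho = wfn.density(coords)
        keep = [int(np.argmax(rho))]
    return np.array(keep, dtype=int)


class BasinAssigner:
    """Deterministic steepest-ascent basin assignment.

    Points are traced uphill until captured by an attractor.  Points that
    stall near a bond critical point are classified by the side of the
    interatomic surface they lie on (sign of the displacement along the
    CP's positive-curvature eigenvector); remaining degenerate points go
    to the nearest attractor, ties to the lowest atom index.
    """

    def __init__(self, wfn: Wavefunction, attractors=None, bond_cps=None,
                 step: float = 0.35, capture: float = 0.2, max_steps: int = 120,
                 capture_radii=None, refine_stalled: bool = False):
        self.refine_stalled = refine_stalled
        self.wfn = wfn
        self.attractors = (
            np.asarray(attractors, dtype=int)
            if attractors is not None
            else detect_attractors(wfn)
        )
        self.step = step
        self.max_steps = max_steps
        # per-attractor capture radius; a beta-sphere is a certificate of
        # ownership, so capture may extend to it
        if capture_radii is None:
            self.capture_radii = np.full(len(self.attractors), capture)
        else:
            self.capture_radii = np.maximum(
                np.asarray(capture_radii, float)[self.attractors], capture
            )
        self.bond_cps = []
        if bond_cps:
            for cp in bond_cps:
                if cp.kind != "bond" or len(cp.atoms) != 2:
                    continue
                rho, grad, hess = wfn.density(cp.position[None], deriv=2)
                ev, evec = np.linalg.eigh(hess[0])
                v = evec[:, np.argmax(ev)]
                # orient v toward cp.atoms[1]
                if v @ (wfn.coords[cp.atoms[1]] - cp.position) < 0:
                    v = -v
                self.bond_cps.append((cp.position.copy(), v, cp.atoms))

    # ------------------------------------------------------------------
    def _nearest_attractor(self, pts) -> np.ndarray:
        d = np.linalg.norm(
            pts[:, None, :] - self.wfn.coords[self.attractors][None], axis=2
        )
        return self.attractors[np.argmin(d, axis=1)]

    def _resolve_stalled(self, pts) -> np.ndarray:
        out = self._nearest_attractor(pts)
        for pos, v, (a_lo, a_hi) in self.bond_cps:
            d = np.linalg.norm(pts - pos, axis=1)
            near = d < 0.8
            if np.any(near):
                side = (pts[near] - pos) @ v
                out[near] = np.where(side >= 0, a_hi, a_lo)
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        wfn = self.wfn
        coords = wfn.coords[self.attractors]
        pts = np.atleast_2d(np.array(points, dtype=float, copy=True))
        n = len(pts)
        out = np.full(n, -1, dtype=int)
        active = np.arange(n)
        x = pts.copy()
        for _ in range(self.max_steps):
            if not len(active):
                break
            d = np.linalg.norm(x[active][:, None, :] - coords[None], axis=2)
            kmin = np.argmin(d - self.capture_radii[None, :], axis=1)
            captured = (
                d[np.arange(len(active)), kmin] < self.capture_radii[kmin]
            )
            out[active[captured]] = self.attractors[kmin[captured]]
            active = active[~captured]
            if not len(active):
                break
            rho, grad = wfn.density(x[active], deriv=1)
            gnorm = np.linalg.norm(grad, axis=1)
            flat = (rho < DENSITY_FLOOR) | (gnorm < 1e-13)
            if np.any(flat):
                idx = active[flat]
                out[idx] = self._nearest_attractor(x[idx])
                active = active[~flat]
                if not len(active):
                    break
                grad = grad[~flat]
                gnorm = gnorm[~flat]
            # keep steps below the clearance to any capture sphere so a
            # discrete step cannot hop across a thin foreign basin
            d_all = np.linalg.norm(x[active][:, None, :] - coords[None], axis=2)
            clearance = np.min(d_all - self.capture_radii[None, :], axis=1)
            h = np.minimum(self.step, np.maximum(0.4 * clearance, 0.02))[:, None]
            # Heun step on the normalized flow: curvature of the gradient
            # field near small basins makes plain Euler hop basin tails
            k1 = grad / gnorm[:, None]
            _, g2 = wfn.density(x[active] + h * k1, deriv=1)
            g2n = np.linalg.norm(g2, axis=1)
            k2 = g2 / np.maximum(g2n, 1e-300)[:, None]
            x[active] += 0.5 * h * (k1 + k2)
        if len(active):
            logger.debug(
                "ascent stalled for %d points; resolving via bond-CP surfaces",
                len(active),
            )
            if self.refine_stalled:
                out[active] = self._refine(pts[active], x[active])
            else:
                out[active] = self._resolve_stalled(x[active])
        return out

    def _refine(self, pts0, stalled_pos, h: float = 0.05,
                max_steps: int = 3000) -> np.ndarray:
        """Careful RK4 re-integration of the normalized gradient flow for
        the few points whose coarse ascent stalled near a separatrix."""
        wfn = self.wfn
        coords = self.wfn.coords[self.attractors]
        x = np.array(pts0, dtype=float, copy=True)
        n = len(x)
        out = np.full(n, -1, dtype=int)
        active = np.arange(n)

        def v(xa):
            _, g = wfn.density(xa, deriv=1)
            gn = np.linalg.norm(g, axis=1)
            return g / np.maximum(gn, 1e-300)[:, None]

        for _ in range(max_steps):
            if not len(active):
                break
            d = np.linalg.norm(x[active][:, None, :] - coords[None], axis=2)
            kmin = np.argmin(d - self.capture_radii[None, :], axis=1)
            captured = d[np.arange(len(active)), kmin] < self.capture_radii[kmin]
            out[active[captured]] = self.attractors[kmin[captured]]
            active = active[~captured]
            if not len(active):
                break
            xa = x[active]
            k1 = v(xa)
            k2 = v(xa + 0.5 * h * k1)
            k3 = v(xa + 0.5 * h * k2)
            k4 = v(xa + h * k3)
            x[active] = xa + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if len(active):
            out[active] = self._resolve_stalled(x[active])
        return out


def assign_attractor(
    wfn: Wavefunction,
    points: np.ndarray,
    assigner: BasinAssigner | None = None,
    **control,
) -> np.ndarray:
    """Attractor (atom) index for each point by batch gradient ascent.

    Points whose coarse ascent stalls near a separatrix are re-integrated
    with a careful fixed-step scheme before falling back to the bond-CP
    surface side test.
    """
    if assigner is None:
        control.setdefault("refine_stalled", True)
        assigner = BasinAssigner(wfn, **control)
    return assigner(points)


# ----------------------------------------------------------------------
# basin grids
# ----------------------------------------------------------------------

@dataclass
class AtomGrid:
    """Quadrature of one atomic basin.

    The basin is sampled on the atom's own spherical grid: a beta-sphere
    segment (radial x angular, trivially owned) plus an outer segment in
    which each angular ray is radially truncated at the basin boundary
    located by bisection on the gradient-ascent ownership test.  All
    stored nodes therefore belong to the atom.
    """

    atom: int
    center: np.ndarray
    beta_radius: float
    rmax: float
    points: np.ndarray   # (N, 3) absolute positions of owned nodes (fine)
    weights: np.ndarray  # (N,) quadrature weights (include r^2 dr dOmega)
    radii: np.ndarray    # (N,) |point - center|
    ray_caps: np.ndarray  # (n_ang_out,) boundary radius per outer ray
    ang_dirs: np.ndarray = None  # (n_ang_out, 3) outer angular directions
    ang_wts: np.ndarray = None   # (n_ang_out,) angular weights (sum 4 pi)
    # coarser node set for six-dimensional two-basin integrals
    pair_points: np.ndarray = None
    pair_weights: np.ndarray = None

    def nodes_weights(self):
        return self.points, self.weights

    @property
    def n_owned(self) -> int:
        return len(self.weights)


@dataclass
class BasinGrid:
    """Per-atom basin quadratures plus shared metadata."""

    atoms: list[AtomGrid]
    preset: GridPreset
    critical_points: CriticalPointSet
    beta_radii: np.ndarray
    assigner: "BasinAssigner | None" = None

    def populations(self, wfn: Wavefunction) -> np.ndarray:
        return atomic_populations(wfn, self)

    def union_grid(self, wfn: Wavefunction, members: tuple[int, ...],
                   center_atom: int | None = None) -> AtomGrid:
        """Single-center grid of the union of several basins.

        Used by the pair-energy route that computes two-basin integrals as
        differences of self-integrals.  The union is sampled on rays from
        ``center_atom`` (default: the member with the largest basin),
        radially capped where the ray leaves the union.
        """
        if self.assigner is None:
            raise ValueError("grid was built without an assigner")
        members = tuple(sorted(members))
        if center_atom is None:
            center_atom = max(members, key=lambda a: self.atoms[a].n_owned)
        preset = self.preset
        z = wfn.numbers[center_atom]
        heavy = z > 1.0
        # the union can extend one neighbor further out than a single basin
        rmax = (preset.rmax_heavy if heavy else preset.rmax_h)
        span = max(
            np.linalg.norm(wfn.coords[m] - wfn.coords[center_atom])
            for m in members
        )
        rmax = rmax + span
        rb = self.atoms[center_atom].beta_radius
        center = wfn.coords[center_atom]

        class _SetAssign:
            def __init__(self, assigner, members):
                self.assigner = assigner
                self.members = set(members)

            def __call__(self, pts):
                out = self.assigner(pts)
                return np.where(np.isin(out, list(self.members)), -1, out)

        # ownership test: "in union" encoded as -1 == center marker
        sa = _SetAssign(self.assigner, members)
        ang_out, wa_out = angular_product_grid(
            preset.ang_out_heavy if heavy else preset.ang_out_h
        )
        caps = _ray_caps(sa, center, -1, ang_out, rb, rmax)
        r_in, wr_in = radial_segment(
            preset.rad_in_heavy if heavy else preset.rad_in_h, 0.0, rb, cusp=True
        )
        ang_in, wa_in = angular_product_grid(
            preset.ang_in_heavy if heavy else preset.ang_in_h
        )
        pts_in = center[None, None, :] + r_in[:, None, None] * ang_in[None, :, :]
        wts_in = wr_in[:, None] * wa_in[None, :]
        x, wq = np.polynomial.legendre.leggauss(
            preset.rad_out_heavy if heavy else preset.rad_out_h
        )
        t = 0.5 * (x + 1.0)
        r_out = rb + np.outer(caps - rb, t)
        wr_out = 0.5 * (caps - rb)[:, None] * wq[None, :] * r_out**2
        pts_out = center[None, None, :] + r_out[..., None] * ang_out[:, None, :]
        wts_out = wr_out * wa_out[:, None]
        rad_in = np.broadcast_to(r_in[:, None], wts_in.shape)
        return AtomGrid(
            atom=center_atom,
            center=center.copy(),
            beta_radius=rb,
            rmax=rmax,
            points=np.vstack([pts_in.reshape(-1, 3), pts_out.reshape(-1, 3)]),
            weights=np.concatenate([wts_in.ravel(), wts_out.ravel()]),
            radii=np.concatenate([rad_in.ravel(), r_out.ravel()]),
            ray_caps=caps,
            ang_dirs=ang_out,
            ang_wts=wa_out,
        )


def _ray_caps(assigner, center, ia, dirs, r_lo, r_hi, n_scan=12, n_bisect=30):
    """Basin-boundary radius along each ray, by batched bisection.

    Rays that never leave basin ``ia`` below ``r_hi`` are capped at r_hi.
    """
    nray = len(dirs)
    rs = np.linspace(r_lo, r_hi, n_scan + 1)[1:]
    owner = np.empty((n_scan, nray), dtype=int)
    for k, r in enumerate(rs):
        owner[k] = assigner(center + r * dirs)
    inside = owner == ia
    caps = np.full(nray, r_hi)
    lo = np.full(nray, r_lo)
    hi = np.full(nray, r_hi)
    active = []
    for iray in range(nray):
        crossing = np.where(~inside[:, iray])[0]
        if len(crossing) == 0:
            continue
        k = crossing[0]
        lo[iray] = rs[k - 1] if k > 0 else r_lo
        hi[iray] = rs[k]
        active.append(iray)
    active = np.array(active, dtype=int)
    for _ in range(n_bisect):
        if not len(active):
            break
        mid = 0.5 * (lo[active] + hi[active])
        own = assigner(center + mid[:, None] * dirs[active])
        is_in = own == ia
        lo[active[is_in]] = mid[is_in]
        hi[active[~is_in]] = mid[~is_in]
        if np.max(hi[active] - lo[active]) < 1e-7:
            break
    caps[active] = 0.5 * (lo[active] + hi[active])
    return caps


def build_basin_grid(
    wfn: Wavefunction,
    preset="desk",
    beta_fraction: float = 0.6,
    cps: CriticalPointSet | None = None,
) -> BasinGrid:
    """Construct basin-resolved quadrature grids for every QM atom."""
    preset = get_preset(preset)
    if cps is None:
        cps = find_critical_points(wfn)
    attractors = sorted(
        cp.atoms[0] for cp in cps.points if cp.kind == "nuclear"
    )
    beta = beta_sphere_radii(wfn, cps, fraction=beta_fraction)
    assigner = BasinAssigner(
        wfn, attractors=attractors, bond_cps=cps.bonds(), capture_radii=beta
    )
    atoms = []
    for ia, z in enumerate(wfn.numbers):
        if ia not in attractors:
            # no basin: the nucleus is not a density attractor
            empty3 = np.zeros((0, 3))
            empty = np.zeros(0)
            atoms.append(
                AtomGrid(ia, wfn.coords[ia].copy(), 0.0, 0.0,
                         empty3, empty, empty, empty, empty3, empty,
                         empty3, empty)
            )
            continue
        heavy = z > 1.0
        rmax = preset.rmax_heavy if heavy else preset.rmax_h
        rb = min(beta[ia], 0.95 * rmax)
        center = wfn.coords[ia]

        def segment(n_ang_in, n_rad_in, n_ang_out, n_rad_out):
            r_in, wr_in = radial_segment(n_rad_in, 0.0, rb, cusp=True)
            ang_in, wa_in = angular_product_grid(n_ang_in)
            pts_in = center[None, None, :] + r_in[:, None, None] * ang_in[None, :, :]
            wts_in = wr_in[:, None] * wa_in[None, :]
            rad_in = np.broadcast_to(r_in[:, None], wts_in.shape)

            ang_out, wa_out = angular_product_grid(n_ang_out)
            caps = _ray_caps(assigner, center, ia, ang_out, rb, rmax)
            x, wq = np.polynomial.legendre.leggauss(n_rad_out)
            t = 0.5 * (x + 1.0)
            r_out = rb + np.outer(caps - rb, t)  # (n_ang, n_rad)
            wr_out = 0.5 * (caps - rb)[:, None] * wq[None, :] * r_out**2
            pts_out = center[None, None, :] + r_out[..., None] * ang_out[:, None, :]
            wts_out = wr_out * wa_out[:, None]
            return (
                np.vstack([pts_in.reshape(-1, 3), pts_out.reshape(-1, 3)]),
                np.concatenate([wts_in.ravel(), wts_out.ravel()]),
                np.concatenate([rad_in.ravel(), r_out.ravel()]),
                caps,
                ang_out,
                wa_out,
            )

        pts, wts, rads, caps, ang_out, wa_out = segment(
            preset.ang_in_heavy if heavy else preset.ang_in_h,
            preset.rad_in_heavy if heavy else preset.rad_in_h,
            preset.ang_out_heavy if heavy else preset.ang_out_h,
            preset.rad_out_heavy if heavy else preset.rad_out_h,
        )
        ppts, pwts, _, _, _, _ = segment(
            (preset.pair_ang_heavy if heavy else preset.pair_ang_h) // 2,
            preset.pair_rad_heavy if heavy else preset.pair_rad_h,
            preset.pair_ang_heavy if heavy else preset.pair_ang_h,
            preset.pair_rad_heavy if heavy else preset.pair_rad_h,
        )
        atoms.append(
            AtomGrid(
                atom=ia,
                center=center.copy(),
                beta_radius=rb,
                rmax=rmax,
                points=pts,
                weights=wts,
                radii=rads,
                ray_caps=caps,
                ang_dirs=ang_out,
                ang_wts=wa_out,
                pair_points=ppts,
                pair_weights=pwts,
            )
        )
    return BasinGrid(atoms=atoms, preset=preset, critical_points=cps,
                     beta_radii=beta, assigner=assigner)


def atomic_populations(wfn: Wavefunction, grid: BasinGrid) -> np.ndarray:
    """Electron population of each basin."""
    out = np.empty(len(grid.atoms))
    for ag in grid.atoms:
        pts, wts = ag.nodes_weights()
        out[ag.atom] = np.dot(wts, wfn.density(pts))
    return out


def atomic_overlap_matrix(wfn: Wavefunction, grid: BasinGrid, atom: int) -> np.ndarray:
    """Occupied-MO overlap matrix over one atomic basin."""
    ag = grid.atoms[atom]
    pts, wts = ag.nodes_weights()
    phi = wfn.mo_values(pts)
    return (phi * wts) @ phi.T
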