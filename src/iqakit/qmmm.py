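"""QM-MM coupling terms, MM energies and their atomic splitting.

The QM region couples to MM point charges through basin-integrated
electrostatics (the QM density restricted to each QTAIM basin interacting
with each MM charge) and through pairwise Lennard-Jones terms in the Amber
convention.  Purely-MM energies (bonded records, MM-MM nonbonded pairs)
are computed from the topology, and bond/angle/torsion energies are split
into atomic shares as 1/2, 1/3, 1/4 per participating atom.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .qtaim import BasinGrid
from .sites import MMTopology
from .system import SystemModel
from .units import BOHR_TO_ANGSTROM, COULOMB_KCAL

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionMask", "MMEnergyBreakdown", "build_interaction_mask",
    "qmmm_electrostatics", "qmmm_vdw", "mm_energy", "bat_atomic_split",
]


@dataclass
class InteractionMask:
    """Which (QM atom/link, MM site) pairs interact, and how.

    MM sites bonded directly to a QM host atom are excluded from QM
    electrostatics (their interactions are taken over by the H-link atom);
    vdW pairs follow the topology's exclusion list.
    """

    ele: np.ndarray        # (n_qm, n_mm) bool
    vdw: np.ndarray        # (n_qm, n_mm) bool
    qm_sites: np.ndarray   # site index per QM row
    mm_sites: np.ndarray   # site index per MM column
    excluded_pairs: set = field(default_factory=set)


def build_interaction_mask(system: SystemModel) -> InteractionMask:
    """Electrostatic/vdW masks implementing the H-link exclusion rule."""
    qm = system.qm_indices
    mm = system.mm_indices
    ele = np.ones((len(qm), len(mm)), dtype=bool)
    vdw = np.ones((len(qm), len(mm)), dtype=bool)
    top = system.topology
    excluded = set()
    for link in system.links:
        if top is None:
            raise ValueError("link atoms require a topology")
        if not any(link.mm_host in (b[0], b[1]) for b in top.bonds):
            raise ValueError(
                f"link MM host {link.mm_host} not found in the topology bonds"
            )
    if top is not None:
        qm_set = set(qm)
        bonded_to_qm = set()
        for a, b, *_ in top.bonds:
            if a in qm_set and b not in qm_set:
                bonded_to_qm.add(b)
            if b in qm_set and a not in qm_set:
                bonded_to_qm.add(a)
        for col, ms in enumerate(mm):
            if ms in bonded_to_qm:
                ele[:, col] = False
                excluded.update((int(q), int(ms)) for q in qm)
        # vdW honors the topology exclusion list
        for pair in top.exclusions:
            a, b = tuple(pair)
            if a in qm_set and b in set(mm):
                vdw[np.where(qm == a)[0][0], np.where(mm == b)[0][0]] = False
            if b in qm_set and a in set(mm):
                vdw[np.where(qm == b)[0][0], np.where(mm == a)[0][0]] = False
    return InteractionMask(ele=ele, vdw=vdw, qm_sites=qm, mm_sites=mm,
                           excluded_pairs=excluded)


# ----------------------------------------------------------------------
# QM-MM electrostatics
# ----------------------------------------------------------------------

def qmmm_electrostatics(
    system: SystemModel,
    grid: BasinGrid,
    mask: InteractionMask | None = None,
) -> np.ndarray:
    """Pairwise (basin I, MM site J') electrostatic energies, hartree.

    E_ele^IJ' = -q_J' int_{Omega_I} rho(r)/|r - R_J'| dV
                + Z_I q_J' / |R_I - R_J'|
    """
    wfn = system.wavefunction
    if wfn is None:
        raise ValueError("QM-MM electrostatics requires a wavefunction")
    if mask is None:
        mask = build_interaction_mask(system)
    mm = mask.mm_sites
    q_mm = system.sites.charges[mm] if system.sites.charges is not None else None
    if q_mm is None or np.any(~np.isfinite(q_mm)):
        raise ValueError("QM-MM electrostatics requires charges on all MM sites")
    R_mm = system.sites.coords[mm]
    n_qm = len(mask.qm_sites)
    out = np.zeros((n_qm, len(mm)))
    for ag in grid.atoms:
        i = ag.atom  # wavefunction nucleus index == row index
        if ag.n_owned == 0:
            elec = np.zeros(len(mm))
        else:
            rho_w = ag.weights * wfn.density(ag.points)
            d = np.linalg.norm(
                ag.points[:, None, :] - R_mm[None, :, :], axis=2
            )
            close = d < 1e-6
            if np.any(close):
                logger.warning(
                    "%d grid nodes coincide with MM sites; excluded",
                    int(close.sum()),
                )
                d = np.where(close, np.inf, d)
            elec = -(rho_w @ (1.0 / d))            # per MM site
        dz = np.linalg.norm(wfn.coords[i] - R_mm, axis=1)
        nuc = wfn.numbers[i] / dz
        out[i] = q_mm * (elec + nuc)
    out[~mask.ele] = 0.0
    return out


def qmmm_electrostatics_direct(system: SystemModel, grid: BasinGrid) -> float:
    """Unpartitioned QM-MM Coulomb energy from rho_tot on the full grid.

    Closure oracle: must match the sum of the pairwise matrix to
    quadrature accuracy.
    """
    mask = build_interaction_mask(system)
    wfn = system.wavefunction
    mm = mask.mm_sites
    q = system.sites.charges[mm]
    R = system.sites.coords[mm]
    # keep only non-excluded charges (exclusion is per whole QM region here)
    active_cols = mask.ele.all(axis=0)
    total = 0.0
    for ag in grid.atoms:
        if ag.n_owned == 0:
            continue
        rho_w = ag.weights * wfn.density(ag.points)
        d = np.linalg.norm(ag.points[:, None, :] - R[None, :, :], axis=2)
        d[d < 1e-6] = np.inf
        contrib = -(rho_w @ (1.0 / d))
        total += float(np.dot(q[active_cols], contrib[active_cols]))
    for i, z in enumerate(wfn.numbers):
        dz = np.linalg.norm(wfn.coords[i] - R, axis=1)
        total += float(np.dot(q[active_cols], z / dz[active_cols]))
    return total


# ----------------------------------------------------------------------
# Lennard-Jones
# ----------------------------------------------------------------------

def lj_pair_energy(eps_i, rmin2_i, eps_j, rmin2_j, r_angstrom):
    """Amber LJ: eps_ij [(rmin_ij/R)^12 - 2 (rmin_ij/R)^6], kcal/mol."""
    eps = np.sqrt(eps_i * eps_j)
    rmin = rmin2_i + rmin2_j
    x = (rmin / r_angstrom) ** 6
    return eps * (x * x - 2.0 * x)


def qmmm_vdw(system: SystemModel, mask: InteractionMask | None = None) -> np.ndarray:
    """Pairwise (QM site, MM site) LJ energies in kcal/mol."""
    if mask is None:
        mask = build_interaction_mask(system)
    sites = system.sites
    sites.require_lj()
    qm, mm = mask.qm_sites, mask.mm_sites
    out = np.zeros((len(qm), len(mm)))
    for a, iq in enumerate(qm):
        r = (
            np.linalg.norm(sites.coords[iq] - sites.coords[mm], axis=1)
            * BOHR_TO_ANGSTROM
        )
        out[a] = lj_pair_energy(
            sites.lj_eps[iq], sites.lj_rmin2[iq],
            sites.lj_eps[mm], sites.lj_rmin2[mm], r,
        )
    out[~mask.vdw] = 0.0
    return out


# ----------------------------------------------------------------------
# MM energies
# ----------------------------------------------------------------------

@dataclass
class MMEnergyBreakdown:
    """Per-record bonded energies and pairwise nonbonded terms, kcal/mol."""

    bond_energies: list          # aligned with topology.bonds
    angle_energies: list
    dihedral_energies: list
    pair_coulomb: dict           # (i, j) -> kcal/mol
    pair_lj: dict
    n_atoms: int

    @property
    def bonded_total(self) -> float:
        return (
            sum(self.bond_energies)
            + sum(self.angle_energies)
            + sum(self.dihedral_energies)
        )

    @property
    def nonbonded_total(self) -> float:
        return sum(self.pair_coulomb.values()) + sum(self.pair_lj.values())

    @property
    def total(self) -> float:
        return self.bonded_total + self.nonbonded_total


def _angle(r1, r2, r3):
    a = r1 - r2
    b = r3 - r2
    cosv = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return np.arccos(np.clip(cosv, -1.0, 1.0))


def _dihedral(r1, r2, r3, r4):
    b1 = r2 - r1
    b2 = r3 - r2
    b3 = r4 - r3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return np.arctan2(y, x)


def mm_energy(
    topology: MMTopology,
    coords_bohr: np.ndarray,
    charges=None,
    lj_eps=None,
    lj_rmin2=None,
    mm_indices=None,
) -> MMEnergyBreakdown:
    """MM energy of the topology at the given coordinates.

    Bonded terms: k_b (r - r0)^2, k_th (th - th0)^2,
    k_n [1 + cos(n phi - gamma)].  Nonbonded over non-excluded pairs with
    Amber 1-4 divisors.  If ``mm_indices`` is given, nonbonded pairs are
    restricted to that subset (pure-MM pairs).
    """
    xyz = np.atleast_2d(coords_bohr) * BOHR_TO_ANGSTROM
    bond_e = [
        kb * (np.linalg.norm(xyz[i] - xyz[j]) - r0) ** 2
        for (i, j, kb, r0) in topology.bonds
    ]
    angle_e = [
        kt * (_angle(xyz[i], xyz[j], xyz[k]) - th0) ** 2
        for (i, j, k, kt, th0) in topology.angles
    ]
    dih_e = [
        kn * (1.0 + np.cos(n * _dihedral(xyz[i], xyz[j], xyz[k], xyz[l]) - gam))
        for (i, j, k, l, kn, n, gam) in topology.dihedrals
    ]
    pair_c, pair_lj = {}, {}
    if charges is not None:
        idx = (
            np.asarray(mm_indices)
            if mm_indices is not None
            else np.arange(topology.n_atoms)
        )
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = int(idx[a]), int(idx[b])
                key = frozenset((i, j))
                if key in topology.exclusions:
                    continue
                scale_e = scale_v = 1.0
                if key in topology.pairs14:
                    scale_e = 1.0 / topology.scee
                    scale_v = 1.0 / topology.scnb
                r = np.linalg.norm(xyz[i] - xyz[j])
                if np.isfinite(charges[i]) and np.isfinite(charges[j]):
                    pair_c[(i, j)] = (
                        scale_e * COULOMB_KCAL * charges[i] * charges[j] / r
                    )
                if lj_eps is not None and np.isfinite(lj_eps[i]) and np.isfinite(lj_eps[j]):
                    pair_lj[(i, j)] = scale_v * lj_pair_energy(
                        lj_eps[i], lj_rmin2[i], lj_eps[j], lj_rmin2[j], r
                    )
    return MMEnergyBreakdown(
        bond_energies=bond_e,
        angle_energies=angle_e,
        dihedral_energies=dih_e,
        pair_coulomb=pair_c,
        pair_lj=pair_lj,
        n_atoms=topology.n_atoms,
    )


def bat_atomic_split(breakdown: MMEnergyBreakdown, topology: MMTopology) -> np.ndarray:
    """Per-atom bond/angle/torsion shares: 1/2, 1/3, 1/4 per record atom.

    The shares sum exactly to the per-record bonded total.
    """
    out = np.zeros(breakdown.n_atoms)
    for (i, j, *_), e in zip(topology.bonds, breakdown.bond_energies):
        out[i] += e / 2.0
        out[j] += e / 2.0
    for (i, j, k, *_), e in zip(topology.angles, breakdown.angle_energies):
        for a in (i, j, k):
            out[a] += e / 3.0
    for (i, j, k, l, *_), e in zip(topology.dihedrals, breakdown.dihedral_energies):
        for a in (i, j, k, l):
            out[a] += e / 4.0
    return out
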