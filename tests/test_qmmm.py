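"""QM-MM coupling, MM energies, BAT splitting and interaction masks."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iqakit.fixtures import make_analytic_system
from iqakit.qmmm import (
    bat_atomic_split,
    build_interaction_mask,
    lj_pair_energy,
    mm_energy,
    qmmm_electrostatics,
    qmmm_electrostatics_direct,
    qmmm_vdw,
)
from iqakit.qtaim import build_basin_grid
from iqakit.sites import MM, QM, MMTopology, SiteSet
from iqakit.system import assemble_system
from iqakit.units import ANGSTROM_TO_BOHR, COULOMB_KCAL


# ----------------------------------------------------------------------
# electrostatics
# ----------------------------------------------------------------------

def _point_charge_system(wfn, q, pos_bohr, region_n):
    qm = SiteSet(["X"] * region_n, wfn.coords,
                 region=np.array([QM] * region_n, dtype=object))
    mm = SiteSet(["X"] * len(q), np.atleast_2d(pos_bohr), charges=q)
    return assemble_system(wfn, qm, mm)


def test_zero_charge_gives_zero_matrix(wfn_h2o, grid_h2o_mini):
    system = _point_charge_system(wfn_h2o, [0.0], [[0, 8.0, 0]], 3)
    mat = qmmm_electrostatics(system, grid_h2o_mini)
    assert np.all(mat == 0.0)


def test_gaussian_cloud_point_charge_closed_form():
    """Single s-Gaussian density + unit charge: the electronic part is
    -erf(sqrt(2 alpha) d)/d and the nuclear part Z/d."""
    sysm = make_analytic_system([[0, 0, 0]], [1.0], weights=[1.0],
                                charges=[1.0])
    wfn = sysm.wavefunction
    grid = build_basin_grid(wfn, "desk")
    d = 2.0
    system = _point_charge_system(wfn, [1.0], [[0, 0, d]], 1)
    mat = qmmm_electrostatics(system, grid)
    from scipy.special import erf

    elec = -erf(np.sqrt(2.0) * d) / d
    nuc = 1.0 / d
    # the MM site sits inside the cloud: the singular kernel limits the
    # node-sum accuracy to a few times 1e-5 at this grid
    assert mat[0, 0] == pytest.approx(elec + nuc, abs=5e-5)


def test_pairwise_sum_equals_direct_integral(toy_complex_run):
    tc, system, grid, terms, mask = toy_complex_run
    total = terms.qmmm_ele.sum()
    direct = qmmm_electrostatics_direct(system, grid)
    assert total == pytest.approx(direct, abs=1e-5)


def test_missing_mm_charges_raise(wfn_h2o, grid_h2o_mini):
    qm = SiteSet(["O", "H", "H"], wfn_h2o.coords,
                 region=np.array([QM] * 3, dtype=object))
    mm = SiteSet(["X"], [[0, 9.0, 0]])
    system = assemble_system(wfn_h2o, qm, mm)
    with pytest.raises(ValueError, match="charges"):
        qmmm_electrostatics(system, grid_h2o_mini)


# ----------------------------------------------------------------------
# Lennard-Jones
# ----------------------------------------------------------------------

def test_lj_minimum_value():
    assert lj_pair_energy(0.1, 1.7, 0.1, 1.7, 3.4) == pytest.approx(-0.1)


def test_lj_vanishes_at_infinity():
    assert lj_pair_energy(0.2, 1.7, 0.2, 1.7, 1e6) == pytest.approx(0.0, abs=1e-30)


@given(
    eps=st.floats(0.01, 0.5),
    rmin2=st.floats(0.8, 2.5),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_lj_combined_minimum_is_minus_eps(eps, rmin2):
    r = 2 * rmin2
    assert lj_pair_energy(eps, rmin2, eps, rmin2, r) == pytest.approx(-eps, rel=1e-12)


def test_qmmm_vdw_matrix(toy_complex_run):
    tc, system, grid, terms, mask = toy_complex_run
    vdw = qmmm_vdw(system, mask)
    # O-O pair dominates; H sites have eps=0 on the QM side rows 1,2 x O cols
    assert vdw.shape == (3, 6)
    r_oo = np.linalg.norm(
        system.sites.coords[0] - system.sites.coords[3]
    ) / ANGSTROM_TO_BOHR
    expect = lj_pair_energy(0.1520, 1.7683, 0.1520, 1.7683, r_oo)
    assert vdw[0, 0] == pytest.approx(expect, rel=1e-10)


def test_missing_lj_parameters_named(wfn_h2o):
    qm = SiteSet(["O", "H", "H"], wfn_h2o.coords,
                 region=np.array([QM] * 3, dtype=object))
    mm = SiteSet(["X"], [[0, 9.0, 0]], charges=[0.1])
    system = assemble_system(wfn_h2o, qm, mm)
    with pytest.raises(ValueError, match="LJ parameters missing"):
        qmmm_vdw(system)


# ----------------------------------------------------------------------
# MM energies
# ----------------------------------------------------------------------

def test_bond_energy_arithmetic():
    top = MMTopology(n_atoms=2, bonds=[(0, 1, 100.0, 1.0)])
    coords = np.array([[0, 0, 0], [1.1, 0, 0]]) * ANGSTROM_TO_BOHR
    bd = mm_energy(top, coords)
    assert bd.bond_energies[0] == pytest.approx(1.0)


def test_dihedral_at_phase_minimum():
    top = MMTopology(
        n_atoms=4, dihedrals=[(0, 1, 2, 3, 2.0, 1, 0.0)]
    )
    # trans arrangement: phi = 180 deg -> k (1 + cos(180)) = 0
    coords = np.array(
        [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float
    ) * ANGSTROM_TO_BOHR
    bd = mm_energy(top, coords)
    assert bd.dihedral_energies[0] == pytest.approx(0.0, abs=1e-12)


def test_tip3p_water_pair_energy_hand_value():
    """Two rigid waters: nonbonded energy against a hand-assembled sum."""
    from iqakit.fixtures import tip3p_geometry

    g1 = tip3p_geometry()
    g2 = tip3p_geometry(center=(0.0, 0.0, 2.8 * ANGSTROM_TO_BOHR))
    coords = np.vstack([g1, g2])
    charges = np.array([-0.834, 0.417, 0.417] * 2)
    eps = np.array([0.1520, 0.0, 0.0] * 2)
    rmin2 = np.array([1.7683, 0.6, 0.6] * 2)
    top = MMTopology(n_atoms=6)
    for o in (0, 3):
        top.exclusions |= {
            frozenset((o, o + 1)), frozenset((o, o + 2)),
            frozenset((o + 1, o + 2)),
        }
    bd = mm_energy(top, coords, charges, eps, rmin2)
    # independent hand evaluation over the 9 intermolecular pairs
    expect = 0.0
    xyz = coords / ANGSTROM_TO_BOHR
    for i in range(3):
        for j in range(3, 6):
            r = np.linalg.norm(xyz[i] - xyz[j])
            expect += COULOMB_KCAL * charges[i] * charges[j] / r
            if eps[i] > 0 and eps[j] > 0:
                e = math.sqrt(eps[i] * eps[j])
                rm = rmin2[i] + rmin2[j]
                expect += e * ((rm / r) ** 12 - 2 * (rm / r) ** 6)
    assert bd.total == pytest.approx(expect, abs=1e-4)


def test_14_scaling_divisors():
    top = MMTopology(n_atoms=2, scee=1.2, scnb=2.0)
    top.pairs14.add(frozenset((0, 1)))
    coords = np.array([[0, 0, 0], [4.0, 0, 0]]) * ANGSTROM_TO_BOHR
    q = np.array([0.3, -0.3])
    eps = np.array([0.1, 0.1])
    rmin2 = np.array([1.9, 1.9])
    bd = mm_energy(top, coords, q, eps, rmin2)
    raw_c = COULOMB_KCAL * 0.3 * -0.3 / 4.0
    raw_lj = lj_pair_energy(0.1, 1.9, 0.1, 1.9, 4.0)
    assert bd.pair_coulomb[(0, 1)] == pytest.approx(raw_c / 1.2)
    assert bd.pair_lj[(0, 1)] == pytest.approx(raw_lj / 2.0)


# ----------------------------------------------------------------------
# BAT splitting
# ----------------------------------------------------------------------

def test_bond_split_half_each():
    top = MMTopology(n_atoms=2, bonds=[(0, 1, 1.0, 0.0)])
    coords = np.array([[0, 0, 0], [np.sqrt(2.0), 0, 0]]) * ANGSTROM_TO_BOHR
    bd = mm_energy(top, coords)
    shares = bat_atomic_split(bd, top)
    assert np.allclose(shares, [bd.bond_energies[0] / 2] * 2)


def test_angle_and_torsion_fractions():
    top = MMTopology(
        n_atoms=4,
        angles=[(0, 1, 2, 1.0, 0.0)],
        dihedrals=[(0, 1, 2, 3, 2.0, 1, math.pi)],
    )
    coords = np.array(
        [[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float
    ) * ANGSTROM_TO_BOHR
    bd = mm_energy(top, coords)
    shares = bat_atomic_split(bd, top)
    ang = bd.angle_energies[0]
    tor = bd.dihedral_energies[0]
    assert shares[0] == pytest.approx(ang / 3 + tor / 4)
    assert shares[3] == pytest.approx(tor / 4)
    assert shares.sum() == pytest.approx(bd.bonded_total)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_bat_conservation_random_topologies(seed):
    """BAT shares sum exactly to the record total for arbitrary records."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    coords = rng.normal(scale=2.0, size=(n, 3)) * ANGSTROM_TO_BOHR
    top = MMTopology(n_atoms=n)
    for _ in range(rng.integers(1, 5)):
        i, j = rng.choice(n, 2, replace=False)
        top.bonds.append((int(i), int(j), float(rng.uniform(50, 500)),
                          float(rng.uniform(0.8, 1.8))))
    for _ in range(rng.integers(0, 4)):
        i, j, k = rng.choice(n, 3, replace=False)
        top.angles.append((int(i), int(j), int(k), float(rng.uniform(20, 80)),
                           float(rng.uniform(1.0, 2.6))))
    for _ in range(rng.integers(0, 3)):
        i, j, k, l = rng.choice(n, 4, replace=False)
        top.dihedrals.append((int(i), int(j), int(k), int(l),
                              float(rng.uniform(0.5, 4.0)),
                              int(rng.integers(1, 4)),
                              float(rng.uniform(0, 2 * math.pi))))
    bd = mm_energy(top, coords)
    shares = bat_atomic_split(bd, top)
    assert shares.sum() == pytest.approx(bd.bonded_total, rel=1e-12)


# ----------------------------------------------------------------------
# interaction masks and link atoms
# ----------------------------------------------------------------------

def test_no_links_full_mask(toy_complex_run):
    tc, system, grid, terms, mask = toy_complex_run
    assert mask.ele.all()


def _ethane_split_model(wfn_methyl):
    man = wfn_methyl.meta["manifest"]
    rcc = man["cc_bond_bohr"]
    qm = SiteSet(["C", "H", "H", "H", "H"], wfn_methyl.coords,
                 region=np.array([QM] * 5, dtype=object))
    # MM side: the other methyl carbon + one H, with charges
    mm = SiteSet(["C", "H"],
                 np.array([[0.0, 0.0, rcc], [0.0, 0.0, rcc + 2.06]]),
                 charges=[-0.3, 0.1])
    top = MMTopology(n_atoms=7, bonds=[(0, 5, 300.0, 1.526),
                                       (5, 6, 340.0, 1.09)])
    return assemble_system(wfn_methyl, qm, mm, topology=top,
                           link_spec=[(0, 5, 4)])


def test_mm_host_excluded_from_qm_electrostatics(wfn_methyl):
    model = _ethane_split_model(wfn_methyl)
    mask = build_interaction_mask(model)
    # MM carbon (site 5, column 0) bonded to the QM carbon: excluded
    assert not mask.ele[:, 0].any()
    # the distal MM hydrogen stays
    assert mask.ele[:, 1].all()


def test_link_h_participates_as_electrostatic_source(wfn_methyl):
    model = _ethane_split_model(wfn_methyl)
    grid = build_basin_grid(wfn_methyl, "mini")
    mask = build_interaction_mask(model)
    mat = qmmm_electrostatics(model, grid, mask)
    # row 4 is the link hydrogen basin: nonzero coupling to the distal H
    assert mat.shape == (5, 2)
    assert mat[4, 1] != 0.0
    assert np.all(mat[:, 0] == 0.0)


def test_link_host_missing_from_topology_raises(wfn_methyl):
    man = wfn_methyl.meta["manifest"]
    rcc = man["cc_bond_bohr"]
    qm = SiteSet(["C", "H", "H", "H", "H"], wfn_methyl.coords,
                 region=np.array([QM] * 5, dtype=object))
    mm = SiteSet(["C"], np.array([[0.0, 0.0, rcc]]), charges=[-0.3])
    top = MMTopology(n_atoms=6)  # no bonds at all
    model = assemble_system(wfn_methyl, qm, mm, topology=top,
                            link_spec=[(0, 5, 4)])
    with pytest.raises(ValueError, match="not found in the topology"):
        build_interaction_mask(model)
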