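"""Poisson reaction field, ESP charges, SAS/SAV geometry, nonpolar terms."""
import numpy as np
import pytest

from iqakit.sites import SiteSet
from iqakit.solvation import (
    PBSpec,
    atomic_solvation,
    cavity_energy,
    chelpg_charges,
    dispersion_surface_terms,
    polar_atomic_terms,
    sas_surface,
    sav_volumes,
    solve_reaction_field,
)
from iqakit.units import COULOMB_KCAL, EBOHR_TO_DEBYE


def born_energy(q, radius_a, eps):
    return -(COULOMB_KCAL / 2.0) * q * q * (1.0 - 1.0 / eps) / radius_a


@pytest.fixture(scope="module")
def born_ion():
    return SiteSet(["Na"], np.zeros((1, 3)), charges=[1.0], pb_radii=[2.0])


# ----------------------------------------------------------------------
# reaction field
# ----------------------------------------------------------------------

def test_zero_charges_zero_reaction_field(born_ion):
    s = SiteSet(["Na"], np.zeros((1, 3)), charges=[0.0], pb_radii=[2.0])
    rf = solve_reaction_field(s, PBSpec(spacing=0.5, probe_radius=0.0))
    assert np.allclose(rf.phi_rf, 0.0)


def test_born_ion_within_two_percent(born_ion):
    rf = solve_reaction_field(born_ion, PBSpec(spacing=0.33, probe_radius=0.0))
    polar = polar_atomic_terms(born_ion, rf).sum()
    ref = born_energy(1.0, 2.0, 80.0)
    assert abs(polar - ref) / abs(ref) < 0.02
    # reaction field opposes the ion's own charge
    assert rf.phi_rf[0] < 0.0


def test_born_error_decreases_with_refinement(born_ion):
    ref = born_energy(1.0, 2.0, 80.0)
    errs = []
    for h in (0.5, 0.33, 0.25):
        rf = solve_reaction_field(born_ion, PBSpec(spacing=h, probe_radius=0.0))
        errs.append(abs(polar_atomic_terms(born_ion, rf).sum() - ref))
    assert errs[0] > errs[1] > errs[2]


def test_atom_outside_box_rejected(born_ion):
    with pytest.raises(ValueError, match="spacing"):
        PBSpec(spacing=-0.1)
    with pytest.raises(ValueError, match="eps"):
        PBSpec(eps_solvent=0.5)


def test_polar_term_arithmetic():
    s = SiteSet(["X"], np.zeros((1, 3)), charges=[1.0], pb_radii=[1.5])

    class FakeRF:
        phi_rf = np.array([-10.0])

    assert polar_atomic_terms(s, FakeRF())[0] == pytest.approx(-5.0)


def test_neutral_site_contributes_nothing():
    s = SiteSet(["X", "Y"], [[0, 0, 0], [4, 0, 0]], charges=[1.0, 0.0],
                pb_radii=[2.0, 1.5])
    rf = solve_reaction_field(s, PBSpec(spacing=0.4, probe_radius=0.0))
    polar = polar_atomic_terms(s, rf)
    assert polar[1] == 0.0


def test_born_single_atomic_term_is_total(born_ion):
    rf = solve_reaction_field(born_ion, PBSpec(spacing=0.4, probe_radius=0.0))
    polar = polar_atomic_terms(born_ion, rf)
    assert polar[0] == pytest.approx(polar.sum())


# ----------------------------------------------------------------------
# ESP-fitted charges
# ----------------------------------------------------------------------

def test_chelpg_total_charge_constraint_machine_precision(wfn_hehp):
    q = chelpg_charges(wfn_hehp)
    assert q.sum() == pytest.approx(1.0, abs=1e-12)


def test_chelpg_reproduces_density_dipole(wfn_h2o, manifests):
    q = chelpg_charges(wfn_h2o)
    mu = np.linalg.norm((q[:, None] * wfn_h2o.coords).sum(axis=0))
    assert mu * EBOHR_TO_DEBYE == pytest.approx(
        manifests["h2o_hf_sto3g"]["dipole_debye"], abs=0.1
    )


def test_chelpg_stable_under_grid_refinement(wfn_h2o):
    q1 = chelpg_charges(wfn_h2o, spacing=0.4)
    q2 = chelpg_charges(wfn_h2o, spacing=0.28)
    assert np.abs(q1 - q2).max() < 0.01


def test_chelpg_sparse_grid_rejected(wfn_h2o):
    with pytest.raises(ValueError, match="sparse|rank"):
        chelpg_charges(wfn_h2o, spacing=8.0)


# ----------------------------------------------------------------------
# SAS / SAV
# ----------------------------------------------------------------------

def test_single_sphere_area():
    s = SiteSet(["O"], np.zeros((1, 3)), pb_radii=[1.6])
    mesh = sas_surface(s, probe=1.4, n_points=960)
    assert mesh.exposed_area[0] == pytest.approx(4 * np.pi * 9.0, rel=1e-12)


def test_far_atoms_have_additive_areas():
    s = SiteSet(["O", "O"], np.array([[0, 0, 0], [40, 0, 0]]),
                pb_radii=[1.6, 1.6])
    mesh = sas_surface(s, probe=1.4)
    assert mesh.exposed_area.sum() == pytest.approx(2 * 4 * np.pi * 9.0, rel=1e-12)


def test_two_sphere_lens_area_closed_form():
    """Overlapping equal spheres: total SAS area from the lens formula."""
    R = 3.0   # inflated radius
    d = 2.5   # center distance, A
    s = SiteSet(["O", "O"], np.array([[0, 0, 0], [d, 0, 0]]) / 0.529177,
                pb_radii=[1.6, 1.6])
    mesh = sas_surface(s, probe=1.4, n_points=960)
    # each sphere loses a cap of height h = R - d/2
    cap = 2 * np.pi * R * (R - d / 2.0)
    exact = 2 * (4 * np.pi * R * R - cap)
    assert mesh.exposed_area.sum() == pytest.approx(exact, rel=0.01)


def test_single_sphere_volume():
    s = SiteSet(["O"], np.zeros((1, 3)), pb_radii=[1.6])
    v = sav_volumes(s, probe=1.4, resolution=0.12)
    assert v[0] == pytest.approx(4.0 / 3.0 * np.pi * 27.0, rel=5e-3)


def test_disjoint_volumes_additive():
    s = SiteSet(["O", "N"], np.array([[0, 0, 0], [30, 0, 0]]),
                pb_radii=[1.6, 1.5])
    v = sav_volumes(s, probe=1.4, resolution=0.25)
    v1 = sav_volumes(s.select([0]), probe=1.4, resolution=0.25)
    v2 = sav_volumes(s.select([1]), probe=1.4, resolution=0.25)
    assert v.sum() == pytest.approx(v1.sum() + v2.sum(), rel=5e-3)


def test_union_volume_closed_form():
    R = 3.0
    d = 2.5
    s = SiteSet(["O", "O"], np.array([[0, 0, 0], [d, 0, 0]]) / 0.529177,
                pb_radii=[1.6, 1.6])
    v = sav_volumes(s, probe=1.4, resolution=0.15)
    # union of two equal spheres: 2 V_sphere - lens volume
    lens = np.pi * (4 * R + d) * (2 * R - d) ** 2 / 12.0
    exact = 2 * (4.0 / 3.0) * np.pi * R**3 - lens
    assert v.sum() == pytest.approx(exact, rel=0.01)


# ----------------------------------------------------------------------
# cavity + surface dispersion
# ----------------------------------------------------------------------

def test_cavity_zero_pressure():
    per, tot = cavity_energy(0.0, [100.0, 50.0])
    assert tot == 0.0 and np.all(per == 0.0)


def test_cavity_arithmetic():
    per, tot = cavity_energy(0.05, [100.0, 50.0])
    assert np.allclose(per, [5.0, 2.5])
    assert tot == pytest.approx(7.5)


def test_cavity_monotone_in_radius():
    totals = []
    for scale in (1.0, 1.1, 1.2):
        s = SiteSet(["O", "H"], np.array([[0, 0, 0], [1.8, 0, 0]]),
                    pb_radii=np.array([1.6, 1.2]) * scale)
        v = sav_volumes(s, probe=1.4, resolution=0.3)
        totals.append(cavity_energy(0.05, v)[1])
    assert totals[0] < totals[1] < totals[2]


def test_surface_dispersion_zero_density():
    s = SiteSet(["O"], np.zeros((1, 3)), lj_eps=[0.2], lj_rmin2=[1.7],
                pb_radii=[1.6])
    mesh = sas_surface(s)
    G, Gs = dispersion_surface_terms(s, mesh, rho_w=0.0)
    assert np.all(G == 0.0)


def test_surface_dispersion_single_sphere_closed_form():
    s = SiteSet(["O"], np.zeros((1, 3)), lj_eps=[0.21], lj_rmin2=[1.66],
                pb_radii=[1.6])
    mesh = sas_surface(s, probe=1.4, n_points=960)
    G, _ = dispersion_surface_terms(s, mesh)
    eps_iw = np.sqrt(0.21 * 0.1520)
    C = 2.0 * eps_iw * (1.66 + 1.7683) ** 6
    exact = -4 * np.pi * 0.03343 * C / (3 * 3.0**3)
    assert G[0, 0] == pytest.approx(exact, rel=0.01)


def test_surface_dispersion_matches_volume_quadrature():
    """Divergence-theorem surface form equals direct volume integration of
    the attractive solute-solvent interaction over the solvent region."""
    s = SiteSet(["O", "C"], np.array([[0, 0, 0], [2.2, 0.4, 0]]) / 0.529177,
                lj_eps=[0.21, 0.1094], lj_rmin2=[1.6612, 1.9080],
                pb_radii=[1.5, 1.7])
    mesh = sas_surface(s, probe=1.4, n_points=960)
    G, _ = dispersion_surface_terms(s, mesh)
    # brute-force volume quadrature of the exterior integral, per solute atom
    xyz = s.coords * 0.529177
    radii = s.pb_radii + 1.4
    eps_iw = np.sqrt(s.lj_eps * 0.1520)
    C = 2.0 * eps_iw * (s.lj_rmin2 + 1.7683) ** 6
    h = 0.12
    box = 14.0
    axes = [np.arange(-box, box, h) + c for c in xyz.mean(axis=0)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d = np.linalg.norm(pts[:, None, :] - xyz[None, :, :], axis=2)
    solvent = (d > radii[None, :]).all(axis=1)
    oracle = np.zeros(2)
    for i in range(2):
        r6 = d[solvent, i] ** 6
        oracle[i] = -C[i] * 0.03343 * np.sum(1.0 / r6) * h**3
        # analytic tail beyond the finite box (spherical estimate)
        oracle[i] += -C[i] * 0.03343 * 4 * np.pi / (3 * box**3)
    mine = G.sum(axis=1)
    assert np.allclose(mine, oracle, rtol=0.02)


def test_symmetrization_conserves_total():
    s = SiteSet(["O", "C"], np.array([[0, 0, 0], [3.1, 0, 0]]) / 0.529177,
                lj_eps=[0.21, 0.1094], lj_rmin2=[1.66, 1.91],
                pb_radii=[1.5, 1.7])
    mesh = sas_surface(s, probe=1.4)
    G, Gs = dispersion_surface_terms(s, mesh)
    assert Gs.sum() == pytest.approx(G.sum(), abs=1e-14)
    assert np.allclose(Gs, Gs.T)


# ----------------------------------------------------------------------
# per-atom solvation assembly
# ----------------------------------------------------------------------

def test_atomic_solvation_zero_components():
    terms = atomic_solvation(np.zeros(3), np.zeros(3), np.zeros((3, 3)))
    assert terms.total == 0.0


def test_atomic_solvation_hand_ledger():
    polar = np.array([-5.0, 1.0, 0.5])
    cavity = np.array([2.0, 1.0, 0.7])
    disp = np.array([[-0.2, -0.1, 0.0],
                     [-0.1, -0.3, -0.05],
                     [0.0, -0.05, -0.1]])
    terms = atomic_solvation(polar, cavity, disp)
    assert terms.g_solv[0] == pytest.approx(-5.0 + 2.0 - 0.3)
    assert terms.g_solv[1] == pytest.approx(1.0 + 1.0 - 0.45)
    assert terms.total == pytest.approx(polar.sum() + cavity.sum() + disp.sum())


def test_atomic_solvation_mismatched_sets():
    with pytest.raises(ValueError, match="atom sets"):
        atomic_solvation(np.zeros(2), np.zeros(3), np.zeros((3, 3)))
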