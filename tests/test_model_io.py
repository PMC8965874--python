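"""Wavefunction/site/topology readers and density-derived fields."""
import numpy as np
import pytest

from iqakit.basis import GaussianBasis, Shell
from iqakit.fixtures import fixture_path
from iqakit.formats import ParseError, load_wavefunction
from iqakit.sites import TopologyError, load_sites, load_topology
from iqakit.system import AssemblyError, assemble_system
from iqakit.sites import QM, SiteSet
from iqakit.wavefunction import (
    Wavefunction,
    WavefunctionError,
    evaluate_density,
    evaluate_ked,
    evaluate_rdm1,
)
from importlib import resources


def _data(name):
    return resources.as_file(fixture_path(name))


# ----------------------------------------------------------------------
# wavefunction loading
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "name,n_elec,n_occ,n_nuc",
    [
        ("h2_hf_sto3g.wfx", 2, 1, 2),
        ("h2o_hf_sto3g.wfx", 10, 5, 3),
        ("hehp_hf_sto3g.wfx", 2, 1, 2),
        ("h2o_hf_sto3g.molden", 10, 5, 3),
        ("h2o_b3lyp_tz.molden", 10, 5, 3),
    ],
)
def test_load_wavefunction_headers(name, n_elec, n_occ, n_nuc):
    with _data(name) as p:
        wfn = load_wavefunction(p)
    assert wfn.n_electrons == pytest.approx(n_elec)
    assert int((wfn.mo_occ > 0).sum()) == n_occ
    assert wfn.n_atoms == n_nuc


def test_loaded_density_matches_generated_samples(manifests):
    """Write->read round trip reproduces rho and grad rho at sample points."""
    for name, m in manifests.items():
        for ext in (".wfx", ".molden"):
            handle = fixture_path(name + ext)
            if not handle.is_file():
                continue
            with _data(name + ext) as p:
                wfn = load_wavefunction(p)
            pts = np.array(m["sample_points_bohr"])
            rho, grad = wfn.density(pts, deriv=1)
            assert np.allclose(rho, m["sample_rho"], atol=1e-10)
            assert np.allclose(grad, m["sample_grad_rho"], atol=1e-9)


def test_wfx_energy_header(wfn_h2, manifests):
    assert wfn_h2.energy == pytest.approx(
        manifests["h2_hf_sto3g"]["scf_energy"], abs=1e-10
    )


def test_occupation_electron_mismatch_raises(tmp_path):
    with _data("h2_hf_sto3g.wfx") as p:
        text = p.read_text()
    bad = text.replace(
        "<Number of Electrons>\n 2", "<Number of Electrons>\n 4"
    )
    f = tmp_path / "bad.wfx"
    f.write_text(bad)
    with pytest.raises(WavefunctionError, match="declares 4 electrons"):
        load_wavefunction(f)


def test_malformed_wfx_names_missing_record(tmp_path):
    f = tmp_path / "broken.wfx"
    f.write_text("<Title>\n x\n</Title>\n")
    with pytest.raises(ParseError, match="Number of Nuclei"):
        load_wavefunction(f)


# ----------------------------------------------------------------------
# density-derived fields
# ----------------------------------------------------------------------

@pytest.fixture()
def one_electron_gaussian():
    basis = GaussianBasis([Shell(0, 0, [0.0, 0.0, 0.0], [1.0], [1.0])])
    return Wavefunction(
        numbers=[1.0], coords=[[0.0, 0.0, 0.0]], basis=basis,
        mo_coeff=np.array([[1.0]]), mo_occ=np.array([1.0]),
    )


def test_density_of_normalized_s_gaussian_at_origin(one_electron_gaussian):
    rho = evaluate_density(one_electron_gaussian, [[0.0, 0.0, 0.0]])
    assert rho[0] == pytest.approx((2.0 / np.pi) ** 1.5, rel=1e-12)


def test_density_normalizes_to_electron_count(wfn_h2o, grid_h2o_desk):
    total = sum(
        np.dot(ag.weights, wfn_h2o.density(ag.points))
        for ag in grid_h2o_desk.atoms
    )
    assert total == pytest.approx(10.0, abs=1e-3)


def test_h2_midpoint_gradient_vanishes(wfn_h2):
    _, grad = evaluate_density(wfn_h2, [[0.0, 0.0, 0.7]], order="gradient")
    assert np.allclose(grad, 0.0, atol=1e-12)


def test_density_gradient_consistent_with_central_differences(wfn_h2o):
    pts = np.array([[0.4, 0.2, 0.9], [-1.0, 0.3, 0.2]])
    _, grad = evaluate_density(wfn_h2o, pts, order="gradient")
    eps = 1e-5
    for ax in range(3):
        dp = pts.copy()
        dp[:, ax] += eps
        dm = pts.copy()
        dm[:, ax] -= eps
        fd = (evaluate_density(wfn_h2o, dp) - evaluate_density(wfn_h2o, dm)) / (
            2 * eps
        )
        assert np.allclose(fd, grad[:, ax], rtol=1e-6, atol=1e-9)


def test_rdm1_diagonal_equals_density(wfn_h2o):
    pts = np.array([[0.3, -0.2, 0.8], [1.1, 0.4, 0.1]])
    rho1 = evaluate_rdm1(wfn_h2o, pts, pts)
    assert np.allclose(np.diag(rho1), wfn_h2o.density(pts), atol=1e-12)


def test_rdm1_single_mo_closed_form(wfn_h2):
    r1 = np.array([[0.1, 0.0, 0.3]])
    r2 = np.array([[-0.2, 0.4, 1.0]])
    phi1 = wfn_h2.mo_values(r1)[0, 0]
    phi2 = wfn_h2.mo_values(r2)[0, 0]
    assert evaluate_rdm1(wfn_h2, r1, r2)[0, 0] == pytest.approx(
        2.0 * phi1 * phi2, rel=1e-12
    )


def test_rdm1_matches_brute_force_contraction(wfn_h2o):
    rng = np.random.default_rng(4)
    r1 = rng.normal(scale=1.2, size=(5, 3))
    r2 = rng.normal(scale=1.2, size=(5, 3))
    rho1 = evaluate_rdm1(wfn_h2o, r1, r2)
    C, occ = wfn_h2o.occupied()
    ao1 = wfn_h2o.basis.eval_ao(r1)
    ao2 = wfn_h2o.basis.eval_ao(r2)
    brute = np.einsum("m,um,ui,vm,vj->ij", occ, C, ao1, C, ao2)
    assert np.allclose(rho1, brute, atol=1e-12)


def test_rdm1_symmetric_under_swap(wfn_h2o):
    rng = np.random.default_rng(5)
    r1 = rng.normal(size=(4, 3))
    r2 = rng.normal(size=(4, 3))
    a = evaluate_rdm1(wfn_h2o, r1, r2)
    b = evaluate_rdm1(wfn_h2o, r2, r1)
    assert np.allclose(a, b.T, atol=1e-13)


def test_ked_positive_everywhere(wfn_h2o):
    pts = np.random.default_rng(6).normal(scale=2.0, size=(1000, 3))
    assert np.all(evaluate_ked(wfn_h2o, pts) >= 0.0)


def test_ked_integral_gaussian_virial(one_electron_gaussian, grid_he_desk):
    # integral of the positive-definite KED for a unit-exponent s Gaussian
    # equals 3 alpha / 2 = 1.5 hartree
    total = sum(
        np.dot(ag.weights, one_electron_gaussian.ked(ag.points))
        for ag in grid_he_desk.atoms
    )
    assert total == pytest.approx(1.5, abs=1e-5)


def test_ked_integral_matches_scf_kinetic(wfn_h2, grid_h2_desk, manifests):
    total = sum(
        np.dot(ag.weights, wfn_h2.ked(ag.points)) for ag in grid_h2_desk.atoms
    )
    assert total == pytest.approx(
        manifests["h2_hf_sto3g"]["kinetic_energy"], abs=1e-3
    )


def test_open_shell_rdm1_rejected(one_electron_gaussian):
    with pytest.raises(WavefunctionError, match="closed-shell"):
        evaluate_rdm1(one_electron_gaussian, [[0, 0, 0]], [[0, 0, 0]])


# ----------------------------------------------------------------------
# site lists and topologies
# ----------------------------------------------------------------------

def test_xyzq_single_line_charge():
    with _data("tip3p_water.xyzq") as p:
        s = load_sites(p)
    assert s.charges[0] == pytest.approx(-0.834)
    assert len(s) == 3
    # positions converted to bohr
    assert np.linalg.norm(s.coords[0] - s.coords[1]) == pytest.approx(
        0.9572 / 0.529177, rel=1e-6
    )


def test_pqr_radius_column_populates_pb_radii():
    with _data("tip3p_water.pqr") as p:
        s = load_sites(p)
    assert np.allclose(s.pb_radii, [1.52, 1.20, 1.20])
    assert np.allclose(s.charges, [-0.834, 0.417, 0.417])


def test_pdb_without_charges_raises_downstream(tmp_path):
    f = tmp_path / "m.pdb"
    f.write_text(
        "ATOM      1  O   HOH A   1       0.000   0.000   0.000"
        "  1.00  0.00           O\n"
    )
    s = load_sites(f, format="pdb")
    assert s.charges is None
    with pytest.raises(ValueError, match="charges"):
        s.require_charges()


def test_xyzq_nonnumeric_field_reports_line(tmp_path):
    f = tmp_path / "bad.xyzq"
    f.write_text("O 0 0 zero -0.8\n")
    with pytest.raises(ValueError, match="bad.xyzq:1"):
        load_sites(f)


def test_prmtop_tip3p_water():
    with _data("tip3p_water.prmtop") as p:
        top, sites = load_topology(p)
    assert len(sites) == 3
    assert sites.charges[0] == pytest.approx(-0.834, abs=1e-6)
    assert sites.lj_eps[0] == pytest.approx(0.1520, abs=1e-4)
    assert sites.lj_rmin2[0] == pytest.approx(1.7683, abs=1e-4)
    assert len(top.bonds) == 2 and len(top.angles) == 1
    assert top.bonds[0][2] == pytest.approx(450.0)


def test_prmtop_missing_mandatory_section(tmp_path):
    f = tmp_path / "broken.prmtop"
    f.write_text("%FLAG CHARGE\n%FORMAT(5E16.8)\n 0.0\n")
    with pytest.raises(TopologyError, match="POINTERS"):
        load_topology(f, dialect="prmtop")


def test_toy_topology_single_bond(tmp_path):
    f = tmp_path / "one.toytop"
    f.write_text("bond 1 2 100.0 1.0\n")
    top, sites = load_topology(f, dialect="toy")
    assert sites is None
    assert top.bonds == [(0, 1, 100.0, 1.0)]
    assert top.n_atoms == 2


def test_empty_topology_with_charged_sites():
    from iqakit.sites import MMTopology

    top = MMTopology(n_atoms=2)
    top.validate()
    assert not top.bonds and not top.angles and not top.dihedrals


# ----------------------------------------------------------------------
# system assembly
# ----------------------------------------------------------------------

def test_assemble_h2o_plus_point_charge(wfn_h2o):
    qm = SiteSet(["O", "H", "H"], wfn_h2o.coords,
                 region=np.array([QM] * 3, dtype=object))
    mm = SiteSet(["X"], [[0.0, 8.0, 0.0]], charges=[-0.5])
    model = assemble_system(wfn_h2o, qm, mm)
    assert model.n_qm == 3
    assert list(model.mm_indices) == [3]


def test_assemble_detects_position_mismatch(wfn_h2o):
    coords = wfn_h2o.coords.copy()
    coords[0, 2] += 0.1
    qm = SiteSet(["O", "H", "H"], coords,
                 region=np.array([QM] * 3, dtype=object))
    with pytest.raises(AssemblyError, match="position mismatch"):
        assemble_system(wfn_h2o, qm, None)


def test_assemble_methyl_link_fixture(wfn_methyl):
    """Ethane cut across the C-C bond: one link record, valid model."""
    from iqakit.sites import MMTopology

    # combined ordering: QM C,H,H,H + link H (wavefunction atoms), then MM CH3
    man = wfn_methyl.meta["manifest"]
    rcc = man["cc_bond_bohr"]
    qm = SiteSet(["C", "H", "H", "H", "H"], wfn_methyl.coords,
                 region=np.array([QM] * 5, dtype=object))
    mm_coords = np.array([[0.0, 0.0, rcc], [0.0, 0.0, rcc + 2.0]])
    mm = SiteSet(["C", "H"], mm_coords, charges=[-0.1, 0.1])
    top = MMTopology(n_atoms=7, bonds=[(0, 5, 300.0, 1.526), (5, 6, 340.0, 1.09)])
    model = assemble_system(wfn_methyl, qm, mm, topology=top,
                            link_spec=[(0, 5, 4)])
    assert len(model.links) == 1
    assert model.sites.region[4] == "LINK"
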