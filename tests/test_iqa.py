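"""IQA net energies, diatomic terms, xc scaling, additivity, persistence."""
import numpy as np
import pytest

from iqakit.iqa import (
    IQATermMatrix,
    additive_energies,
    build_term_matrix,
    diatomic_terms,
    localize_orbitals,
    net_energies,
    atomic_overlap_diag,
    pair_coulomb_direct,
    pair_exchange_direct,
    reconstruct_total,
    scale_dft_xc,
    screen_orbitals,
)
from iqakit.qtaim import build_basin_grid


# ----------------------------------------------------------------------
# net energies
# ----------------------------------------------------------------------

def test_single_basin_net_energy_is_total_electronic(
    wfn_he, grid_he_desk, terms_he_desk, manifests
):
    """He: one basin = whole space, so E_net equals the SCF total."""
    assert terms_he_desk.e_net[0] == pytest.approx(
        manifests["he_hf_sto3g"]["scf_energy"], abs=1e-3
    )


def test_h2_net_energies_symmetric(terms_h2_desk):
    assert terms_h2_desk.e_net[0] == pytest.approx(
        terms_h2_desk.e_net[1], abs=1e-5
    )


def test_h2_kinetic_sum_matches_scf(terms_h2_desk, manifests):
    assert terms_h2_desk.kinetic.sum() == pytest.approx(
        manifests["h2_hf_sto3g"]["kinetic_energy"], abs=1e-3
    )


def test_net_energy_requires_wavefunction(grid_h2_desk):
    with pytest.raises(ValueError, match="wavefunction"):
        net_energies(None, grid_h2_desk)


# ----------------------------------------------------------------------
# diatomic terms
# ----------------------------------------------------------------------

def test_xc_zeroed_beyond_cutoff():
    """Two basins beyond 17 au: E_xc = 0 by rule, E_ele ~ 0 for neutral."""
    from iqakit.fixtures import make_analytic_system

    sysm = make_analytic_system(
        [[0, 0, 0], [0, 0, 18.0]], [0.9, 0.9], weights=[2.0, 2.0],
        charges=[2.0, 2.0],
    )
    wfn = sysm.wavefunction
    grid = build_basin_grid(wfn, "mini")
    t = diatomic_terms(wfn, grid, (0, 1))
    assert t["vee_xc"] == 0.0
    assert t["e_int"] == pytest.approx(0.0, abs=1e-4)  # neutral, no overlap


def test_separated_neutral_atoms_have_no_electrostatic_interaction():
    """Two 'He-like' clouds at 8 bohr: E_ele ~ 0, E_int ~ E_xc."""
    from iqakit.fixtures import make_analytic_system

    sysm = make_analytic_system(
        [[0, 0, 0], [0, 0, 8.0]], [0.9, 0.9], weights=[2.0, 2.0],
        charges=[2.0, 2.0],
    )
    wfn = sysm.wavefunction
    grid = build_basin_grid(wfn, "mini")
    t = diatomic_terms(wfn, grid, (0, 1))
    assert t["e_ele"] == pytest.approx(0.0, abs=1e-4)
    assert t["e_int"] == pytest.approx(t["e_xc"], abs=1e-4)


def test_multipolar_mode_refused_at_short_range(wfn_h2, grid_h2_desk, caplog):
    import logging

    with caplog.at_level(logging.WARNING, logger="iqakit.iqa"):
        t = diatomic_terms(wfn_h2, grid_h2_desk, (0, 1), mode="multipolar")
    assert "falling back to exact" in caplog.text
    # fell back: classical split carries the separate nuclear terms
    assert t["v_en"] != 0.0


def test_multipolar_matches_exact_at_long_range():
    from iqakit.fixtures import make_analytic_system

    sysm = make_analytic_system(
        [[0, 0, 0], [0, 0, 7.0]], [1.0, 1.0], weights=[2.0, 1.0],
        charges=[2.0, 2.0],   # net charges 0 and +1: real electrostatics
    )
    wfn = sysm.wavefunction
    grid = build_basin_grid(wfn, "mini")
    exact = diatomic_terms(wfn, grid, (0, 1), mode="exact")
    multi = diatomic_terms(wfn, grid, (0, 1), mode="multipolar")
    assert multi["e_ele"] == pytest.approx(exact["e_ele"], abs=1e-5)


# ----------------------------------------------------------------------
# reconstruction
# ----------------------------------------------------------------------

@pytest.mark.parametrize("fixture_name", ["terms_he_desk", "terms_h2_desk"])
def test_reconstruction_residual_small(fixture_name, request):
    terms = request.getfixturevalue(fixture_name)
    _, residual = reconstruct_total(terms)
    assert abs(residual) < 1e-3


def test_reconstruct_single_net_term():
    t = IQATermMatrix(
        n_atoms=1,
        kinetic=np.array([0.5]), v_ne_own=np.array([-1.5]),
        vee_intra_coul=np.array([0.25]), vee_intra_xc=np.array([-0.05]),
        v_nn=np.zeros((1, 1)), v_en_cross=np.zeros((1, 1)),
        vee_coul=np.zeros((1, 1)), vee_xc=np.zeros((1, 1)),
        scf_reference=-0.8,
    )
    total, residual = reconstruct_total(t)
    assert total == pytest.approx(-0.8)
    assert residual == pytest.approx(0.0)


# ----------------------------------------------------------------------
# DFT xc scaling
# ----------------------------------------------------------------------

def test_hf_wavefunction_needs_no_scaling(terms_h2_desk):
    """Scaling an HF matrix to its own reconstructed total gives kappa=1."""
    total, _ = reconstruct_total(terms_h2_desk)
    scaled = scale_dft_xc(terms_h2_desk, total)
    assert scaled.xc_scale == pytest.approx(1.0, abs=1e-12)
    terms_h2_desk.xc_scale = 1.0  # restore the shared fixture


def test_synthetic_scaling_arithmetic():
    t = IQATermMatrix(
        n_atoms=2,
        kinetic=np.array([1.0, 1.0]), v_ne_own=np.array([-2.0, -2.0]),
        vee_intra_coul=np.array([0.5, 0.5]),
        vee_intra_xc=np.array([-0.5, -0.3]),
        v_nn=np.array([[0.0, 0.2], [0.2, 0.0]]),
        v_en_cross=np.zeros((2, 2)),
        vee_coul=np.zeros((2, 2)),
        vee_xc=np.array([[0.0, -0.2], [-0.2, 0.0]]),
    )
    # unscaled total: -1.1; sum xc = -1.0; target gap -0.1 -> kappa = 1.1
    target = t.reconstructed_total() - 0.1
    scaled = scale_dft_xc(t, target)
    assert scaled.xc_scale == pytest.approx(1.1)
    assert scaled.reconstructed_total() == pytest.approx(target, abs=1e-14)


def test_b3lyp_scaling_recovers_scf_total(wfn_h2o_b3lyp, manifests):
    grid = build_basin_grid(wfn_h2o_b3lyp, "mini")
    terms = build_term_matrix(wfn_h2o_b3lyp, grid)
    e_ref = manifests["h2o_b3lyp_sto3g"]["scf_energy"]
    scaled = scale_dft_xc(terms, e_ref)
    total, residual = reconstruct_total(scaled)
    assert residual == pytest.approx(0.0, abs=1e-12)
    assert 0.8 <= scaled.xc_scale <= 1.3


def test_scaling_impossible_when_xc_vanishes(caplog):
    import logging

    t = IQATermMatrix(
        n_atoms=1,
        kinetic=np.array([1.0]), v_ne_own=np.array([-2.0]),
        vee_intra_coul=np.array([0.5]), vee_intra_xc=np.array([0.0]),
        v_nn=np.zeros((1, 1)), v_en_cross=np.zeros((1, 1)),
        vee_coul=np.zeros((1, 1)), vee_xc=np.zeros((1, 1)),
    )
    with caplog.at_level(logging.WARNING, logger="iqakit.iqa"):
        scale_dft_xc(t, -0.6)
    assert t.meta["xc_scaling"] == "impossible"
    assert t.xc_scale == 1.0


# ----------------------------------------------------------------------
# additive energies
# ----------------------------------------------------------------------

def test_half_share_arithmetic_two_atoms():
    t = IQATermMatrix(
        n_atoms=2,
        kinetic=np.array([-1.0, -2.0]), v_ne_own=np.zeros(2),
        vee_intra_coul=np.zeros(2), vee_intra_xc=np.zeros(2),
        v_nn=np.array([[0.0, -0.5], [-0.5, 0.0]]),
        v_en_cross=np.zeros((2, 2)), vee_coul=np.zeros((2, 2)),
        vee_xc=np.zeros((2, 2)),
    )
    e_add, mm = additive_energies(t, "half_share")
    assert np.allclose(e_add, [-1.25, -2.25])
    assert e_add.sum() + mm == pytest.approx(-3.5)


def test_qm_full_vs_half_share_with_qmmm_pair():
    t = IQATermMatrix(
        n_atoms=2,
        kinetic=np.array([-1.0, -2.0]), v_ne_own=np.zeros(2),
        vee_intra_coul=np.zeros(2), vee_intra_xc=np.zeros(2),
        v_nn=np.array([[0.0, -0.5], [-0.5, 0.0]]),
        v_en_cross=np.zeros((2, 2)), vee_coul=np.zeros((2, 2)),
        vee_xc=np.zeros((2, 2)),
        qmmm_ele=np.array([[-0.1], [0.0]]),
    )
    full, mm_full = additive_energies(t, "qm_full_qmmm")
    assert np.allclose(full, [-1.35, -2.25])
    assert mm_full == 0.0
    half, mm_half = additive_energies(t, "half_share")
    assert np.allclose(half, [-1.30, -2.25])
    assert mm_half == pytest.approx(-0.05)
    # both conventions reproduce the same total
    assert full.sum() + mm_full == pytest.approx(half.sum() + mm_half)


def test_additivity_exact_on_real_matrix(terms_h2o_desk):
    e_add, mm = additive_energies(terms_h2o_desk, "half_share")
    total, _ = reconstruct_total(terms_h2o_desk)
    assert e_add.sum() + mm == pytest.approx(total, abs=1e-12)


def test_unknown_convention_rejected(terms_h2_desk):
    with pytest.raises(ValueError, match="unknown convention"):
        additive_energies(terms_h2_desk, "thirds")


def test_pairwise_split_holds_exactly(terms_h2o_desk):
    t = terms_h2o_desk
    assert np.allclose(t.e_int, t.e_ele + t.e_xc, atol=0.0)
    assert np.allclose(t.e_int, t.e_int.T, atol=0.0)


# ----------------------------------------------------------------------
# localization and screening
# ----------------------------------------------------------------------

def test_single_mo_localization_is_identity(wfn_h2):
    loc = localize_orbitals(wfn_h2)
    assert loc is wfn_h2


def test_localization_preserves_density(wfn_h2o):
    loc = localize_orbitals(wfn_h2o)
    pts = np.random.default_rng(2).normal(scale=1.5, size=(100, 3))
    assert np.allclose(wfn_h2o.density(pts), loc.density(pts), atol=1e-8)


def test_localization_orthogonal_transform(wfn_h2o):
    loc = localize_orbitals(wfn_h2o)
    S = wfn_h2o.basis.overlap()
    C, _ = loc.occupied()
    assert np.allclose(C.T @ S @ C, np.eye(C.shape[1]), atol=1e-10)


def test_iqa_terms_invariant_under_localization(wfn_h2o, grid_h2o_mini,
                                                terms_h2o_mini):
    loc = localize_orbitals(wfn_h2o)
    terms_loc = build_term_matrix(loc, grid_h2o_mini)
    assert np.allclose(terms_loc.e_net, terms_h2o_mini.e_net, atol=1e-6)
    assert np.allclose(terms_loc.e_int, terms_h2o_mini.e_int, atol=1e-6)


def test_screening_threshold_zero_keeps_everything(wfn_h2o, grid_h2o_mini):
    overlaps = [
        atomic_overlap_diag(wfn_h2o, grid_h2o_mini, a) for a in range(3)
    ]
    subsets = screen_orbitals(grid_h2o_mini, overlaps, threshold=0.0)
    for s in subsets:
        assert s == [0, 1, 2, 3, 4]


def test_screening_isolated_atom_keeps_all(wfn_he, grid_he_desk):
    overlaps = [atomic_overlap_diag(wfn_he, grid_he_desk, 0)]
    subsets = screen_orbitals(grid_he_desk, overlaps, threshold=1e-6)
    assert subsets[0] == [0]


def test_screened_energies_match_unscreened(wfn_h2o, grid_h2o_mini,
                                            terms_h2o_mini):
    terms_s = build_term_matrix(wfn_h2o, grid_h2o_mini, screen_threshold=1e-6)
    assert np.allclose(terms_s.e_net, terms_h2o_mini.e_net, atol=1e-5)
    assert np.allclose(terms_s.e_int, terms_h2o_mini.e_int, atol=1e-5)


# ----------------------------------------------------------------------
# persistence
# ----------------------------------------------------------------------

def test_term_matrix_round_trip_bit_exact(terms_h2o_mini, tmp_path):
    from iqakit.container import load_term_matrix, save_term_matrix

    f = save_term_matrix(terms_h2o_mini, tmp_path / "terms.h5")
    back = load_term_matrix(f)
    for name in ("kinetic", "v_ne_own", "vee_intra_coul", "vee_intra_xc",
                 "v_nn", "v_en_cross", "vee_coul", "vee_xc"):
        assert np.array_equal(getattr(back, name), getattr(terms_h2o_mini, name))
    assert back.xc_scale == terms_h2o_mini.xc_scale
    assert back.scf_reference == terms_h2o_mini.scf_reference
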