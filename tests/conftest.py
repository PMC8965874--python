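"""Shared fixtures: packaged wavefunctions, cached basin grids and term
matrices (the expensive objects are built once per session)."""
import logging

import numpy as np
import pytest

logging.getLogger("iqakit").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def manifests():
    from iqakit.fixtures import manifest

    return manifest()


def _wfn(name):
    from iqakit.fixtures import load_fixture

    return load_fixture(name)


@pytest.fixture(scope="session")
def wfn_h2():
    return _wfn("h2_hf_sto3g")


@pytest.fixture(scope="session")
def wfn_he():
    return _wfn("he_hf_sto3g")


@pytest.fixture(scope="session")
def wfn_hehp():
    return _wfn("hehp_hf_sto3g")


@pytest.fixture(scope="session")
def wfn_h2o():
    return _wfn("h2o_hf_sto3g")


@pytest.fixture(scope="session")
def wfn_h2o_b3lyp():
    return _wfn("h2o_b3lyp_sto3g")


@pytest.fixture(scope="session")
def wfn_h2o_tz():
    return _wfn("h2o_b3lyp_tz")


@pytest.fixture(scope="session")
def wfn_methyl():
    return _wfn("methyl_link_hf_sto3g")


def _grid(wfn, preset):
    from iqakit.qtaim import build_basin_grid

    return build_basin_grid(wfn, preset)


@pytest.fixture(scope="session")
def grid_h2_desk(wfn_h2):
    return _grid(wfn_h2, "desk")


@pytest.fixture(scope="session")
def grid_he_desk(wfn_he):
    return _grid(wfn_he, "desk")


@pytest.fixture(scope="session")
def grid_hehp_desk(wfn_hehp):
    return _grid(wfn_hehp, "desk")


@pytest.fixture(scope="session")
def grid_h2o_desk(wfn_h2o):
    return _grid(wfn_h2o, "desk")


@pytest.fixture(scope="session")
def grid_h2o_mini(wfn_h2o):
    return _grid(wfn_h2o, "mini")


@pytest.fixture(scope="session")
def terms_h2_desk(wfn_h2, grid_h2_desk):
    from iqakit.iqa import build_term_matrix

    return build_term_matrix(wfn_h2, grid_h2_desk)


@pytest.fixture(scope="session")
def terms_he_desk(wfn_he, grid_he_desk):
    from iqakit.iqa import build_term_matrix

    return build_term_matrix(wfn_he, grid_he_desk)


@pytest.fixture(scope="session")
def terms_h2o_desk(wfn_h2o, grid_h2o_desk):
    from iqakit.iqa import build_term_matrix

    return build_term_matrix(wfn_h2o, grid_h2o_desk)


@pytest.fixture(scope="session")
def terms_h2o_mini(wfn_h2o, grid_h2o_mini):
    from iqakit.iqa import build_term_matrix

    return build_term_matrix(wfn_h2o, grid_h2o_mini)


@pytest.fixture(scope="session")
def toy_complex_run():
    """Toy host-guest complex with grid + term matrix + QM-MM terms."""
    from iqakit.fixtures import make_toy_complex
    from iqakit.iqa import build_term_matrix
    from iqakit.qmmm import build_interaction_mask, qmmm_electrostatics, qmmm_vdw
    from iqakit.qtaim import build_basin_grid
    from iqakit.sites import QM, SiteSet
    from iqakit.system import assemble_system
    from iqakit.units import HARTREE_TO_KCAL

    tc = make_toy_complex()
    qm_sites = SiteSet(
        ["O", "H", "H"], tc.ligand_wfn.coords,
        lj_eps=np.array([0.1520, 0.0, 0.0]),
        lj_rmin2=np.array([1.7683, 0.6, 0.6]),
        pb_radii=np.array([1.52, 1.2, 1.2]),
        region=np.array([QM] * 3, dtype=object),
    )
    system = assemble_system(tc.ligand_wfn, qm_sites, tc.cage, tc.topology)
    grid = build_basin_grid(tc.ligand_wfn, "mini")
    terms = build_term_matrix(tc.ligand_wfn, grid)
    mask = build_interaction_mask(system)
    terms.qmmm_ele = qmmm_electrostatics(system, grid, mask)
    terms.qmmm_vdw = qmmm_vdw(system, mask) / HARTREE_TO_KCAL
    terms.mm_site_index = mask.mm_sites
    return tc, system, grid, terms, mask
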