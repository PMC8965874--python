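"""Generate the packaged wavefunction fixtures and their manifests.

Run from the repository root:

    python scripts/make_fixtures.py [--fast]

Produces the committed files under src/iqakit/data/ .  The SCF engine is
the small closed-shell RHF/RKS implementation under scripts/scfgen; every
manifest records the level of theory, total/kinetic/nuclear energies and
the dipole so that tests can use them as oracles without re-running SCF.

The triple-zeta ("tz") basis is a reconstruction: published cc-pVTZ
primitive exponents with contraction coefficients re-derived by spherically
averaged atomic HF in the same primitives (no basis-set library is
available here); fixture metadata labels it "tz-synthetic".
"""
from __future__ import annotations

import argparse
import json
import math
import pathlib
import sys

import numpy as np

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from scfgen.basisdata import STO3G, TZ_PRIMS, sto3g_basis, tz_basis  # noqa: E402
from scfgen.integrals import eri_cart, nuclear_attraction, overlap_kinetic  # noqa: E402
from scfgen.scf import dipole_matrices, run_scf  # noqa: E402
from scfgen.writers import write_molden, write_wfx  # noqa: E402

from iqakit.basis import GaussianBasis, Shell  # noqa: E402
from iqakit.wavefunction import Wavefunction  # noqa: E402

DATA = pathlib.Path(__file__).resolve().parent.parent / "src" / "iqakit" / "data"
ANG = 1.0 / 0.529177


def tip3p_geometry(center=(0.0, 0.0, 0.0), rotation=None):
    """Rigid TIP3P water geometry in bohr: O-H 0.9572 A, H-O-H 104.52 deg."""
    r = 0.9572 * ANG
    th = math.radians(104.52 / 2.0)
    geom = np.array(
        [
            [0.0, 0.0, 0.0],
            [r * math.sin(th), 0.0, r * math.cos(th)],
            [-r * math.sin(th), 0.0, r * math.cos(th)],
        ]
    )
    if rotation is not None:
        geom = geom @ np.asarray(rotation).T
    return geom + np.asarray(center)


def atomic_contractions(sym: str) -> dict:
    """Derive tz contraction coefficients by atomic HF in the primitives."""
    prim = TZ_PRIMS[sym]
    if sym == "H":
        b = GaussianBasis([Shell(0, 0, [0, 0, 0], [e], [1.0]) for e in prim["s"]])
        S, T = overlap_kinetic(b)
        V = nuclear_attraction(b, [1.0], [[0, 0, 0]])
        ev, U = np.linalg.eigh(S)
        X = U / np.sqrt(ev)
        e, c = np.linalg.eigh(X.T @ (T + V) @ X)
        c1 = X @ c[:, 0]
        if c1[np.argmax(np.abs(c1))] < 0:
            c1 = -c1
        return {"s": [c1]}
    Z = {"O": 8.0}[sym]
    nspr = len(prim["s"])
    shells = [Shell(0, 0, [0, 0, 0], [e], [1.0]) for e in prim["s"]]
    shells += [Shell(0, 1, [0, 0, 0], [e], [1.0]) for e in prim["p"]]
    b = GaussianBasis(shells)
    S, T = overlap_kinetic(b)
    V = nuclear_attraction(b, [Z], [[0, 0, 0]])
    eri = eri_cart(b)
    h = T + V
    ev, U = np.linalg.eigh(S)
    X = U[:, ev > 1e-10] / np.sqrt(ev[ev > 1e-10])
    F = h.copy()
    e_old = 0.0
    # spherically averaged occupations: 1s2 2s2 2p(4/3 each)
    for it in range(500):
        e, c = np.linalg.eigh(X.T @ F @ X)
        C = X @ c
        p_w = np.einsum("ui,uv,vi->i", C[nspr:], S[nspr:, nspr:], C[nspr:])
        s_mos = [i for i in range(C.shape[1]) if p_w[i] < 0.5]
        p_mos = [i for i in range(C.shape[1]) if p_w[i] >= 0.5]
        occ = np.zeros(C.shape[1])
        occ[s_mos[0]] = occ[s_mos[1]] = 2.0
        for i in p_mos[:3]:
            occ[i] = 4.0 / 3.0
        D = (C * occ) @ C.T
        J = np.einsum("ijkl,kl->ij", eri, D, optimize=True)
        K = np.einsum("ikjl,kl->ij", eri, D, optimize=True)
        E = np.sum(D * h) + 0.5 * np.sum(D * J) - 0.25 * np.sum(D * K)
        if abs(E - e_old) < 1e-12 and it > 5:
            break
        e_old = E
        F = 0.5 * (h + J - 0.5 * K) + 0.5 * F
    c1s = C[:nspr, s_mos[0]]
    c2s = C[:nspr, s_mos[1]]
    Cp = C[nspr:, p_mos[0]].reshape(len(prim["p"]), 3)
    comp = int(np.argmax((Cp**2).sum(axis=0)))
    cp = Cp[:, comp]
    out = []
    for cvec in (c1s, c2s, cp):
        if cvec[np.argmax(np.abs(cvec))] < 0:
            cvec = -cvec
        out.append(cvec)
    return {"s": out[:2], "p": [out[2]]}


def _dipole(res, basis, numbers, coords):
    Cocc = res.mo_coeff[:, res.mo_occ > 0]
    D = 2.0 * Cocc @ Cocc.T
    dm = dipole_matrices(basis)
    if basis.spherical:
        Tr = basis.sph_transform()
        dm = np.einsum("pi,aij,qj->apq", Tr, dm, Tr)
    el = -np.einsum("apq,pq->a", dm, D)
    return el + np.asarray(numbers, float) @ np.atleast_2d(coords)


def _sample_points(coords):
    coords = np.atleast_2d(coords)
    com = coords.mean(axis=0)
    offsets = np.array(
        [
            [0.3, 0.2, -0.1],
            [-0.5, 0.4, 0.3],
            [0.9, -0.7, 0.5],
            [0.0, 0.0, 1.1],
            [1.7, 1.3, -0.9],
            [-2.1, 0.6, 1.4],
        ]
    )
    return com + offsets


def _manifest(name, res, basis, numbers, coords, symbols, basis_label,
              method, functional=None, extra=None):
    wfn = Wavefunction(
        numbers=numbers, coords=coords, basis=basis,
        mo_coeff=res.mo_coeff, mo_occ=res.mo_occ,
    )
    pts = _sample_points(coords)
    rho, grad = wfn.density(pts, deriv=1)
    mu = _dipole(res, basis, numbers, coords)
    man = {
        "name": name,
        "method": method,
        "functional": functional,
        "basis": basis_label,
        "symbols": list(symbols),
        "numbers": [float(z) for z in numbers],
        "coords_bohr": np.atleast_2d(coords).tolist(),
        "n_electrons": float(res.mo_occ.sum()),
        "n_occupied": int((res.mo_occ > 0).sum()),
        "scf_energy": res.energy,
        "kinetic_energy": res.components["e_kinetic"],
        "nuclear_repulsion": res.components["e_nuclear_repulsion"],
        "components": res.components,
        "dipole_au": mu.tolist(),
        "dipole_debye": float(np.linalg.norm(mu) * 2.541746),
        "sample_points_bohr": pts.tolist(),
        "sample_rho": rho.tolist(),
        "sample_grad_rho": grad.tolist(),
        "converged": bool(res.converged),
    }
    if extra:
        man.update(extra)
    return man


def write_mm_fixtures():
    """Small MM-format text fixtures (prmtop / toy topology / xyzq / pqr)."""
    eps_o, rmin2_o = 0.1520, 1.7683
    rmin_oo = 2 * rmin2_o
    a_oo = eps_o * rmin_oo**12
    b_oo = 2 * eps_o * rmin_oo**6
    q_o, q_h = -0.834 * 18.2223, 0.417 * 18.2223

    def fmt(vals, per, spec):
        return "\n".join(
            "".join(spec % v for v in vals[i : i + per])
            for i in range(0, len(vals), per)
        )

    ptr = [3, 2, 2, 0, 1, 0, 0, 0, 0, 0,
           0, 1, 0, 0, 0, 1, 1, 0, 0, 0,
           0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
    t = []
    t.append("%VERSION  VERSION_STAMP = V0001.000  DATE = 01/01/24")
    t += ["%FLAG TITLE", "%FORMAT(20a4)", "TIP3P water"]
    t += ["%FLAG POINTERS", "%FORMAT(10I8)", fmt(ptr, 10, "%8d")]
    t += ["%FLAG ATOM_NAME", "%FORMAT(20a4)", "O   H1  H2  "]
    t += ["%FLAG CHARGE", "%FORMAT(5E16.8)", fmt([q_o, q_h, q_h], 5, "%16.8E")]
    t += ["%FLAG ATOMIC_NUMBER", "%FORMAT(10I8)", fmt([8, 1, 1], 10, "%8d")]
    t += ["%FLAG MASS", "%FORMAT(5E16.8)", fmt([16.0, 1.008, 1.008], 5, "%16.8E")]
    t += ["%FLAG ATOM_TYPE_INDEX", "%FORMAT(10I8)", fmt([1, 2, 2], 10, "%8d")]
    t += ["%FLAG NUMBER_EXCLUDED_ATOMS", "%FORMAT(10I8)", fmt([2, 1, 1], 10, "%8d")]
    t += ["%FLAG NONBONDED_PARM_INDEX", "%FORMAT(10I8)", fmt([1, 2, 2, 3], 10, "%8d")]
    t += ["%FLAG LENNARD_JONES_ACOEF", "%FORMAT(5E16.8)", fmt([a_oo, 0.0, 0.0], 5, "%16.8E")]
    t += ["%FLAG LENNARD_JONES_BCOEF", "%FORMAT(5E16.8)", fmt([b_oo, 0.0, 0.0], 5, "%16.8E")]
    t += ["%FLAG BONDS_INC_HYDROGEN", "%FORMAT(10I8)", fmt([0, 3, 1, 0, 6, 1], 10, "%8d")]
    t += ["%FLAG BOND_FORCE_CONSTANT", "%FORMAT(5E16.8)", fmt([450.0], 5, "%16.8E")]
    t += ["%FLAG BOND_EQUIL_VALUE", "%FORMAT(5E16.8)", fmt([0.9572], 5, "%16.8E")]
    t += ["%FLAG ANGLES_INC_HYDROGEN", "%FORMAT(10I8)", fmt([3, 0, 6, 1], 10, "%8d")]
    t += ["%FLAG ANGLE_FORCE_CONSTANT", "%FORMAT(5E16.8)", fmt([55.0], 5, "%16.8E")]
    t += ["%FLAG ANGLE_EQUIL_VALUE", "%FORMAT(5E16.8)",
          fmt([math.radians(104.52)], 5, "%16.8E")]
    t += ["%FLAG EXCLUDED_ATOMS_LIST", "%FORMAT(10I8)", fmt([2, 3, 3, 0], 10, "%8d")]
    t += ["%FLAG SCEE_SCALE_FACTOR", "%FORMAT(5E16.8)", fmt([1.2], 5, "%16.8E")]
    t += ["%FLAG SCNB_SCALE_FACTOR", "%FORMAT(5E16.8)", fmt([2.0], 5, "%16.8E")]
    t += ["%FLAG RADII", "%FORMAT(5E16.8)", fmt([1.52, 1.2, 1.2], 5, "%16.8E")]
    (DATA / "tip3p_water.prmtop").write_text("\n".join(t) + "\n")

    (DATA / "toy_water_pair.top").write_text(
        "# toy topology: two rigid waters (atoms 1-3, 4-6)\n"
        "natoms 6\n"
        "bond 1 2 450.0 0.9572\nbond 1 3 450.0 0.9572\n"
        "angle 2 1 3 55.0 104.52\n"
        "bond 4 5 450.0 0.9572\nbond 4 6 450.0 0.9572\n"
        "angle 5 4 6 55.0 104.52\n"
        "exclude 1 2\nexclude 1 3\nexclude 2 3\n"
        "exclude 4 5\nexclude 4 6\nexclude 5 6\n"
        "scee 1.2\nscnb 2.0\n"
    )
    (DATA / "tip3p_water.xyzq").write_text(
        "# element x y z q [eps rmin2 radius] (A, e, kcal/mol)\n"
        "O  0.000000  0.000000  0.000000  -0.834  0.1520 1.7683 1.52\n"
        "H  0.756950  0.000000  0.585882   0.417  0.0000 0.6000 1.20\n"
        "H -0.756950  0.000000  0.585882   0.417  0.0000 0.6000 1.20\n"
    )
    (DATA / "tip3p_water.pqr").write_text(
        "ATOM      1  O   HOH     1       0.000   0.000   0.000 -0.834 1.52\n"
        "ATOM      2  H1  HOH     1       0.757   0.000   0.586  0.417 1.20\n"
        "ATOM      3  H2  HOH     1      -0.757   0.000   0.586  0.417 1.20\n"
    )


def main(fast=False):
    DATA.mkdir(parents=True, exist_ok=True)
    manifests = {}

    # ------------------------------------------------------ H2 HF/STO-3G
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.4]])
    basis = sto3g_basis(["H", "H"], coords)
    res = run_scf([1, 1], coords, basis, method="HF")
    write_wfx(DATA / "h2_hf_sto3g.wfx", [1, 1], coords, basis,
              res.mo_coeff, res.mo_occ, res.mo_energy, res.energy,
              title="H2 RHF/STO-3G R=1.4 bohr")
    manifests["h2_hf_sto3g"] = _manifest(
        "h2_hf_sto3g", res, basis, [1, 1], coords, ["H", "H"], "STO-3G", "HF")

    # ------------------------------------------------------ He HF/STO-3G
    coords = np.zeros((1, 3))
    basis = sto3g_basis(["He"], coords)
    res = run_scf([2], coords, basis, method="HF")
    write_wfx(DATA / "he_hf_sto3g.wfx", [2], coords, basis,
              res.mo_coeff, res.mo_occ, res.mo_energy, res.energy,
              title="He RHF/STO-3G")
    manifests["he_hf_sto3g"] = _manifest(
        "he_hf_sto3g", res, basis, [2], coords, ["He"], "STO-3G", "HF")

    # ---------------------------------------------------- HeH+ HF/STO-3G
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.4632]])
    basis = sto3g_basis(["He", "H"], coords)
    res = run_scf([2, 1], coords, basis, method="HF", charge=1)
    write_wfx(DATA / "hehp_hf_sto3g.wfx", [2, 1], coords, basis,
              res.mo_coeff, res.mo_occ, res.mo_energy, res.energy,
              title="HeH+ RHF/STO-3G R=1.4632 bohr")
    manifests["hehp_hf_sto3g"] = _manifest(
        "hehp_hf_sto3g", res, basis, [2, 1], coords, ["He", "H"],
        "STO-3G", "HF", extra={"charge": 1})

    # ----------------------------------------------------- H2O HF/STO-3G
    coords = tip3p_geometry()
    basis = sto3g_basis(["O", "H", "H"], coords)
    res = run_scf([8, 1, 1], coords, basis, method="HF")
    write_wfx(DATA / "h2o_hf_sto3g.wfx", [8, 1, 1], coords, basis,
              res.mo_coeff, res.mo_occ, res.mo_energy, res.energy,
              title="H2O RHF/STO-3G TIP3P geometry")
    write_molden(DATA / "h2o_hf_sto3g.molden", [8, 1, 1], coords, basis,
                 res.mo_coeff, res.mo_occ, res.mo_energy,
                 title="H2O RHF/STO-3G TIP3P geometry", occupied_only=False)
    manifests["h2o_hf_sto3g"] = _manifest(
        "h2o_hf_sto3g", res, basis, [8, 1, 1], coords, ["O", "H", "H"],
        "STO-3G", "HF")

    # -------------------------------------------------- H2O B3LYP/STO-3G
    res = run_scf([8, 1, 1], coords, basis, method="B3LYP",
                  grid_level=(60, 16))
    write_molden(DATA / "h2o_b3lyp_sto3g.molden", [8, 1, 1], coords, basis,
                 res.mo_coeff, res.mo_occ, res.mo_energy,
                 title="H2O B3LYP/STO-3G TIP3P geometry")
    manifests["h2o_b3lyp_sto3g"] = _manifest(
        "h2o_b3lyp_sto3g", res, basis, [8, 1, 1], coords, ["O", "H", "H"],
        "STO-3G", "DFT", functional="B3LYP")

    # ------------------------------------------- embedded H2O (QM/MM toy)
    # point-charge cage: two TIP3P waters flanking the QM water
    mm1 = tip3p_geometry(center=(0.0, 5.2, 0.5))
    mm2 = tip3p_geometry(center=(0.0, -5.2, 0.5))
    mm_xyz = np.vstack([mm1, mm2])
    mm_q = np.array([-0.834, 0.417, 0.417, -0.834, 0.417, 0.417])
    basis = sto3g_basis(["O", "H", "H"], coords)
    res = run_scf([8, 1, 1], coords, basis, method="HF",
                  point_charges=(mm_q, mm_xyz))
    write_wfx(DATA / "h2o_embedded_sto3g.wfx", [8, 1, 1], coords, basis,
              res.mo_coeff, res.mo_occ, res.mo_energy, res.energy,
              title="H2O RHF/STO-3G embedded in 2 TIP3P point-charge waters")
    manifests["h2o_embedded_sto3g"] = _manifest(
        "h2o_embedded_sto3g", res, basis, [8, 1, 1], coords,
        ["O", "H", "H"], "STO-3G", "HF",
        extra={
            "point_charges": mm_q.tolist(),
            "point_charge_coords_bohr": mm_xyz.tolist(),
            "e_nuc_point_charges": res.components["e_nuc_point_charges"],
        })

    # ------------------------------------- CH3(+link H) for the QM/MM cut
    # methyl fragment of ethane, link H placed along the former C-C bond
    rcc = 1.526 * ANG
    rch = 1.090 * ANG
    rlink = 1.090 * ANG
    c0 = np.zeros(3)
    # tetrahedral methyl pointing -z; link H along +z toward the cut C
    ang_t = math.radians(109.47)
    hs = []
    for k in range(3):
        phi = 2 * math.pi * k / 3
        hs.append(
            c0
            + rch
            * np.array(
                [
                    math.sin(ang_t) * math.cos(phi),
                    math.sin(ang_t) * math.sin(phi),
                    math.cos(ang_t),
                ]
            )
        )
    hlink = c0 + np.array([0.0, 0.0, rlink])
    coords_l = np.vstack([c0] + hs + [hlink])
    syms_l = ["C", "H", "H", "H", "H"]
    basis = sto3g_basis(syms_l, coords_l)
    res = run_scf([6, 1, 1, 1, 1], coords_l, basis, method="HF")
    write_wfx(DATA / "methyl_link_hf_sto3g.wfx", [6, 1, 1, 1, 1], coords_l,
              basis, res.mo_coeff, res.mo_occ, res.mo_energy, res.energy,
              title="CH3 + H-link RHF/STO-3G (ethane QM/MM cut)")
    manifests["methyl_link_hf_sto3g"] = _manifest(
        "methyl_link_hf_sto3g", res, basis, [6, 1, 1, 1, 1], coords_l,
        syms_l, "STO-3G", "HF",
        extra={"link_atom_index": 4, "cc_bond_bohr": rcc})

    # ------------------------------------------------- H2O B3LYP/TZ (t5)
    if not fast:
        ctr = {"H": atomic_contractions("H"), "O": atomic_contractions("O")}
        coords = tip3p_geometry()
        basis = tz_basis(["O", "H", "H"], coords, ctr)
        res = run_scf([8, 1, 1], coords, basis, method="B3LYP",
                      grid_level=(90, 24))
        write_molden(DATA / "h2o_b3lyp_tz.molden", [8, 1, 1], coords, basis,
                     res.mo_coeff, res.mo_occ, res.mo_energy,
                     title="H2O B3LYP/tz-synthetic (cc-pVTZ-style) TIP3P geometry")
        manifests["h2o_b3lyp_tz"] = _manifest(
            "h2o_b3lyp_tz", res, basis, [8, 1, 1], coords, ["O", "H", "H"],
            "tz-synthetic", "DFT", functional="B3LYP")

    write_mm_fixtures()

    with open(DATA / "manifest.json", "w") as fh:
        json.dump(manifests, fh, indent=1)
    print("wrote", len(manifests), "fixtures to", DATA)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true", help="skip the tz fixture")
    main(**vars(ap.parse_args()))
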