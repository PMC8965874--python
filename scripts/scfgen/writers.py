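"""Writers for the packaged wavefunction fixtures (wfx / molden)."""
from __future__ import annotations

import numpy as np

from iqakit.basis import GaussianBasis, cart_powers, prim_norm
from iqakit.units import element_symbol

# wfx/wfn primitive type codes for our canonical cartesian component order
WFX_TYPE = {
    (0, (0, 0, 0)): 1,
    (1, (1, 0, 0)): 2, (1, (0, 1, 0)): 3, (1, (0, 0, 1)): 4,
    (2, (2, 0, 0)): 5, (2, (0, 2, 0)): 6, (2, (0, 0, 2)): 7,
    (2, (1, 1, 0)): 8, (2, (1, 0, 1)): 9, (2, (0, 1, 1)): 10,
    (3, (3, 0, 0)): 11, (3, (0, 3, 0)): 12, (3, (0, 0, 3)): 13,
    (3, (2, 1, 0)): 14, (3, (2, 0, 1)): 15, (3, (0, 2, 1)): 16,
    (3, (1, 2, 0)): 17, (3, (1, 0, 2)): 18, (3, (0, 1, 2)): 19,
    (3, (1, 1, 1)): 20,
}


def write_wfx(path, numbers, coords, basis: GaussianBasis, mo_coeff, mo_occ,
              mo_energy, energy, title="iqakit fixture"):
    """Write an AIM wfx file.

    MO coefficients are expanded over raw (unnormalized) cartesian
    primitives, i.e. normalization and contraction are folded into the
    printed coefficients, following common wfn/wfx practice.
    """
    if basis.spherical:
        T = basis.sph_transform()
        mo_cart = T.T @ mo_coeff
    else:
        mo_cart = mo_coeff
    occ_mask = np.asarray(mo_occ) > 1e-12
    occs = np.asarray(mo_occ)[occ_mask]
    enes = np.asarray(mo_energy)[occ_mask]
    C = mo_cart[:, occ_mask]

    centers, types, exps, prim_rows = [], [], [], []
    iao = 0
    for sh in basis.shells:
        for comp in cart_powers(sh.l):
            for alpha, cf in zip(sh.exps, sh.coefs):
                centers.append(sh.atom + 1)
                types.append(WFX_TYPE[(sh.l, comp)])
                exps.append(alpha)
                prim_rows.append(cf * prim_norm(alpha, *comp) * C[iao])
            iao += 1
    prim_rows = np.array(prim_rows)  # (nprim, nmo_occ)

    nelec = float(occs.sum())
    lines = []
    w = lines.append
    w("<Title>")
    w(f" {title}")
    w("</Title>")
    w("<Keywords>")
    w(" GTO")
    w("</Keywords>")
    w("<Number of Nuclei>")
    w(f" {len(numbers)}")
    w("</Number of Nuclei>")
    w("<Number of Occupied Molecular Orbitals>")
    w(f" {len(occs)}")
    w("</Number of Occupied Molecular Orbitals>")
    w("<Number of Perturbations>")
    w(" 0")
    w("</Number of Perturbations>")
    w("<Number of Electrons>")
    w(f" {int(round(nelec))}")
    w("</Number of Electrons>")
    w("<Charge>")
    w(f" {int(round(sum(numbers) - nelec))}")
    w("</Charge>")
    w("<Electronic Spin Multiplicity>")
    w(" 1")
    w("</Electronic Spin Multiplicity>")
    w("<Nuclear Names>")
    for i, z in enumerate(numbers):
        w(f" {element_symbol(int(z))}{i + 1}")
    w("</Nuclear Names>")
    w("<Atomic Numbers>")
    for z in numbers:
        w(f" {int(z)}")
    w("</Atomic Numbers>")
    w("<Nuclear Charges>")
    for z in numbers:
        w(f" {float(z):.10E}")
    w("</Nuclear Charges>")
    w("<Nuclear Cartesian Coordinates>")
    for xyz in np.atleast_2d(coords):
        w(" " + " ".join(f"{v: .12E}" for v in xyz))
    w("</Nuclear Cartesian Coordinates>")
    w("<Number of Primitives>")
    w(f" {len(exps)}")
    w("</Number of Primitives>")
    w("<Primitive Centers>")
    _wrap_ints(w, centers)
    w("</Primitive Centers>")
    w("<Primitive Types>")
    _wrap_ints(w, types)
    w("</Primitive Types>")
    w("<Primitive Exponents>")
    _wrap_floats(w, exps)
    w("</Primitive Exponents>")
    w("<Molecular Orbital Occupation Numbers>")
    for o in occs:
        w(f" {o:.12E}")
    w("</Molecular Orbital Occupation Numbers>")
    w("<Molecular Orbital Energies>")
    for e in enes:
        w(f" {e:.12E}")
    w("</Molecular Orbital Energies>")
    w("<Molecular Orbital Spin Types>")
    for _ in occs:
        w(" Alpha and Beta")
    w("</Molecular Orbital Spin Types>")
    w("<Molecular Orbital Primitive Coefficients>")
    for imo in range(len(occs)):
        w("<MO Number>")
        w(f" {imo + 1}")
        w("</MO Number>")
        _wrap_floats(w, prim_rows[:, imo])
    w("</Molecular Orbital Primitive Coefficients>")
    w("<Energy = T + Vne + Vee + Vnn>")
    w(f" {energy:.12E}")
    w("</Energy = T + Vne + Vee + Vnn>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _wrap_ints(w, vals, per=10):
    for i in range(0, len(vals), per):
        w(" " + " ".join(str(v) for v in vals[i : i + per]))


def _wrap_floats(w, vals, per=4):
    for i in range(0, len(vals), per):
        w(" " + " ".join(f"{float(v): .12E}" for v in vals[i : i + per]))


_LCHAR = {0: "s", 1: "p", 2: "d", 3: "f"}


def write_molden(path, numbers, coords, basis: GaussianBasis, mo_coeff, mo_occ,
                 mo_energy, title="iqakit fixture", occupied_only=True):
    """Write a molden file (spherical [5D][7F] if the basis is spherical)."""
    lines = ["[Molden Format]", "[Title]", f" {title}", "[Atoms] AU"]
    for i, (z, xyz) in enumerate(zip(numbers, np.atleast_2d(coords))):
        sym = element_symbol(int(z))
        lines.append(
            f" {sym:<3s} {i + 1:4d} {int(z):4d} "
            + " ".join(f"{v: .10f}" for v in xyz)
        )
    lines.append("[GTO]")
    for ia in range(len(numbers)):
        lines.append(f" {ia + 1} 0")
        for sh in basis.shells:
            if sh.atom != ia:
                continue
            lines.append(f" {_LCHAR[sh.l]} {len(sh.exps)} 1.00")
            for e, c in zip(sh.exps, sh.coefs):
                lines.append(f"  {e: .10E} {c: .10E}")
        lines.append("")
    if basis.spherical:
        lines.append("[5D]")
        lines.append("[7F]")
    lines.append("[MO]")
    mo_occ = np.asarray(mo_occ)
    for imo in range(mo_coeff.shape[1]):
        if occupied_only and mo_occ[imo] <= 1e-12:
            continue
        lines.append(" Sym= A")
        lines.append(f" Ene= {mo_energy[imo]: .10E}")
        lines.append(" Spin= Alpha")
        lines.append(f" Occup= {mo_occ[imo]:.8f}")
        for iao in range(mo_coeff.shape[0]):
            lines.append(f" {iao + 1:4d}  {mo_coeff[iao, imo]: .12E}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
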