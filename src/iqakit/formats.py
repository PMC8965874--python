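"""Readers for wavefunction-exchange formats (AIM wfx, molden).

Both readers produce a :class:`~iqakit.wavefunction.Wavefunction` whose MO
coefficients refer to the AO conventions of :mod:`iqakit.basis`.

wfx: primitives are raw Cartesian Gaussians ``x^a y^b z^c exp(-a r^2)``
with normalization folded into the printed MO coefficients (the common
wfn/wfx practice).  Each primitive becomes a one-primitive shell and its
coefficient is un-folded into the normalized-AO convention on load.

molden: contracted shells; ``[5D]/[7F]`` selects real-spherical d/f
ordering ``m = 0, +1, -1, ...``; without those flags Cartesian components
are assumed, normalized per component.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .basis import GaussianBasis, Shell, cart_powers, prim_norm
from .wavefunction import Wavefunction

__all__ = ["load_wavefunction", "read_wfx", "read_molden"]


class ParseError(ValueError):
    pass


def load_wavefunction(path, format: str | None = None) -> Wavefunction:
    """Load a wavefunction from a wfx or molden file.

    The format is inferred from the suffix when not given.  The returned
    wavefunction has passed its consistency checks (electron count,
    occupied-MO orthonormality, shell-center validity).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "wfx" if path.suffix.lower() == ".wfx" else "molden"
    if format == "wfx":
        wfn = read_wfx(path)
    elif format == "molden":
        wfn = read_molden(path)
    else:
        raise ValueError(f"unsupported wavefunction format {format!r}")
    wfn.validate()
    return wfn


# ----------------------------------------------------------------------
# wfx
# ----------------------------------------------------------------------

_WFX_POWERS = {
    1: (0, (0, 0, 0)),
    2: (1, (1, 0, 0)), 3: (1, (0, 1, 0)), 4: (1, (0, 0, 1)),
    5: (2, (2, 0, 0)), 6: (2, (0, 2, 0)), 7: (2, (0, 0, 2)),
    8: (2, (1, 1, 0)), 9: (2, (1, 0, 1)), 10: (2, (0, 1, 1)),
    11: (3, (3, 0, 0)), 12: (3, (0, 3, 0)), 13: (3, (0, 0, 3)),
    14: (3, (2, 1, 0)), 15: (3, (2, 0, 1)), 16: (3, (0, 2, 1)),
    17: (3, (1, 2, 0)), 18: (3, (1, 0, 2)), 19: (3, (0, 1, 2)),
    20: (3, (1, 1, 1)),
}


def _wfx_sections(text: str) -> dict[str, str]:
    secs = {}
    for m in re.finditer(r"<([^/<>]+)>\n(.*?)\n</\1>", text, re.S):
        secs[m.group(1).strip()] = m.group(2)
    return secs


def read_wfx(path) -> Wavefunction:
    text = Path(path).read_text()
    secs = _wfx_sections(text)

    def need(tag):
        if tag not in secs:
            raise ParseError(f"{path}: missing wfx record <{tag}>")
        return secs[tag]

    nat = int(need("Number of Nuclei"))
    numbers = np.array([float(x) for x in need("Nuclear Charges").split()])
    coords = np.array(
        [float(x) for x in need("Nuclear Cartesian Coordinates").split()]
    ).reshape(nat, 3)
    nprim = int(need("Number of Primitives"))
    centers = [int(x) - 1 for x in need("Primitive Centers").split()]
    types = [int(x) for x in need("Primitive Types").split()]
    exps = [float(x) for x in need("Primitive Exponents").split()]
    if not (len(centers) == len(types) == len(exps) == nprim):
        raise ParseError(f"{path}: primitive record lengths disagree")
    occs = np.array(
        [float(x) for x in need("Molecular Orbital Occupation Numbers").split()]
    )
    enes = np.array(
        [float(x) for x in need("Molecular Orbital Energies").split()]
    )
    spins = need("Molecular Orbital Spin Types")
    if re.search(r"^\s*(Alpha|Beta)\s*$", spins, re.M):
        raise ParseError(
            f"{path}: open-shell wfx (spin-resolved orbitals) not supported"
        )

    coef_sec = need("Molecular Orbital Primitive Coefficients")
    # strip <MO Number> markers, collect per-MO blocks
    blocks = re.split(r"<MO Number>\s*\d+\s*</MO Number>", coef_sec)
    blocks = [b for b in blocks if b.strip()]
    if len(blocks) != len(occs):
        raise ParseError(
            f"{path}: found {len(blocks)} MO coefficient blocks for "
            f"{len(occs)} occupations"
        )
    cmat = np.array([[float(x) for x in b.split()] for b in blocks]).T
    if cmat.shape[0] != nprim:
        raise ParseError(f"{path}: MO coefficient count != primitive count")

    shells = []
    Cconv = np.empty_like(cmat)
    row = 0
    for ip in range(nprim):
        if types[ip] not in _WFX_POWERS:
            raise ParseError(f"{path}: unsupported primitive type {types[ip]}")
        l, (a, b, c) = _WFX_POWERS[types[ip]]
        # represent as a one-primitive shell; only the matching component
        # carries a coefficient
        shells.append(Shell(centers[ip], l, coords[centers[ip]], [exps[ip]], [1.0]))
        ncomp = len(cart_powers(l))
        block = np.zeros((ncomp, cmat.shape[1]))
        comp_index = cart_powers(l).index((a, b, c))
        block[comp_index] = cmat[ip] / prim_norm(exps[ip], a, b, c)
        if row + ncomp > Cconv.shape[0]:
            Cconv = np.vstack([Cconv, np.zeros((ncomp, cmat.shape[1]))])
        Cconv[row : row + ncomp] = block
        row += ncomp
    Cconv = Cconv[:row]

    energy = None
    for tag in secs:
        if tag.startswith("Energy"):
            energy = float(secs[tag].split()[0])
    nelec = float(need("Number of Electrons"))
    return Wavefunction(
        numbers=numbers,
        coords=coords,
        basis=GaussianBasis(shells, spherical=False),
        mo_coeff=Cconv,
        mo_occ=occs,
        mo_energy=enes,
        energy=energy,
        n_electrons_declared=nelec,
        method="HF",
        source=str(path),
    )


# ----------------------------------------------------------------------
# molden
# ----------------------------------------------------------------------

_L_OF = {"s": 0, "p": 1, "d": 2, "f": 3}

# molden cartesian component orders mapped onto our canonical order
_MOLDEN_CART = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
    3: [
        (3, 0, 0), (0, 3, 0), (0, 0, 3), (1, 2, 0), (2, 1, 0),
        (2, 0, 1), (1, 0, 2), (0, 1, 2), (0, 2, 1), (1, 1, 1),
    ],
}


def read_molden(path) -> Wavefunction:
    lines = Path(path).read_text().splitlines()
    sections: dict[str, list[str]] = {}
    tag = None
    flags = set()
    for raw in lines:
        line = raw.strip()
        m = re.match(r"\[([^\]]+)\]\s*(.*)", line)
        if m:
            name = m.group(1).lower()
            if name in ("5d", "7f", "9g", "6d", "10f", "5d7f", "5d10f"):
                flags.add(name)
                continue
            tag = name
            sections[tag] = []
            rest = m.group(2).strip()
            if rest:
                sections[tag].append(rest)
            continue
        if tag is not None:
            sections[tag].append(raw)

    if "atoms" not in sections or "gto" not in sections or "mo" not in sections:
        raise ParseError(f"{path}: missing [Atoms], [GTO] or [MO] section")
    spherical = "5d" in flags or "5d7f" in flags

    # ----- atoms ([Atoms] AU | Angs; the unit token lands as first content)
    unit = 1.0
    atoms_lines = [ln for ln in sections["atoms"] if ln.strip()]
    if atoms_lines and atoms_lines[0].strip().lower() in ("au", "angs", "angstrom"):
        if atoms_lines[0].strip().lower() != "au":
            unit = 1.0 / 0.529177
        atoms_lines = atoms_lines[1:]
    numbers, coords = [], []
    for ln in atoms_lines:
        parts = ln.split()
        if len(parts) < 6:
            raise ParseError(f"{path}: malformed [Atoms] line: {ln!r}")
        numbers.append(float(parts[2]))
        coords.append([float(x) * unit for x in parts[3:6]])
    numbers = np.array(numbers)
    coords = np.array(coords)

    # ----- GTO
    shells = []
    i = 0
    gto = [ln for ln in sections["gto"]]
    while i < len(gto):
        ln = gto[i].strip()
        i += 1
        if not ln:
            continue
        parts = ln.split()
        if len(parts) >= 1 and parts[0].isdigit() and (len(parts) == 1 or parts[1] in ("0",)):
            atom = int(parts[0]) - 1
            # shells until blank line
            while i < len(gto):
                sline = gto[i].strip()
                if not sline:
                    i += 1
                    break
                sp = sline.split()
                ltag = sp[0].lower()
                if ltag not in _L_OF and ltag != "sp":
                    raise ParseError(f"{path}: unsupported shell type {sp[0]!r}")
                nprim = int(sp[1])
                i += 1
                exps, cs, cp = [], [], []
                for _ in range(nprim):
                    nums = gto[i].replace("D", "E").replace("d", "e").split()
                    exps.append(float(nums[0]))
                    cs.append(float(nums[1]))
                    if ltag == "sp":
                        cp.append(float(nums[2]))
                    i += 1
                if ltag == "sp":
                    shells.append(Shell(atom, 0, coords[atom], exps, cs))
                    shells.append(Shell(atom, 1, coords[atom], exps, cp))
                else:
                    shells.append(Shell(atom, _L_OF[ltag], coords[atom], exps, cs))
        else:
            raise ParseError(f"{path}: unexpected [GTO] line: {ln!r}")
    basis = GaussianBasis(shells, spherical=spherical)

    # ----- MO
    nao = basis.n_ao
    mo_blocks = []
    cur = None
    for ln in sections["mo"]:
        s = ln.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith("sym="):
            cur = {"coeff": np.zeros(nao), "occ": 0.0, "ene": 0.0}
            mo_blocks.append(cur)
            continue
        if cur is None and ("=" in low or s[0].isdigit()):
            cur = {"coeff": np.zeros(nao), "occ": 0.0, "ene": 0.0}
            mo_blocks.append(cur)
        if low.startswith("ene="):
            cur["ene"] = float(s.split("=")[1])
        elif low.startswith("spin="):
            if "beta" in low:
                raise ParseError(f"{path}: open-shell molden not supported")
        elif low.startswith("occup="):
            cur["occ"] = float(s.split("=")[1])
        else:
            parts = s.split()
            try:
                idx = int(parts[0]) - 1
                val = float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: malformed [MO] line: {ln!r}") from exc
            cur["coeff"][idx] = val

    C_file = np.array([b["coeff"] for b in mo_blocks]).T  # (nao, nmo) molden order
    occs = np.array([b["occ"] for b in mo_blocks])
    enes = np.array([b["ene"] for b in mo_blocks])

    # reorder AO rows from molden component order to canonical order
    perm = np.zeros(nao, dtype=int)
    pos = 0
    for sh in shells:
        if spherical:
            n = sh.n_sph
            perm[pos : pos + n] = np.arange(pos, pos + n)  # same m-order
        else:
            order = _MOLDEN_CART[sh.l]
            canon = cart_powers(sh.l)
            n = sh.n_cart
            for k, comp in enumerate(order):
                perm[pos + canon.index(comp)] = pos + k
        pos += n
    C = C_file[perm]

    return Wavefunction(
        numbers=numbers,
        coords=coords,
        basis=basis,
        mo_coeff=C,
        mo_occ=occs,
        mo_energy=enes,
        energy=None,
        n_electrons_declared=None,
        method="HF",
        source=str(path),
    )
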