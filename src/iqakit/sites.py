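"""MM site lists and topologies: xyzq / PQR / PDB / prmtop / toy formats.

Positions are Å on file and bohr internally; charges are electrons
(prmtop's ``q*18.2223`` storage is converted on load); Lennard-Jones
parameters are kept in the Amber convention (``eps`` kcal/mol,
``r_min/2`` Å) with sigma-form inputs converted on load.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .units import AMBER_CHARGE_FACTOR, ANGSTROM_TO_BOHR

__all__ = ["SiteSet", "MMTopology", "load_sites", "load_topology"]

QM, MM, LINK = "QM", "MM", "LINK"


class TopologyError(ValueError):
    pass


@dataclass
class SiteSet:
    """Point sites with charges, LJ parameters, PB radii and region tags."""

    elements: list[str]
    coords: np.ndarray                     # (n, 3) bohr
    charges: np.ndarray | None = None      # e
    lj_eps: np.ndarray | None = None       # kcal/mol
    lj_rmin2: np.ndarray | None = None     # r_min/2, A
    pb_radii: np.ndarray | None = None     # A
    region: np.ndarray | None = None       # "QM" | "MM" | "LINK"

    def __post_init__(self):
        n = len(self.elements)
        self.coords = np.atleast_2d(np.asarray(self.coords, float))
        if self.coords.shape != (n, 3):
            raise ValueError("coords shape mismatch")
        for name in ("charges", "lj_eps", "lj_rmin2", "pb_radii"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, float))
        if self.region is None:
            self.region = np.array([MM] * n, dtype=object)
        else:
            self.region = np.asarray(self.region, dtype=object)
        self.validate()

    def validate(self):
        if self.lj_eps is not None and np.any(self.lj_eps[np.isfinite(self.lj_eps)] < 0):
            raise ValueError("LJ epsilon must be >= 0")
        bad = set(self.region) - {QM, MM, LINK}
        if bad:
            raise ValueError(f"unknown region tags: {bad}")

    # ------------------------------------------------------------------
    def __len__(self):
        return len(self.elements)

    @property
    def n_sites(self):
        return len(self.elements)

    def require_charges(self):
        if self.charges is None or np.any(~np.isfinite(self.charges)):
            raise ValueError("operation requires partial charges on all sites")
        return self.charges

    def require_lj(self):
        if (
            self.lj_eps is None
            or self.lj_rmin2 is None
            or np.any(~np.isfinite(self.lj_eps))
            or np.any(~np.isfinite(self.lj_rmin2))
        ):
            missing = []
            if self.lj_eps is None or self.lj_rmin2 is None:
                missing = list(range(len(self)))
            else:
                missing = list(
                    np.where(~np.isfinite(self.lj_eps) | ~np.isfinite(self.lj_rmin2))[0]
                )
            raise ValueError(f"LJ parameters missing for sites {missing}")

    def require_radii(self):
        if self.pb_radii is None or np.any(
            ~np.isfinite(self.pb_radii) | (self.pb_radii <= 0)
        ):
            raise ValueError("positive PB radii required on all sites")
        return self.pb_radii

    def select(self, mask) -> "SiteSet":
        idx = np.where(mask)[0] if np.asarray(mask).dtype == bool else np.asarray(mask)
        take = lambda v: None if v is None else v[idx]
        return SiteSet(
            [self.elements[i] for i in idx],
            self.coords[idx],
            take(self.charges),
            take(self.lj_eps),
            take(self.lj_rmin2),
            take(self.pb_radii),
            self.region[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": self.elements,
                "x_bohr": self.coords[:, 0],
                "y_bohr": self.coords[:, 1],
                "z_bohr": self.coords[:, 2],
                "charge": self.charges if self.charges is not None else np.nan,
                "lj_eps": self.lj_eps if self.lj_eps is not None else np.nan,
                "lj_rmin2": self.lj_rmin2 if self.lj_rmin2 is not None else np.nan,
                "pb_radius": self.pb_radii if self.pb_radii is not None else np.nan,
                "region": self.region,
            }
        )


@dataclass
class MMTopology:
    """Bonded records and nonbonded bookkeeping of an MM region."""

    n_atoms: int
    bonds: list = field(default_factory=list)      # (i, j, k_b, r0_A)
    angles: list = field(default_factory=list)     # (i, j, k, k_th, th0_rad)
    dihedrals: list = field(default_factory=list)  # (i, j, k, l, k_n, n, gamma_rad)
    exclusions: set = field(default_factory=set)   # frozenset({i, j})
    pairs14: set = field(default_factory=set)      # frozenset({i, j})
    scee: float = 1.2
    scnb: float = 2.0

    def validate(self):
        def chk(idx):
            if not 0 <= idx < self.n_atoms:
                raise TopologyError(f"atom index {idx} out of range")

        for b in self.bonds:
            chk(b[0]), chk(b[1])
        for a in self.angles:
            chk(a[0]), chk(a[1]), chk(a[2])
        for d in self.dihedrals:
            for i in d[:4]:
                chk(i)
            if d[5] < 1:
                raise TopologyError("dihedral periodicity must be >= 1")
        for pair in self.exclusions | self.pairs14:
            for i in pair:
                chk(i)

    def bonded_neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b, *_ in self.bonds:
            if a == i:
                out.add(b)
            if b == i:
                out.add(a)
        return out


# ----------------------------------------------------------------------
# site-list loaders
# ----------------------------------------------------------------------

def load_sites(path, format: str | None = None) -> SiteSet:
    """Load sites from xyzq, PQR or PDB.  Positions converted to bohr."""
    path = Path(path)
    if format is None:
        format = {".xyzq": "xyzq", ".pqr": "pqr", ".pdb": "pdb"}.get(
            path.suffix.lower(), "xyzq"
        )
    text = path.read_text().splitlines()
    if format == "xyzq":
        return _parse_xyzq(text, path)
    if format == "pqr":
        return _parse_pqr(text, path)
    if format == "pdb":
        return _parse_pdb(text, path)
    raise ValueError(f"unsupported site format {format!r}")


def _parse_xyzq(lines, path):
    """``element x y z q [eps rmin2 [radius]]`` per line, Å / e / kcal/mol."""
    el, xyz, q, eps, rmin2, rad = [], [], [], [], [], []
    for ln_no, ln in enumerate(lines, 1):
        s = ln.split("#")[0].strip()
        if not s:
            continue
        parts = s.split()
        # skip xyz-style header lines (atom count / comment)
        if len(parts) == 1 and parts[0].isdigit():
            continue
        try:
            el.append(parts[0])
            xyz.append([float(x) for x in parts[1:4]])
            q.append(float(parts[4]) if len(parts) > 4 else np.nan)
            eps.append(float(parts[5]) if len(parts) > 6 else np.nan)
            rmin2.append(float(parts[6]) if len(parts) > 6 else np.nan)
            rad.append(float(parts[7]) if len(parts) > 7 else np.nan)
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln_no}: non-numeric field in {ln!r}") from exc
    return SiteSet(
        el, np.array(xyz) * ANGSTROM_TO_BOHR, np.array(q),
        np.array(eps), np.array(rmin2), np.array(rad) if np.any(np.isfinite(rad)) else None,
    )


def _parse_pqr(lines, path):
    el, xyz, q, rad = [], [], [], []
    for ln_no, ln in enumerate(lines, 1):
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        parts = ln.split()
        try:
            name = parts[2]
            xyz.append([float(x) for x in parts[-5:-2]])
            q.append(float(parts[-2]))
            rad.append(float(parts[-1]))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln_no}: malformed PQR line {ln!r}") from exc
        el.append("".join(c for c in name if c.isalpha())[:2].capitalize()
                  if name[:1].isalpha() else name)
    return SiteSet(el, np.array(xyz) * ANGSTROM_TO_BOHR, np.array(q),
                   None, None, np.array(rad))


def _parse_pdb(lines, path):
    el, xyz = [], []
    for ln_no, ln in enumerate(lines, 1):
        if not ln.startswith(("ATOM", "HETATM")):
            continue
        try:
            x = float(ln[30:38])
            y = float(ln[38:46])
            z = float(ln[46:54])
        except ValueError as exc:
            raise ValueError(f"{path}:{ln_no}: malformed PDB coordinates") from exc
        elem = ln[76:78].strip() or ln[12:16].strip()[:1]
        el.append(elem.capitalize())
        xyz.append([x, y, z])
    return SiteSet(el, np.array(xyz) * ANGSTROM_TO_BOHR)


# ----------------------------------------------------------------------
# topology loaders
# ----------------------------------------------------------------------

def load_topology(path, dialect: str | None = None):
    """Load an MM topology (+ sites where the format carries them).

    Returns ``(MMTopology, SiteSet | None)``.  ``dialect`` is "prmtop" or
    "toy"; inferred from the suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        if path.suffix.lower() in (".prmtop", ".parm7"):
            dialect = "prmtop"
        else:
            # sniff: Amber prmtop files carry %FLAG records
            head = path.read_text()[:4096]
            dialect = "prmtop" if "%FLAG" in head else "toy"
    if dialect == "prmtop":
        return _parse_prmtop(path)
    if dialect == "toy":
        return _parse_toy(path)
    raise ValueError(f"unsupported topology dialect {dialect!r}")


def _parse_toy(path):
    """Simple declarative topology; 1-based indices.

    Keywords: natoms, bond, angle, dihedral, exclude, pair14, scee, scnb.
    Angles/phases in degrees on file.
    """
    top = MMTopology(n_atoms=0)
    for ln_no, ln in enumerate(Path(path).read_text().splitlines(), 1):
        s = ln.split("#")[0].strip()
        if not s:
            continue
        key, *rest = s.split()
        try:
            if key == "natoms":
                top.n_atoms = int(rest[0])
            elif key == "bond":
                i, j = int(rest[0]) - 1, int(rest[1]) - 1
                top.bonds.append((i, j, float(rest[2]), float(rest[3])))
            elif key == "angle":
                i, j, k = (int(x) - 1 for x in rest[:3])
                top.angles.append((i, j, k, float(rest[3]), np.radians(float(rest[4]))))
            elif key == "dihedral":
                i, j, k, l = (int(x) - 1 for x in rest[:4])
                top.dihedrals.append(
                    (i, j, k, l, float(rest[4]), int(rest[5]), np.radians(float(rest[6])))
                )
            elif key == "exclude":
                top.exclusions.add(frozenset((int(rest[0]) - 1, int(rest[1]) - 1)))
            elif key == "pair14":
                top.pairs14.add(frozenset((int(rest[0]) - 1, int(rest[1]) - 1)))
            elif key == "scee":
                top.scee = float(rest[0])
            elif key == "scnb":
                top.scnb = float(rest[0])
            else:
                raise TopologyError(f"unknown keyword {key!r}")
        except (ValueError, IndexError) as exc:
            raise TopologyError(f"{path}:{ln_no}: malformed record {ln!r}") from exc
    if top.n_atoms == 0:
        idx = [0]
        for rec in top.bonds:
            idx += list(rec[:2])
        for rec in top.angles:
            idx += list(rec[:3])
        for rec in top.dihedrals:
            idx += list(rec[:4])
        top.n_atoms = max(idx) + 1
    top.validate()
    return top, None


def _prmtop_sections(path):
    secs = {}
    name = None
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("%FLAG"):
            name = ln.split()[1]
            secs[name] = []
        elif ln.startswith("%"):
            continue
        elif name is not None:
            secs[name].append(ln)
    return {k: " ".join(v).split() for k, v in secs.items()}


def _parse_prmtop(path):
    secs = _prmtop_sections(path)
    for required in ("POINTERS", "CHARGE"):
        if required not in secs:
            raise TopologyError(f"{path}: missing mandatory prmtop section {required}")
    ptr = [int(x) for x in secs["POINTERS"]]
    natom, ntypes = ptr[0], ptr[1]
    charges = np.array([float(x) for x in secs["CHARGE"]]) / AMBER_CHARGE_FACTOR
    if len(charges) != natom:
        raise TopologyError(f"{path}: CHARGE length != NATOM")
    znums = [int(x) for x in secs.get("ATOMIC_NUMBER", ["0"] * natom)]
    elements = []
    from .units import ELEMENTS

    for z in znums:
        elements.append(ELEMENTS[z] if 0 < z < len(ELEMENTS) else "X")

    # LJ from diagonal A/B coefficients
    eps = np.full(natom, np.nan)
    rmin2 = np.full(natom, np.nan)
    if "ATOM_TYPE_INDEX" in secs and "LENNARD_JONES_ACOEF" in secs:
        tidx = [int(x) - 1 for x in secs["ATOM_TYPE_INDEX"]]
        nbidx = [int(x) - 1 for x in secs["NONBONDED_PARM_INDEX"]]
        A = [float(x) for x in secs["LENNARD_JONES_ACOEF"]]
        B = [float(x) for x in secs["LENNARD_JONES_BCOEF"]]
        for i in range(natom):
            t = tidx[i]
            k = nbidx[ntypes * t + t]
            if k >= 0 and A[k] > 0 and B[k] > 0:
                rmin = (2.0 * A[k] / B[k]) ** (1.0 / 6.0)
                eps[i] = B[k] ** 2 / (4.0 * A[k])
                rmin2[i] = rmin / 2.0
            else:
                eps[i] = 0.0
                rmin2[i] = 0.0
    radii = None
    if "RADII" in secs:
        radii = np.array([float(x) for x in secs["RADII"]])

    top = MMTopology(n_atoms=natom)
    bk = [float(x) for x in secs.get("BOND_FORCE_CONSTANT", [])]
    br = [float(x) for x in secs.get("BOND_EQUIL_VALUE", [])]
    for sec in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
        vals = [int(x) for x in secs.get(sec, [])]
        for i0 in range(0, len(vals), 3):
            i, j, t = vals[i0] // 3, vals[i0 + 1] // 3, vals[i0 + 2] - 1
            top.bonds.append((i, j, bk[t], br[t]))
    ak = [float(x) for x in secs.get("ANGLE_FORCE_CONSTANT", [])]
    ar = [float(x) for x in secs.get("ANGLE_EQUIL_VALUE", [])]  # radians in prmtop
    for sec in ("ANGLES_INC_HYDROGEN", "ANGLES_WITHOUT_HYDROGEN"):
        vals = [int(x) for x in secs.get(sec, [])]
        for i0 in range(0, len(vals), 4):
            i, j, k, t = (
                vals[i0] // 3,
                vals[i0 + 1] // 3,
                vals[i0 + 2] // 3,
                vals[i0 + 3] - 1,
            )
            top.angles.append((i, j, k, ak[t], ar[t]))
    dk = [float(x) for x in secs.get("DIHEDRAL_FORCE_CONSTANT", [])]
    dn = [float(x) for x in secs.get("DIHEDRAL_PERIODICITY", [])]
    dp = [float(x) for x in secs.get("DIHEDRAL_PHASE", [])]  # radians
    for sec in ("DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN"):
        vals = [int(x) for x in secs.get(sec, [])]
        for i0 in range(0, len(vals), 5):
            i, j, k, l, t = vals[i0 : i0 + 5]
            keep14 = k >= 0
            i, j, k, l = i // 3, j // 3, abs(k) // 3, abs(l) // 3
            t -= 1
            top.dihedrals.append((i, j, k, l, dk[t], max(1, int(round(dn[t]))), dp[t]))
            if keep14 and l >= 0:
                top.pairs14.add(frozenset((i, l)))
    if "NUMBER_EXCLUDED_ATOMS" in secs:
        counts = [int(x) for x in secs["NUMBER_EXCLUDED_ATOMS"]]
        excl = [int(x) for x in secs.get("EXCLUDED_ATOMS_LIST", [])]
        pos = 0
        for i, c in enumerate(counts):
            for j in excl[pos : pos + c]:
                if j > 0:
                    top.exclusions.add(frozenset((i, j - 1)))
            pos += c
    else:
        for i, j, *_ in top.bonds:
            top.exclusions.add(frozenset((i, j)))
        for i, j, k, *_ in top.angles:
            top.exclusions.add(frozenset((i, k)))
    if "SCEE_SCALE_FACTOR" in secs and secs["SCEE_SCALE_FACTOR"]:
        top.scee = float(secs["SCEE_SCALE_FACTOR"][0])
    if "SCNB_SCALE_FACTOR" in secs and secs["SCNB_SCALE_FACTOR"]:
        top.scnb = float(secs["SCNB_SCALE_FACTOR"][0])
    top.validate()

    coords = np.zeros((natom, 3))  # prmtop carries no coordinates
    sites = SiteSet(elements, coords, charges, eps, rmin2, radii)
    return top, sites
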