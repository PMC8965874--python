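"""Packaged and synthetic test systems with known reference values.

Three families:

* packaged small wavefunctions (H2, He, HeH+, H2O at HF/STO-3G; H2O at
  B3LYP in STO-3G and in a triple-zeta set; an embedded H2O; a methyl
  fragment with an H-link) generated once by the documented script
  ``scripts/make_fixtures.py`` and shipped with JSON manifests holding
  their oracle values;
* analytic spherical-Gaussian model systems with closed-form populations
  and inter-cloud Coulomb energies;
* geometry generators: hydrated-metal clusters with shell structure and a
  toy host-guest complex for end-to-end scoring runs.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import erf

from .basis import GaussianBasis, Shell
from .sites import MM, QM, MMTopology, SiteSet
from .units import ANGSTROM_TO_BOHR
from .wavefunction import Wavefunction

__all__ = [
    "fixture_path", "manifest", "load_fixture",
    "AnalyticModelSystem", "make_analytic_system",
    "ClusterSpec", "make_metal_cluster", "ToyComplex", "make_toy_complex",
    "tip3p_geometry", "TIP3P_Q_O", "TIP3P_Q_H",
]

TIP3P_Q_O = -0.834
TIP3P_Q_H = 0.417
TIP3P_OH = 0.9572          # A
TIP3P_HOH = 104.52         # degrees


def tip3p_geometry(center=(0.0, 0.0, 0.0), rotation=None) -> np.ndarray:
    """Rigid three-site water geometry in bohr (O first)."""
    r = TIP3P_OH * ANGSTROM_TO_BOHR
    th = math.radians(TIP3P_HOH / 2.0)
    geom = np.array(
        [
            [0.0, 0.0, 0.0],
            [r * math.sin(th), 0.0, r * math.cos(th)],
            [-r * math.sin(th), 0.0, r * math.cos(th)],
        ]
    )
    if rotation is not None:
        geom = geom @ np.asarray(rotation).T
    return geom + np.asarray(center, dtype=float)


# ----------------------------------------------------------------------
# packaged fixtures
# ----------------------------------------------------------------------

def fixture_path(filename: str):
    """Path-like handle to a packaged data file."""
    return resources.files("iqakit.data").joinpath(filename)


def manifest() -> dict:
    with fixture_path("manifest.json").open() as fh:
        return json.load(fh)


def load_fixture(name: str, ext: str | None = None) -> Wavefunction:
    """Load a packaged wavefunction fixture with its manifest attached."""
    from .formats import load_wavefunction

    man = manifest()[name]
    if ext is None:
        ext = ".wfx" if fixture_path(name + ".wfx").is_file() else ".molden"
    with resources.as_file(fixture_path(name + ext)) as p:
        wfn = load_wavefunction(p)
    wfn.method = man["method"]
    wfn.functional = man.get("functional")
    if wfn.energy is None:
        wfn.energy = man["scf_energy"]
    wfn.meta["manifest"] = man
    return wfn


# ----------------------------------------------------------------------
# analytic spherical-Gaussian models
# ----------------------------------------------------------------------

@dataclass
class AnalyticModelSystem:
    """Spherical-Gaussian 'atoms' with closed-form reference values."""

    centers: np.ndarray        # (n, 3) bohr
    exponents: np.ndarray      # (n,)
    weights: np.ndarray        # (n,) electron counts per cloud
    charges: np.ndarray        # (n,) nuclear charges
    seed: int
    wavefunction: Wavefunction = None
    expected: dict = field(default_factory=dict)


def gaussian_cloud_coulomb(alpha1: float, alpha2: float, R: float) -> float:
    """Coulomb energy of two unit spherical-Gaussian charge clouds.

    E = erf(sqrt(mu) R) / R with 1/mu = 1/(2 alpha1) + 1/(2 alpha2)
    (each cloud's charge density is the square of a normalized s
    Gaussian, i.e. a Gaussian with exponent 2 alpha).
    """
    if R < 1e-12:
        mu = 1.0 / (0.5 / alpha1 + 0.5 / alpha2)
        return 2.0 * np.sqrt(mu / np.pi)
    mu = 1.0 / (0.5 / alpha1 + 0.5 / alpha2)
    return float(erf(np.sqrt(mu) * R) / R)


def make_analytic_system(
    centers,
    exponents,
    weights=None,
    charges=None,
    seed: int = 0,
    jitter: float = 0.0,
) -> AnalyticModelSystem:
    """Build an s-Gaussian pseudo-wavefunction plus closed-form references.

    Each cloud is one occupied MO (normalized s Gaussian).  MOs on
    well-separated centers are near-orthogonal; closed-form populations
    are the cloud weights and pair Coulomb energies follow the
    error-function formula.
    """
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, float)).copy()
    if jitter > 0:
        centers += rng.normal(scale=jitter, size=centers.shape)
    exponents = np.asarray(exponents, float)
    if np.any(exponents <= 0):
        raise ValueError("exponents must be positive")
    n = len(centers)
    weights = (
        np.ones(n) if weights is None else np.asarray(weights, float)
    )
    charges = (
        weights.copy() if charges is None else np.asarray(charges, float)
    )
    shells = [
        Shell(i, 0, centers[i], [exponents[i]], [1.0]) for i in range(n)
    ]
    basis = GaussianBasis(shells)
    wfn = Wavefunction(
        numbers=charges,
        coords=centers,
        basis=basis,
        mo_coeff=np.eye(n),
        mo_occ=weights,
        energy=None,
        method="HF",
        source="analytic-model",
    )
    expected = {"populations": weights.copy(), "pair_coulomb": {}}
    for i in range(n):
        for j in range(i + 1, n):
            R = float(np.linalg.norm(centers[i] - centers[j]))
            expected["pair_coulomb"][(i, j)] = (
                weights[i]
                * weights[j]
                * gaussian_cloud_coulomb(exponents[i], exponents[j], R)
            )
    return AnalyticModelSystem(
        centers=centers, exponents=exponents, weights=weights,
        charges=charges, seed=seed, wavefunction=wfn, expected=expected,
    )


# ----------------------------------------------------------------------
# hydrated-metal clusters
# ----------------------------------------------------------------------

@dataclass
class ClusterSpec:
    """Shell-structured hydrated-ion cluster."""

    metal: str = "Zn"
    metal_charge: float = 2.0
    shell_counts: tuple = (6, 12, 24, 48, 96)
    shell_radii: tuple = (2.1, 4.5, 6.9, 9.3, 11.8)   # A (metal-O)
    n_qm_shells: int = 1
    min_oo: float = 2.3                                 # A
    seed: int = 0


def _fibonacci_dirs(n, rng):
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i + rng.uniform(0, 2 * np.pi)
    z = 1.0 - 2.0 * i / n
    s = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def make_metal_cluster(spec: ClusterSpec | None = None) -> SiteSet:
    """Metal ion + shell-structured rigid waters, tagged QM/MM.

    The first shell is octahedral; outer shells use deterministic
    quasi-uniform directions with a minimum O-O distance check.  MM
    waters carry TIP3P charges; the region tag of each water follows its
    shell.  Cumulative QM water counts for the full shell series are
    6, 18, 42, 90, 186.
    """
    if spec is None:
        spec = ClusterSpec()
    if any(c <= 0 for c in spec.shell_counts):
        raise ValueError("shell counts must be positive")
    rng = np.random.default_rng(spec.seed)
    elements = [spec.metal]
    coords = [np.zeros(3)]
    charges = [spec.metal_charge]
    region = [QM if spec.n_qm_shells > 0 else MM]
    oxy_positions = []
    octa = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    for ishell, (count, radius) in enumerate(
        zip(spec.shell_counts, spec.shell_radii)
    ):
        if ishell == 0:
            if count != 6:
                raise ValueError("the first hydration shell is octahedral (6)")
            dirs = octa
        else:
            dirs = _fibonacci_dirs(count, rng)
        tag = QM if ishell < spec.n_qm_shells else MM
        for d in dirs:
            opos = radius * d
            if oxy_positions:
                dmin = np.min(
                    np.linalg.norm(np.array(oxy_positions) - opos, axis=1)
                )
                if dmin < spec.min_oo:
                    raise ValueError(
                        f"infeasible packing in shell {ishell}: O-O "
                        f"{dmin:.2f} A < {spec.min_oo} A"
                    )
            oxy_positions.append(opos)
            # rigid water, oxygen toward the metal, random azimuthal spin
            zax = d
            ref = np.array([0.0, 0.0, 1.0])
            if abs(np.dot(zax, ref)) > 0.9:
                ref = np.array([1.0, 0.0, 0.0])
            xax = np.cross(zax, ref)
            xax /= np.linalg.norm(xax)
            yax = np.cross(zax, xax)
            spin = rng.uniform(0, 2 * np.pi)
            rot = np.column_stack(
                [np.cos(spin) * xax + np.sin(spin) * yax,
                 -np.sin(spin) * xax + np.cos(spin) * yax,
                 zax]
            )
            geom = tip3p_geometry(rotation=rot) / 1.0
            geom = geom + opos[None, :] * ANGSTROM_TO_BOHR
            for k, el in enumerate(("O", "H", "H")):
                elements.append(el)
                coords.append(geom[k])
                charges.append(TIP3P_Q_O if k == 0 else TIP3P_Q_H)
                region.append(tag)
    return SiteSet(
        elements, np.array(coords), np.array(charges), region=np.array(region, dtype=object)
    )


# ----------------------------------------------------------------------
# toy host-guest complex
# ----------------------------------------------------------------------

@dataclass
class ToyComplex:
    """QM water 'ligand' in an MM point-charge cage, plus the separated
    species at identical geometries for scoring."""

    ligand_wfn: Wavefunction          # embedded (polarized) wavefunction
    ligand_wfn_isolated: Wavefunction
    cage: SiteSet
    topology: MMTopology
    fragment_labels: list
    cage_scale: float = 1.0


def make_toy_complex(seed: int = 0, cage_scale: float = 1.0) -> ToyComplex:
    """Assemble the packaged embedded-water toy complex.

    ``cage_scale`` radially scales the MM cage positions (used by decay
    tests); the packaged embedded wavefunction corresponds to scale 1.
    """
    wfn_emb = load_fixture("h2o_embedded_sto3g")
    wfn_iso = load_fixture("h2o_hf_sto3g")
    man = wfn_emb.meta["manifest"]
    mm_xyz = np.array(man["point_charge_coords_bohr"]) * cage_scale
    mm_q = np.array(man["point_charges"])
    elements = ["O", "H", "H", "O", "H", "H"]
    cage = SiteSet(
        elements, mm_xyz, mm_q,
        lj_eps=np.array([0.1520, 0.0, 0.0] * 2),
        lj_rmin2=np.array([1.7683, 0.6, 0.6] * 2),
        pb_radii=np.array([1.52, 1.2, 1.2] * 2),
    )
    # toy topology for the two MM waters within the combined ordering
    # (QM sites 0-2 first, then the cage)
    top = MMTopology(n_atoms=9)
    for o in (3, 6):
        top.bonds.append((o, o + 1, 450.0, TIP3P_OH))
        top.bonds.append((o, o + 2, 450.0, TIP3P_OH))
        top.angles.append((o + 1, o, o + 2, 55.0, math.radians(TIP3P_HOH)))
        top.exclusions |= {
            frozenset((o, o + 1)), frozenset((o, o + 2)),
            frozenset((o + 1, o + 2)),
        }
    top.validate()
    labels = ["guest"] * 3 + ["hostA"] * 3 + ["hostB"] * 3
    return ToyComplex(
        ligand_wfn=wfn_emb,
        ligand_wfn_isolated=wfn_iso,
        cage=cage,
        topology=top,
        fragment_labels=labels,
        cage_scale=cage_scale,
    )
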