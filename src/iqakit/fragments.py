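"""Fragment (IQF) regrouping, formation decomposition and binding scores.

Atomic IQA terms regroup exactly into fragment terms: a fragment's net
energy collects its atoms' net energies plus all intra-fragment pair
interactions, and fragment pairs collect the inter-fragment pair terms by
type (electrostatic, exchange-correlation, dispersion, QM-MM vdW).  Any
grouping conserves the total energy to machine precision.

Binding scores follow the QM/MM-PBSA recipe: for complex, receptor* and
ligand* (asterisk: geometries taken from the complex),

    G = E^QM/MM + G_solv (+ 3RT),   dG = G(cmplx) - G(rec*) - G(lig*).

The 3RT term (six translational/rotational degrees of freedom) is off by
default so that component sums reproduce tabulated scorings.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .iqa import IQATermMatrix, additive_energies, reconstruct_total
from .units import HARTREE_TO_KCAL, R_GAS_KCAL

__all__ = [
    "FragmentScheme", "FragmentMatrix", "ScoreSpec", "iqf_regroup",
    "formation_decomposition", "fragment_additive_energy", "qmmm_pbsa_score",
    "consistency_check", "DecompositionReport", "write_report",
]


@dataclass
class FragmentScheme:
    """Total, surjective map from atom index to fragment label."""

    labels: dict[int, str]

    @classmethod
    def from_list(cls, labels_list) -> "FragmentScheme":
        return cls({i: str(lbl) for i, lbl in enumerate(labels_list)})

    def validate(self, n_atoms: int):
        missing = [i for i in range(n_atoms) if i not in self.labels]
        if missing:
            raise ValueError(f"fragment scheme does not map atoms {missing}")

    def fragments(self) -> list[str]:
        seen = []
        for i in sorted(self.labels):
            if self.labels[i] not in seen:
                seen.append(self.labels[i])
        return seen

    def members(self, label: str) -> list[int]:
        return [i for i, l in sorted(self.labels.items()) if l == label]


@dataclass
class ScoreSpec:
    temperature: float = 300.0
    include_3rt: bool = False
    relative_mode: bool = True   # drop purely-MM terms

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def three_rt(self) -> float:
        return 3.0 * R_GAS_KCAL * self.temperature


@dataclass
class FragmentMatrix:
    """Fragment-level energies (hartree for QM terms, kcal/mol for G_solv)."""

    labels: list[str]
    e_net: dict            # label -> intra-fragment net + interactions
    pairs: dict            # (A, B) sorted tuple -> component dict
    g_solv: dict = field(default_factory=dict)
    populations: dict = field(default_factory=dict)

    def pair(self, a: str, b: str) -> dict:
        return self.pairs.get(tuple(sorted((a, b))), {})

    def total(self) -> float:
        tot = sum(self.e_net.values())
        for comps in self.pairs.values():
            tot += comps["e_int"]
        return tot


def iqf_regroup(
    terms: IQATermMatrix,
    scheme: FragmentScheme,
    populations: np.ndarray | None = None,
    mm_fragments: dict[int, str] | None = None,
) -> FragmentMatrix:
    """Regroup the atomic term matrix over fragments; totals conserved.

    ``scheme`` maps QM atom indices (wavefunction order); QM-MM pairwise
    terms are regrouped with ``mm_fragments`` mapping the columns of the
    QM-MM matrices to fragment labels.
    """
    n = terms.n_atoms
    scheme.validate(n)
    labels = scheme.fragments()
    e_net = {lbl: 0.0 for lbl in labels}
    pairs = {}
    e_int = terms.e_int
    e_ele = terms.e_ele
    e_xc = terms.e_xc
    disp = terms.disp if terms.disp is not None else np.zeros((n, n))
    for i in range(n):
        e_net[scheme.labels[i]] += terms.e_net[i]
    for i in range(n):
        for j in range(i + 1, n):
            a, b = scheme.labels[i], scheme.labels[j]
            if a == b:
                e_net[a] += e_int[i, j]
                continue
            key = tuple(sorted((a, b)))
            comps = pairs.setdefault(
                key,
                {"e_ele": 0.0, "e_xc": 0.0, "e_disp": 0.0, "e_vdw": 0.0,
                 "e_int": 0.0},
            )
            comps["e_ele"] += e_ele[i, j]
            comps["e_xc"] += e_xc[i, j]
            comps["e_disp"] += disp[i, j]
            comps["e_int"] += e_int[i, j]
    if terms.qmmm_ele is not None or terms.qmmm_vdw is not None:
        if mm_fragments is None:
            raise ValueError("QM-MM terms present but no MM fragment map given")
        ncol = (
            terms.qmmm_ele.shape[1]
            if terms.qmmm_ele is not None
            else terms.qmmm_vdw.shape[1]
        )
        for col in range(ncol):
            site = (
                int(terms.mm_site_index[col])
                if terms.mm_site_index is not None
                else col
            )
            b = mm_fragments[site]
            if b not in labels:
                labels.append(b)
                e_net.setdefault(b, 0.0)
            for i in range(n):
                a = scheme.labels[i]
                ele = terms.qmmm_ele[i, col] if terms.qmmm_ele is not None else 0.0
                vdw = terms.qmmm_vdw[i, col] if terms.qmmm_vdw is not None else 0.0
                if a == b:
                    e_net[a] += ele + vdw
                    continue
                key = tuple(sorted((a, b)))
                comps = pairs.setdefault(
                    key,
                    {"e_ele": 0.0, "e_xc": 0.0, "e_disp": 0.0, "e_vdw": 0.0,
                     "e_int": 0.0},
                )
                comps["e_ele"] += ele
                comps["e_vdw"] += vdw
                comps["e_int"] += ele + vdw
    pops = {}
    if populations is not None:
        for lbl in labels:
            pops[lbl] = float(
                sum(populations[i] for i in scheme.members(lbl))
            )
    return FragmentMatrix(labels=labels, e_net=e_net, pairs=pairs,
                          populations=pops)


def formation_decomposition(
    complex_matrix: FragmentMatrix,
    isolated_refs: dict[str, float],
    geometry_check: dict | None = None,
    tol_bohr: float = 1e-4,
) -> dict:
    """Rigid formation-energy decomposition A + B -> AB.

    dE_form = sum_A E_def^A + sum_{A<B} E_int^AB with
    E_def^A = E_net^A(in complex) - E^A(isolated).  ``geometry_check``
    optionally maps labels to (complex coords, isolated coords) pairs that
    must agree within ``tol_bohr`` (rigid assumption).
    """
    if geometry_check:
        for lbl, (rc, ri) in geometry_check.items():
            rc = np.atleast_2d(rc)
            ri = np.atleast_2d(ri)
            # allow a rigid-body shift: compare internal geometry
            dc = rc - rc.mean(axis=0)
            di = ri - ri.mean(axis=0)
            if np.max(np.linalg.norm(dc - di, axis=1)) > tol_bohr:
                raise ValueError(
                    f"fragment {lbl!r} geometry differs between complex and "
                    f"isolated reference (rigid decomposition violated)"
                )
    out = {"e_def": {}, "e_int_pairs": {}, "delta_e_form": 0.0}
    for lbl in complex_matrix.labels:
        if lbl not in isolated_refs:
            raise ValueError(f"no isolated reference energy for fragment {lbl!r}")
        e_def = complex_matrix.e_net[lbl] - isolated_refs[lbl]
        out["e_def"][lbl] = e_def
        out["delta_e_form"] += e_def
    for key, comps in complex_matrix.pairs.items():
        out["e_int_pairs"][key] = dict(comps)
        out["delta_e_form"] += comps["e_int"]
    return out


def fragment_additive_energy(delta_e_net, delta_g_solv, half_delta_e_int):
    """dG_add = dE_net + dG_solv + dE_int/2 (fragment-level, kcal/mol)."""
    return float(delta_e_net) + float(delta_g_solv) + float(half_delta_e_int)


def qmmm_pbsa_score(
    complex_components: dict,
    receptor_components: dict,
    ligand_components: dict,
    spec: ScoreSpec | None = None,
) -> dict:
    """Binding score dG = G(cmplx) - G(rec*) - G(lig*), kcal/mol.

    Each species dict carries any of the keys ``coulomb``, ``vdw``,
    ``solvation`` (kcal/mol); missing keys count as zero.  Components are
    differenced separately and their sum (plus the net -3RT when enabled)
    is the score.
    """
    if spec is None:
        spec = ScoreSpec()
    comps = {}
    for key in ("coulomb", "vdw", "solvation"):
        comps[key] = (
            complex_components.get(key, 0.0)
            - receptor_components.get(key, 0.0)
            - ligand_components.get(key, 0.0)
        )
    dg = sum(comps.values())
    if spec.include_3rt:
        # complex has 6 external degrees of freedom versus 12 for the
        # separated pair: net -3RT on binding
        comps["three_rt"] = -spec.three_rt
        dg -= spec.three_rt
    return {"dg": dg, "components": comps, "temperature": spec.temperature,
            "include_3rt": spec.include_3rt}


# ----------------------------------------------------------------------
# consistency diagnostics and reports
# ----------------------------------------------------------------------

def consistency_check(
    terms: IQATermMatrix | None = None,
    fragment_matrix: FragmentMatrix | None = None,
    solvation=None,
    tol: float = 1e-10,
) -> list[dict]:
    """Verify the bookkeeping identities; returns diagnostics, not errors."""
    diags = []

    def add(name, magnitude, threshold):
        diags.append(
            {"check": name, "magnitude": float(abs(magnitude)),
             "ok": bool(abs(magnitude) <= threshold), "tolerance": threshold}
        )

    if terms is not None:
        split = terms.e_int - (
            terms.e_ele + terms.e_xc
            + (terms.disp if terms.disp is not None else 0.0)
        )
        add("pairwise split E_int = E_ele + E_xc (+disp)", np.abs(split).max(), tol)
        add("pair matrices symmetric",
            np.abs(terms.e_int - terms.e_int.T).max(), tol)
        e_add, mm_share = additive_energies(terms, "half_share")
        total, _ = reconstruct_total(terms)
        add("sum of additive energies equals the total",
            e_add.sum() + mm_share - total, 1e-9 * max(1.0, abs(total)))
        if fragment_matrix is not None:
            add("fragment regrouping conserves the total",
                fragment_matrix.total() - total, 1e-9 * max(1.0, abs(total)))
    if solvation is not None:
        direct = (
            solvation.polar.sum()
            + solvation.cavity.sum()
            + solvation.disp_pair.sum()
        )
        add("per-atom G_solv sums to the total solvation energy",
            solvation.g_solv.sum() - direct, 1e-9 * max(1.0, abs(direct)))
    return diags


@dataclass
class DecompositionReport:
    """Atom- and fragment-level tables plus run metadata."""

    atomic: pd.DataFrame
    fragment: pd.DataFrame | None
    metadata: dict
    diagnostics: list = field(default_factory=list)

    @classmethod
    def build(cls, terms: IQATermMatrix, scheme: FragmentScheme | None = None,
              solvation=None, populations=None, convention="half_share",
              mm_fragments=None):
        n = terms.n_atoms
        e_add, mm_share = additive_energies(terms, convention)
        total, residual = reconstruct_total(terms)
        atomic = pd.DataFrame(
            {
                "atom": np.arange(n),
                "e_net_hartree": terms.e_net,
                "e_add_hartree": e_add,
                "e_add_kcal": e_add * HARTREE_TO_KCAL,
            }
        )
        if populations is not None:
            atomic["population"] = populations
        if solvation is not None and len(solvation.g_solv) >= n:
            atomic["g_solv_kcal"] = solvation.g_solv[:n]
        frag_df = None
        fm = None
        if scheme is not None:
            fm = iqf_regroup(terms, scheme, populations=populations,
                             mm_fragments=mm_fragments)
            rows = []
            for lbl in fm.labels:
                half_int = 0.5 * sum(
                    comps["e_int"]
                    for key, comps in fm.pairs.items()
                    if lbl in key
                )
                rows.append(
                    {
                        "fragment": lbl,
                        "e_net_kcal": fm.e_net.get(lbl, 0.0) * HARTREE_TO_KCAL,
                        "half_e_int_kcal": half_int * HARTREE_TO_KCAL,
                        "population": fm.populations.get(lbl, np.nan),
                    }
                )
            frag_df = pd.DataFrame(rows)
        meta = {
            "convention": convention,
            "xc_scale": terms.xc_scale,
            "reconstructed_total_hartree": total,
            "residual_hartree": residual,
            "mm_half_share_hartree": mm_share,
            **terms.meta,
        }
        if solvation is not None:
            meta["solvation"] = solvation.parameters
        diags = consistency_check(terms, fm, solvation)
        return cls(atomic=atomic, fragment=frag_df, metadata=meta,
                   diagnostics=diags)

    def violations(self, tol_scale: float = 1.0) -> list[dict]:
        return [d for d in self.diagnostics if not d["ok"]]


def write_report(report: DecompositionReport, path, format: str = "tsv"):
    """Write the report tables + metadata; returns the files written."""
    path = Path(path)
    written = []
    if format == "tsv":
        f = path.with_suffix(".atoms.tsv")
        report.atomic.to_csv(f, sep="\t", index=False)
        written.append(f)
        if report.fragment is not None:
            f = path.with_suffix(".fragments.tsv")
            report.fragment.to_csv(f, sep="\t", index=False)
            written.append(f)
        f = path.with_suffix(".meta.json")
        f.write_text(json.dumps(
            {"metadata": report.metadata, "diagnostics": report.diagnostics},
            indent=1, default=float))
        written.append(f)
    elif format == "json":
        f = path.with_suffix(".json")
        payload = {
            "atomic": report.atomic.to_dict(orient="list"),
            "fragment": (
                report.fragment.to_dict(orient="list")
                if report.fragment is not None
                else None
            ),
            "metadata": report.metadata,
            "diagnostics": report.diagnostics,
        }
        f.write_text(json.dumps(payload, indent=1, default=float))
        written.append(f)
    else:
        raise ValueError(f"unsupported report format {format!r}")
    return written
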