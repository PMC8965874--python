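"""The composite QM/MM system model."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .sites import LINK, MM, QM, MMTopology, SiteSet
from .wavefunction import Wavefunction

__all__ = ["SystemModel", "LinkRecord", "assemble_system"]


class AssemblyError(ValueError):
    pass


@dataclass
class LinkRecord:
    """A hydrogen link atom capping a covalent QM-MM cut."""

    qm_host: int   # site index of the QM boundary atom
    mm_host: int   # site index of the MM boundary atom
    link_site: int  # site index of the capping H (region tag LINK)


@dataclass
class SystemModel:
    """QM wavefunction + site list + MM topology + link map + fragments.

    The single object pipelines operate on.  All positions bohr, energies
    hartree; conversion constants live in :mod:`iqakit.units` and are
    applied once, at the report layer.
    """

    sites: SiteSet
    wavefunction: Wavefunction | None = None
    topology: MMTopology | None = None
    links: list[LinkRecord] = field(default_factory=list)
    fragments: dict[int, str] | None = None  # site index -> fragment label

    hartree_to_kcal: float = units.HARTREE_TO_KCAL
    bohr_to_angstrom: float = units.BOHR_TO_ANGSTROM
    coulomb_kcal: float = units.COULOMB_KCAL

    # ------------------------------------------------------------------
    @property
    def qm_indices(self) -> np.ndarray:
        return np.where((self.sites.region == QM) | (self.sites.region == LINK))[0]

    @property
    def mm_indices(self) -> np.ndarray:
        return np.where(self.sites.region == MM)[0]

    @property
    def n_qm(self) -> int:
        return len(self.qm_indices)

    def qm_site_of_nucleus(self, i_nuc: int) -> int:
        """Site index corresponding to nucleus i of the wavefunction."""
        return int(self.qm_indices[i_nuc])

    def validate(self) -> None:
        wfn = self.wavefunction
        if wfn is not None:
            qm = self.qm_indices
            if wfn.n_atoms != len(qm):
                raise AssemblyError(
                    f"wavefunction has {wfn.n_atoms} nuclei but "
                    f"{len(qm)} QM/LINK sites are tagged"
                )
            d = np.linalg.norm(wfn.coords - self.sites.coords[qm], axis=1)
            bad = np.where(d > 1e-4)[0]
            if len(bad):
                detail = ", ".join(
                    f"nucleus {i} vs site {qm[i]} ({d[i]:.2e} bohr)" for i in bad
                )
                raise AssemblyError(f"QM nucleus/site position mismatch: {detail}")
        site_regions = self.sites.region
        link_sites = set(np.where(site_regions == LINK)[0])
        rec_sites = {l.link_site for l in self.links}
        if link_sites != rec_sites:
            raise AssemblyError(
                f"LINK-tagged sites {sorted(link_sites)} do not match link "
                f"records {sorted(rec_sites)}"
            )
        for l in self.links:
            if site_regions[l.qm_host] != QM:
                raise AssemblyError(f"link QM host {l.qm_host} is not QM-tagged")
            if site_regions[l.mm_host] != MM:
                raise AssemblyError(f"link MM host {l.mm_host} is not MM-tagged")
        if self.fragments is not None:
            missing = [i for i in range(len(self.sites)) if i not in self.fragments]
            if missing:
                raise AssemblyError(f"fragment map does not cover sites {missing}")


def assemble_system(
    wfn: Wavefunction | None,
    qm_sites: SiteSet | None,
    mm_sites: SiteSet | None = None,
    topology: MMTopology | None = None,
    link_spec: list[tuple[int, int, int]] | None = None,
    fragments: dict[int, str] | None = None,
) -> SystemModel:
    """Combine QM sites, MM sites and topology into a SystemModel.

    ``link_spec`` entries are (qm_host, mm_host, link_site) site indices in
    the combined ordering (QM sites first, then MM sites).  Topology atom
    indices must already refer to the combined ordering.
    """
    pieces = []
    if qm_sites is not None:
        qs = qm_sites
        region = np.array(
            [r if r == LINK else QM for r in qs.region], dtype=object
        )
        qs = SiteSet(qs.elements, qs.coords, qs.charges, qs.lj_eps,
                     qs.lj_rmin2, qs.pb_radii, region)
        pieces.append(qs)
    if mm_sites is not None:
        ms = mm_sites
        region = np.array([MM] * len(ms), dtype=object)
        ms = SiteSet(ms.elements, ms.coords, ms.charges, ms.lj_eps,
                     ms.lj_rmin2, ms.pb_radii, region)
        pieces.append(ms)
    if not pieces:
        raise AssemblyError("no sites given")
    combined = pieces[0]
    for extra in pieces[1:]:
        combined = _concat_sites(combined, extra)

    links = [LinkRecord(*spec) for spec in (link_spec or [])]
    for l in links:
        combined.region[l.link_site] = LINK

    model = SystemModel(
        sites=combined,
        wavefunction=wfn,
        topology=topology,
        links=links,
        fragments=fragments,
    )
    model.validate()
    return model


def _concat_sites(a: SiteSet, b: SiteSet) -> SiteSet:
    def cat(x, y, n_a, n_b):
        if x is None and y is None:
            return None
        if x is None:
            x = np.full(n_a, np.nan)
        if y is None:
            y = np.full(n_b, np.nan)
        return np.concatenate([x, y])

    return SiteSet(
        list(a.elements) + list(b.elements),
        np.vstack([a.coords, b.coords]),
        cat(a.charges, b.charges, len(a), len(b)),
        cat(a.lj_eps, b.lj_eps, len(a), len(b)),
        cat(a.lj_rmin2, b.lj_rmin2, len(a), len(b)),
        cat(a.pb_radii, b.pb_radii, len(a), len(b)),
        np.concatenate([a.region, b.region]),
    )
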