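"""Molecular wavefunctions and density-derived fields.

A :class:`Wavefunction` couples a Gaussian AO basis with an MO coefficient
matrix and occupations.  It is the source of every field the rest of the
package integrates: the electron density rho(r) and its derivatives, the
first-order reduced density matrix rho1(r1, r2) of a single-determinant
state, and the positive-definite kinetic-energy density.

Only closed-shell (RHF/RKS-like) determinants are supported: occupations
are spin-summed and the exchange(-correlation) pair density is built from
rho1 with the closed-shell prescription rho_xc = -1/2 rho1^2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .basis import GaussianBasis

__all__ = [
    "Wavefunction",
    "evaluate_density",
    "evaluate_rdm1",
    "evaluate_ked",
]


class WavefunctionError(ValueError):
    pass


@dataclass
class Wavefunction:
    numbers: np.ndarray          # (nat,) nuclear charges Z_I
    coords: np.ndarray           # (nat, 3) bohr
    basis: GaussianBasis
    mo_coeff: np.ndarray         # (n_ao, nmo)
    mo_occ: np.ndarray           # (nmo,)
    energy: float | None = None  # total SCF energy, hartree
    method: str = "HF"           # "HF" or "DFT"
    functional: str | None = None
    mo_energy: np.ndarray | None = None
    n_electrons_declared: float | None = None
    source: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.numbers = np.asarray(self.numbers, dtype=float)
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        self.mo_coeff = np.asarray(self.mo_coeff, dtype=float)
        self.mo_occ = np.asarray(self.mo_occ, dtype=float)

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.numbers)

    @property
    def n_electrons(self) -> float:
        return float(self.mo_occ.sum())

    @property
    def is_closed_shell(self) -> bool:
        occ = self.mo_occ[self.mo_occ > 1e-12]
        return bool(np.all(np.abs(occ - 2.0) < 1e-8))

    def occupied(self) -> tuple[np.ndarray, np.ndarray]:
        """(coefficients, occupations) restricted to occupied MOs."""
        mask = self.mo_occ > 1e-12
        return self.mo_coeff[:, mask], self.mo_occ[mask]

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += self.numbers[i] * self.numbers[j] / np.linalg.norm(
                    self.coords[i] - self.coords[j]
                )
        return e

    def nuclear_dipole(self) -> np.ndarray:
        return self.numbers @ self.coords

    # ------------------------------------------------------------------
    def validate(self, tol_orth: float = 1e-6, tol_electrons: float = 1e-6) -> None:
        """Check declared electron count, MO orthonormality and shell centers.

        Raises :class:`WavefunctionError` on violation.
        """
        if self.n_electrons_declared is not None:
            if abs(self.n_electrons - self.n_electrons_declared) > tol_electrons:
                raise WavefunctionError(
                    f"occupations sum to {self.n_electrons:.6f} but the file "
                    f"declares {self.n_electrons_declared:g} electrons"
                )
        for sh in self.basis.shells:
            if not 0 <= sh.atom < self.n_atoms:
                raise WavefunctionError(
                    f"shell references center {sh.atom}, but only "
                    f"{self.n_atoms} nuclei are present"
                )
        S = self.basis.overlap()
        C, occ = self.occupied()
        ortho = C.T @ S @ C
        err = np.max(np.abs(ortho - np.eye(len(occ))))
        if err > tol_orth:
            raise WavefunctionError(
                f"occupied MOs are not orthonormal in the declared basis "
                f"(max deviation {err:.2e})"
            )

    # ------------------------------------------------------------------
    def mo_values(self, points: np.ndarray, deriv: int = 0):
        """Occupied-MO values (nocc, N) and optionally gradients (3, nocc, N)."""
        C, _ = self.occupied()
        out = self.basis.eval_ao(points, deriv=deriv)
        if deriv == 0:
            return C.T @ out
        if deriv == 1:
            vals, grad = out
            return C.T @ vals, np.einsum("um,aun->amn", C, grad)
        vals, grad, hess = out
        return (
            C.T @ vals,
            np.einsum("um,aun->amn", C, grad),
            np.einsum("um,abun->abmn", C, hess),
        )

    def density(self, points: np.ndarray, deriv: int = 0):
        """rho (N,), optionally with gradient (N, 3) and hessian (N, 3, 3)."""
        _, occ = self.occupied()
        if deriv == 0:
            phi = self.mo_values(points)
            return occ @ (phi * phi)
        if deriv == 1:
            phi, dphi = self.mo_values(points, deriv=1)
            rho = occ @ (phi * phi)
            grad = 2.0 * np.einsum("m,mn,amn->na", occ, phi, dphi)
            return rho, grad
        phi, dphi, hphi = self.mo_values(points, deriv=2)
        rho = occ @ (phi * phi)
        grad = 2.0 * np.einsum("m,mn,amn->na", occ, phi, dphi)
        hess = 2.0 * np.einsum("m,amn,bmn->nab", occ, dphi, dphi)
        hess += 2.0 * np.einsum("m,mn,abmn->nab", occ, phi, hphi)
        return rho, grad, hess

    def rdm1(self, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        """Spin-summed rho1(r1, r2) for batches of points (N, 3) x (N, 3)."""
        if not self.is_closed_shell:
            raise WavefunctionError(
                "rho1 is only defined here for closed-shell determinants"
            )
        phi1 = self.mo_values(np.atleast_2d(r1))
        phi2 = self.mo_values(np.atleast_2d(r2))
        _, occ = self.occupied()
        return np.einsum("m,mi,mj->ij", occ, phi1, phi2)

    def ked(self, points: np.ndarray) -> np.ndarray:
        """Positive-definite kinetic-energy density 1/2 sum occ |grad phi|^2."""
        phi, dphi = self.mo_values(points, deriv=1)
        _, occ = self.occupied()
        return 0.5 * np.einsum("m,amn,amn->n", occ, dphi, dphi)

    def electronic_dipole(self, grid) -> np.ndarray:
        """-integral rho(r) r dV on a quadrature grid (points, weights)."""
        pts, w = grid
        rho = self.density(pts)
        return -np.einsum("n,na->a", rho * w, pts)


# ----------------------------------------------------------------------
# Operation-level wrappers
# ----------------------------------------------------------------------

def evaluate_density(wfn: Wavefunction, points, order: str = "value"):
    """Evaluate rho (order="value") or rho and its gradient (order="gradient")."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("evaluation points must be finite")
    if order == "value":
        return wfn.density(points)
    if order == "gradient":
        return wfn.density(points, deriv=1)
    raise ValueError(f"unknown order {order!r}")


def evaluate_rdm1(wfn: Wavefunction, r1, r2):
    """First-order reduced density matrix between two point batches."""
    return wfn.rdm1(np.asarray(r1, float), np.asarray(r2, float))


def evaluate_ked(wfn: Wavefunction, points):
    """Positive-definite kinetic-energy density at the given points."""
    return wfn.ked(np.atleast_2d(np.asarray(points, dtype=float)))
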