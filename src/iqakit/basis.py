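"""Contracted Cartesian/spherical Gaussian basis sets.

The in-memory atomic-orbital (AO) set is a list of contracted Cartesian
Gaussian shells.  A molecular-orbital coefficient matrix may refer either
to the raw Cartesian components or to real-spherical-harmonic combinations
of them (the ``[5D]/[7F]`` molden convention); in the latter case the basis
carries a sparse spherical->Cartesian transform so that all pointwise
evaluation happens in the Cartesian representation.

Conventions
-----------
* A primitive is ``x^a y^b z^c exp(-alpha r^2)`` relative to its center.
* Contraction coefficients multiply *normalized* primitives.
* Spherical components follow the molden ordering ``m = 0, +1, -1, +2, -2, ...``
  with the usual real harmonics (``d+2 ~ x^2-y^2``, ``d-2 ~ xy``).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["Shell", "GaussianBasis", "cart_powers", "prim_norm"]

_DFACT = {-1: 1.0, 0: 1.0, 1: 1.0, 2: 2.0, 3: 3.0, 4: 8.0, 5: 15.0, 6: 48.0, 7: 105.0}


def _double_factorial(n: int) -> float:
    if n < 2:
        return 1.0
    out = 1.0
    while n > 1:
        out *= n
        n -= 2
    return out


@lru_cache(maxsize=None)
def cart_powers(l: int) -> tuple[tuple[int, int, int], ...]:
    """Cartesian monomial powers of angular momentum *l*, canonical order.

    The order is lexicographic with x-power descending (xx, xy, xz, yy, yz,
    zz for d), matching the wfx primitive-type enumeration used here.
    """
    return tuple(
        (a, b, l - a - b) for a in range(l, -1, -1) for b in range(l - a, -1, -1)
    )


def prim_norm(alpha: float, a: int, b: int, c: int) -> float:
    """Normalization constant of a Cartesian primitive Gaussian."""
    l = a + b + c
    num = (2.0 * alpha / np.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0)
    den = np.sqrt(
        _double_factorial(2 * a - 1)
        * _double_factorial(2 * b - 1)
        * _double_factorial(2 * c - 1)
    )
    return num / den


@dataclass
class Shell:
    """One contracted shell on one center."""

    atom: int
    l: int
    center: np.ndarray  # (3,) bohr
    exps: np.ndarray  # (K,)
    coefs: np.ndarray  # (K,) coefficients of normalized primitives

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.exps = np.asarray(self.exps, dtype=float)
        self.coefs = np.asarray(self.coefs, dtype=float)
        if self.exps.shape != self.coefs.shape:
            raise ValueError("exponent/coefficient length mismatch")
        if np.any(self.exps <= 0):
            raise ValueError("primitive exponents must be positive")

    @property
    def n_cart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2

    @property
    def n_sph(self) -> int:
        return 2 * self.l + 1


def _real_sph(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic, molden sign convention."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** abs(m) * np.imag(y)


@lru_cache(maxsize=None)
def sph_to_cart_matrix(l: int) -> np.ndarray:
    """(2l+1, ncart) matrix T s.t. a unit-norm real-spherical AO is
    ``sum_c T[m,c] * (normalized cartesian component c)``.

    Solved exactly (to rounding) from point values on a sphere; the result
    is deterministic and cached.
    """
    powers = cart_powers(l)
    ncart = len(powers)
    if l < 2:
        return np.eye(2 * l + 1, ncart)
    rng = np.random.default_rng(12345 + l)
    npts = 40 * ncart
    theta = np.arccos(rng.uniform(-1, 1, npts))
    phi = rng.uniform(0, 2 * np.pi, npts)
    x = np.sin(theta) * np.cos(phi)
    y = np.sin(theta) * np.sin(phi)
    z = np.cos(theta)
    alpha = 1.0
    # normalized cartesian components evaluated on the unit sphere
    cart_vals = np.empty((ncart, npts))
    for ic, (a, b, c) in enumerate(powers):
        cart_vals[ic] = prim_norm(alpha, a, b, c) * x**a * y**b * z**c
    cart_vals *= np.exp(-alpha)
    morder = [0]
    for m in range(1, l + 1):
        morder += [m, -m]
    T = np.empty((2 * l + 1, ncart))
    # radial part of a unit-norm pure-l spherical gaussian with alpha=1
    rad_norm = np.sqrt(
        2.0 * (2.0 * alpha) ** (l + 1.5) / _gamma_half(2 * l + 3)
    )
    for im, m in enumerate(morder):
        target = rad_norm * _real_sph(l, m, theta, phi) * np.exp(-alpha)
        coef, *_ = np.linalg.lstsq(cart_vals.T, target, rcond=None)
        coef[np.abs(coef) < 1e-10] = 0.0
        T[im] = coef
    return T


def _gamma_half(n: int) -> float:
    """Gamma(n/2) for integer n >= 1."""
    from math import gamma

    return gamma(n / 2.0)


@dataclass
class GaussianBasis:
    """A full AO basis: shells plus (optionally) a spherical layer."""

    shells: list[Shell] = field(default_factory=list)
    spherical: bool = False

    # ------------------------------------------------------------------
    @property
    def n_cart(self) -> int:
        return sum(s.n_cart for s in self.shells)

    @property
    def n_ao(self) -> int:
        if self.spherical:
            return sum(s.n_sph for s in self.shells)
        return self.n_cart

    def sph_transform(self) -> np.ndarray:
        """(n_ao, n_cart) block-diagonal spherical->cartesian transform."""
        T = np.zeros((self.n_ao, self.n_cart))
        irow = icol = 0
        for s in self.shells:
            if self.spherical:
                T[irow : irow + s.n_sph, icol : icol + s.n_cart] = sph_to_cart_matrix(
                    s.l
                )
                irow += s.n_sph
            else:
                T[irow : irow + s.n_cart, icol : icol + s.n_cart] = np.eye(s.n_cart)
                irow += s.n_cart
            icol += s.n_cart
        return T

    # ------------------------------------------------------------------
    def eval_ao(self, points: np.ndarray, deriv: int = 0):
        """Evaluate AOs (and derivatives) at Cartesian points (N, 3) bohr.

        Returns ``vals`` of shape (nao, N); with ``deriv>=1`` also ``grad``
        (3, nao, N); with ``deriv==2`` also ``hess`` (3, 3, nao, N).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        npts = points.shape[0]
        ncart = self.n_cart
        vals = np.zeros((ncart, npts))
        grad = np.zeros((3, ncart, npts)) if deriv >= 1 else None
        hess = np.zeros((3, 3, ncart, npts)) if deriv >= 2 else None

        iao = 0
        for sh in self.shells:
            d = points - sh.center
            r2 = np.einsum("ij,ij->i", d, d)
            l = sh.l
            norm0 = np.array(
                [prim_norm(a, l, 0, 0) for a in sh.exps]
            )  # pure-l normalization; component factor applied below
            e = np.exp(-np.outer(sh.exps, r2))  # (K, N)
            cn = sh.coefs * norm0
            R0 = cn @ e
            R1 = (cn * sh.exps) @ e if deriv >= 1 else None
            R2 = (cn * sh.exps**2) @ e if deriv >= 2 else None

            x, y, z = d[:, 0], d[:, 1], d[:, 2]
            for a, b, c in cart_powers(l):
                comp = np.sqrt(
                    _double_factorial(2 * l - 1)
                    / (
                        _double_factorial(2 * a - 1)
                        * _double_factorial(2 * b - 1)
                        * _double_factorial(2 * c - 1)
                    )
                )
                mono = x**a * y**b * z**c
                vals[iao] = comp * mono * R0
                if deriv >= 1:
                    for axis, (p, w) in enumerate(((a, x), (b, y), (c, z))):
                        lower = (
                            p * _safe_pow(w, p - 1)
                            * _mono_except(x, y, z, a, b, c, axis)
                            if p > 0
                            else 0.0
                        )
                        upper = (
                            _safe_pow(w, p + 1)
                            * _mono_except(x, y, z, a, b, c, axis)
                        )
                        grad[axis, iao] = comp * (lower * R0 - 2.0 * upper * R1)
                if deriv >= 2:
                    pw = (a, b, c)
                    ws = (x, y, z)
                    for i in range(3):
                        for j in range(i, 3):
                            hess[i, j, iao] = comp * _hess_term(
                                ws, pw, i, j, R0, R1, R2
                            )
                            hess[j, i, iao] = hess[i, j, iao]
                iao += 1

        if self.spherical:
            T = self.sph_transform()
            vals = T @ vals
            if deriv >= 1:
                grad = np.einsum("sc,acn->asn", T, grad)
            if deriv >= 2:
                hess = np.einsum("sc,abcn->absn", T, hess)
        if deriv == 0:
            return vals
        if deriv == 1:
            return vals, grad
        return vals, grad, hess

    # ------------------------------------------------------------------
    def overlap(self) -> np.ndarray:
        """Analytic AO overlap matrix (in the AO representation of the MOs)."""
        from . import _mdint

        S = _mdint.overlap_cart(self.shells)
        if self.spherical:
            T = self.sph_transform()
            S = T @ S @ T.T
        return S


def _safe_pow(w: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return np.ones_like(w)
    return w**p


def _mono_except(x, y, z, a, b, c, axis):
    """Monomial with the `axis` factor removed."""
    if axis == 0:
        return _safe_pow(y, b) * _safe_pow(z, c)
    if axis == 1:
        return _safe_pow(x, a) * _safe_pow(z, c)
    return _safe_pow(x, a) * _safe_pow(y, b)


def _hess_term(ws, pw, i, j, R0, R1, R2):
    """Second derivative d^2/dw_i dw_j of mono(r) * R(r^2)."""
    a, b, c = pw
    x, y, z = ws
    p_i, p_j = pw[i], pw[j]
    w_i, w_j = ws[i], ws[j]
    if i == j:
        rest = _mono_except(x, y, z, a, b, c, i)
        t = 0.0
        if p_i >= 2:
            t = p_i * (p_i - 1) * _safe_pow(w_i, p_i - 2) * rest * R0
        t = t - 2.0 * (2 * p_i + 1) * _safe_pow(w_i, p_i) * rest * R1
        t = t + 4.0 * _safe_pow(w_i, p_i + 2) * rest * R2
        return t
    # off-diagonal: remove both factors
    k = 3 - i - j
    rest = _safe_pow(ws[k], pw[k])
    t = 0.0
    if p_i >= 1 and p_j >= 1:
        t = p_i * p_j * _safe_pow(w_i, p_i - 1) * _safe_pow(w_j, p_j - 1) * rest * R0
    if p_j >= 1:
        t = t - 2.0 * p_j * _safe_pow(w_i, p_i + 1) * _safe_pow(w_j, p_j - 1) * rest * R1
    if p_i >= 1:
        t = t - 2.0 * p_i * _safe_pow(w_i, p_i - 1) * _safe_pow(w_j, p_j + 1) * rest * R1
    t = t + 4.0 * _safe_pow(w_i, p_i + 1) * _safe_pow(w_j, p_j + 1) * rest * R2
    return t
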