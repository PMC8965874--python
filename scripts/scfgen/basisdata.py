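"""Basis-set data for fixture generation.

STO-3G exponents/coefficients are the standard published values.  The
triple-zeta set ("tz") uses the published correlation-consistent cc-pVTZ
primitive exponents; its contracted s/p coefficients are re-derived
variationally by a spherically averaged atomic HF calculation in the same
primitives (see make_fixtures.py), because no basis-set library is
available in this environment.  The resulting set is labelled "tz-synthetic"
in fixture metadata.
"""
from __future__ import annotations

import numpy as np

from iqakit.basis import GaussianBasis, Shell

STO3G = {
    "H": [
        (0, [3.42525091, 0.62391373, 0.16885540],
            [0.15432897, 0.53532814, 0.44463454]),
    ],
    "He": [
        (0, [6.36242139, 1.15892300, 0.31364979],
            [0.15432897, 0.53532814, 0.44463454]),
    ],
    "C": [
        (0, [71.61683735, 13.04509632, 3.53051216],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [2.94124940, 0.68348310, 0.22228990],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [2.94124940, 0.68348310, 0.22228990],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
    "N": [
        (0, [99.10616896, 18.05231239, 4.88566024],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [3.78045590, 0.87849664, 0.28571437],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [3.78045590, 0.87849664, 0.28571437],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
    "O": [
        (0, [130.70932140, 23.80886605, 6.44360831],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [5.03315132, 1.16959612, 0.38038896],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [5.03315132, 1.16959612, 0.38038896],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
}

# cc-pVTZ primitive exponents (published values); contractions re-derived.
TZ_PRIMS = {
    "H": {
        "s": [33.8700, 5.0950, 1.1590, 0.3258, 0.1027],
        "s_contracted": 1,   # one contracted function from all s primitives
        "s_free": [0.3258, 0.1027],
        "p": [1.4070, 0.3880],
        "d": [1.0570],
        "f": [],
    },
    "O": {
        "s": [15330.0, 2299.0, 522.4, 147.3, 47.55, 16.76, 6.207, 1.752,
              0.6882, 0.2384],
        "s_contracted": 2,   # 1s- and 2s-like contractions
        "s_free": [0.6882, 0.2384],
        "p": [34.46, 7.749, 2.280, 0.7156, 0.2140],
        "p_contracted": 1,
        "p_free": [0.7156, 0.2140],
        "d": [2.314, 0.645],
        "f": [1.428],
    },
}


def sto3g_basis(symbols, coords_bohr) -> GaussianBasis:
    shells = []
    for ia, (sym, xyz) in enumerate(zip(symbols, coords_bohr)):
        for l, exps, coefs in STO3G[sym]:
            shells.append(Shell(ia, l, np.asarray(xyz), exps, coefs))
    return GaussianBasis(shells, spherical=False)


def tz_basis(symbols, coords_bohr, contractions) -> GaussianBasis:
    """Build the reconstructed triple-zeta basis (spherical).

    ``contractions`` maps element -> dict with contraction coefficient
    arrays for the generally contracted s (and p) functions, as produced by
    the atomic-HF derivation in make_fixtures.py.
    """
    shells = []
    for ia, (sym, xyz) in enumerate(zip(symbols, coords_bohr)):
        prim = TZ_PRIMS[sym]
        ctr = contractions[sym]
        xyz = np.asarray(xyz)
        s_exps = np.array(prim["s"])
        for coefs in ctr["s"]:
            shells.append(Shell(ia, 0, xyz, s_exps, np.asarray(coefs)))
        for e in prim["s_free"]:
            shells.append(Shell(ia, 0, xyz, [e], [1.0]))
        p_exps = np.array(prim["p"])
        for coefs in ctr.get("p", []):
            shells.append(Shell(ia, 1, xyz, p_exps, np.asarray(coefs)))
        for e in prim.get("p_free", prim["p"] if sym == "H" else []):
            shells.append(Shell(ia, 1, xyz, [e], [1.0]))
        for e in prim["d"]:
            shells.append(Shell(ia, 2, xyz, [e], [1.0]))
        for e in prim["f"]:
            shells.append(Shell(ia, 3, xyz, [e], [1.0]))
    return GaussianBasis(shells, spherical=True)
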