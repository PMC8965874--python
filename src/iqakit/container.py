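"""HDF5 persistence of term matrices (bit-exact round trip)."""
from __future__ import annotations

import json
from pathlib import Path

import h5py

from .iqa import IQATermMatrix

__all__ = ["save_term_matrix", "load_term_matrix"]

_ARRAYS = [
    "kinetic", "v_ne_own", "vee_intra_coul", "vee_intra_xc",
    "v_nn", "v_en_cross", "vee_coul", "vee_xc",
]
_OPTIONAL = ["qmmm_ele", "qmmm_vdw", "disp", "mm_site_index"]


def save_term_matrix(terms: IQATermMatrix, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_atoms"] = terms.n_atoms
        f.attrs["xc_scale"] = terms.xc_scale
        if terms.scf_reference is not None:
            f.attrs["scf_reference"] = terms.scf_reference
        f.attrs["meta"] = json.dumps(terms.meta, default=float)
        for name in _ARRAYS:
            f.create_dataset(name, data=getattr(terms, name))
        for name in _OPTIONAL:
            v = getattr(terms, name)
            if v is not None:
                f.create_dataset(name, data=v)
    return path


def load_term_matrix(path) -> IQATermMatrix:
    with h5py.File(path, "r") as f:
        kwargs = {name: f[name][...] for name in _ARRAYS}
        for name in _OPTIONAL:
            kwargs[name] = f[name][...] if name in f else None
        terms = IQATermMatrix(
            n_atoms=int(f.attrs["n_atoms"]),
            xc_scale=float(f.attrs["xc_scale"]),
            scf_reference=(
                float(f.attrs["scf_reference"])
                if "scf_reference" in f.attrs
                else None
            ),
            meta=json.loads(f.attrs["meta"]),
            **kwargs,
        )
    return terms
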