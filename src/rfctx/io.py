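"""HDF5 model containers.

Context models are stored as /w0, /rf, /cfs/<l>/weights, /cfs/<l>/assignment;
filter banks as /filters, /eigenvalues; low-rank QN models as /c, /v plus the
selected filters.  Provenance attributes (family, C, seed) ride along as file
attributes.
"""

from __future__ import annotations

from .context import ContextField, ContextModelParams
from .stimulus import ContextWindowSpec
from .subspace import FilterBank, LowRankFilter, QNModel


def save_model_hdf5(path, model, **provenance) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        for k, v in provenance.items():
            h5.attrs[k] = v
        if isinstance(model, ContextModelParams):
            h5.attrs["kind"] = "context"
            h5.create_dataset("w0", data=model.w0)
            h5.create_dataset("rf", data=model.rf)
            for l, cf in enumerate(model.cfs):
                g = h5.create_group(f"cfs/{l}")
                g.create_dataset("weights", data=cf.weights)
                g.attrs["origin"] = cf.spec.origin
                if cf.rf_assignment is not None:
                    g.create_dataset("assignment", data=cf.rf_assignment)
        elif isinstance(model, FilterBank):
            h5.attrs["kind"] = "bank"
            h5.attrs["bank_kind"] = model.kind
            h5.create_dataset("filters", data=model.filters)
            if model.eigenvalues is not None:
                h5.create_dataset("eigenvalues", data=model.eigenvalues)
        elif isinstance(model, QNModel):
            h5.attrs["kind"] = "qn"
            h5.create_dataset("c", data=model.c)
            h5.create_dataset("v", data=model.v)
            h5.create_dataset("J", data=model.J)
            for i, f in enumerate(model.selected):
                g = h5.create_group(f"selected/{i}")
                g.create_dataset("w", data=f.w)
                g.attrs["lam"] = f.lam
                g.attrs["source"] = f.source
        else:
            raise TypeError(f"cannot store model of type {type(model).__name__}")


def load_model_hdf5(path):
    import h5py

    with h5py.File(path, "r") as h5:
        kind = h5.attrs["kind"]
        if kind == "context":
            cfs = []
            for l in sorted(h5.get("cfs", {}), key=int):
                g = h5[f"cfs/{l}"]
                w = g["weights"][...]
                spec = ContextWindowSpec(height=w.shape[0], width=w.shape[1],
                                         origin=tuple(g.attrs["origin"]))
                assign = g["assignment"][...] if "assignment" in g else None
                cfs.append(ContextField(w, spec, assign))
            return ContextModelParams(w0=float(h5["w0"][()]),
                                      rf=h5["rf"][...], cfs=cfs)
        if kind == "bank":
            ev = h5["eigenvalues"][...] if "eigenvalues" in h5 else None
            return FilterBank(filters=h5["filters"][...], eigenvalues=ev,
                              kind=str(h5.attrs.get("bank_kind", "stc")))
        if kind == "qn":
            sel = []
            for i in sorted(h5.get("selected", {}), key=int):
                g = h5[f"selected/{i}"]
                sel.append(LowRankFilter(g["w"][...], float(g.attrs["lam"]),
                                         str(g.attrs["source"])))
            return QNModel(c=float(h5["c"][()]), v=h5["v"][...],
                           J=h5["J"][...], selected=sel)
    raise ValueError(f"unknown model kind {kind!r}")
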