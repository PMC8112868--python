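"""One-file HDF5 persistence for :class:`~cytoclust.core.Experiment`.

Layout::

    /assays/raw, /assays/transformed      float64 matrices
    /cell_meta                            per-cell columns (incl. cell_sample)
    /sample_meta, /panel                  metadata tables
    /reductions/<name>                    (n_cells, 2) coordinates
    /clusterings/<name>/labels_by_k/<K>   integer label vectors
    /cell_labels/<name>                   text labels
    /provenance                           appendable JSON records

The checksum helper hashes everything except provenance timestamps, so two
runs of the same seeded command sequence produce identical digests.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import ClusterAssignments, Experiment, Panel, SampleTable

_STR = h5py.string_dtype(encoding="utf-8")


def _write_frame(grp: h5py.Group, df: pd.DataFrame) -> None:
    grp.attrs["columns"] = json.dumps([str(c) for c in df.columns])
    for col in df.columns:
        vals = df[col]
        if pd.api.types.is_numeric_dtype(vals) and not pd.api.types.is_bool_dtype(vals):
            grp.create_dataset(str(col), data=vals.to_numpy())
        elif pd.api.types.is_bool_dtype(vals):
            grp.create_dataset(str(col), data=vals.to_numpy(dtype=np.uint8))
            grp[str(col)].attrs["bool"] = 1
        else:
            grp.create_dataset(str(col), data=vals.astype(str).to_numpy(), dtype=_STR)


def _read_frame(grp: h5py.Group) -> pd.DataFrame:
    cols = json.loads(grp.attrs["columns"])
    data = {}
    for col in cols:
        ds = grp[col]
        arr = ds[()]
        if ds.attrs.get("bool"):
            arr = arr.astype(bool)
        elif arr.dtype.kind in ("S", "O"):
            arr = np.array([x.decode() if isinstance(x, bytes) else x for x in arr], dtype=object)
        data[col] = arr
    return pd.DataFrame(data, columns=cols)


def save_experiment(exp: Experiment, path, provenance: list[dict] | None = None) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        assays = f.create_group("assays")
        assays.create_dataset("raw", data=exp.raw)
        assays.create_dataset("transformed", data=exp.transformed)

        cm = exp.cell_meta.copy()
        cm.insert(0, "cell_sample", exp.cell_sample.astype(str))
        _write_frame(f.create_group("cell_meta"), cm)
        _write_frame(f.create_group("sample_meta"), exp.samples.table)
        _write_frame(f.create_group("panel"), exp.panel.table)

        red = f.create_group("reductions")
        for name, coords in exp.reductions.items():
            red.create_dataset(name, data=coords)

        cl = f.create_group("clusterings")
        for name, ca in exp.clusterings.items():
            g = cl.create_group(name)
            g.attrs["algorithm"] = ca.algorithm
            g.attrs["params"] = json.dumps(_jsonable(ca.params))
            lk = g.create_group("labels_by_k")
            for k, labels in ca.labels_by_k.items():
                lk.create_dataset(str(k), data=np.asarray(labels, dtype=np.int32))
            if ca.node_of_cell is not None:
                g.create_dataset("node_of_cell", data=ca.node_of_cell.astype(np.int32))
            model = ca.model if isinstance(ca.model, dict) else {}
            som = model.get("som")
            if som is not None:
                g.create_dataset("som_codes", data=som.codes)
            cr = model.get("consensus")
            if cr is not None:
                cg = g.create_group("consensus")
                for k, mat in cr.consensus.items():
                    cg.create_dataset(str(k), data=mat)
                cg.attrs["areas"] = json.dumps({str(k): v for k, v in cr.areas.items()})
                cg.attrs["deltas"] = json.dumps({str(k): v for k, v in cr.deltas.items()})

        lab = f.create_group("cell_labels")
        for name, labels in exp.cell_labels.items():
            lab.create_dataset(name, data=np.asarray(labels, dtype=object), dtype=_STR)
        f.attrs["merge_provenance"] = json.dumps(exp.merge_provenance)

        prov = f.create_dataset(
            "provenance", shape=(0,), maxshape=(None,), dtype=_STR
        )
        for rec in provenance or []:
            _append(prov, rec)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _append(ds: h5py.Dataset, rec: dict) -> None:
    ds.resize((ds.shape[0] + 1,))
    ds[-1] = json.dumps(rec, sort_keys=True)


def load_experiment(path) -> Experiment:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"container not found: {path}")
    with h5py.File(path, "r") as f:
        raw = f["assays/raw"][()]
        transformed = f["assays/transformed"][()]
        cm = _read_frame(f["cell_meta"])
        cell_sample = cm.pop("cell_sample").to_numpy(dtype=object)
        samples = SampleTable(_read_frame(f["sample_meta"]))
        panel = Panel(_read_frame(f["panel"]))
        exp = Experiment(raw, transformed, cell_sample, panel, samples, cm)

        for name in f["reductions"]:
            exp.reductions[name] = f["reductions"][name][()]
        for name in f["clusterings"]:
            g = f["clusterings"][name]
            labels_by_k = {
                int(k): g["labels_by_k"][k][()].astype(int) for k in g["labels_by_k"]
            }
            ca = ClusterAssignments(
                algorithm=g.attrs["algorithm"],
                params=json.loads(g.attrs["params"]),
                labels_by_k=labels_by_k,
                node_of_cell=g["node_of_cell"][()].astype(int)
                if "node_of_cell" in g
                else None,
            )
            exp.clusterings[name] = ca
        for name in f["cell_labels"]:
            arr = f["cell_labels"][name][()]
            exp.cell_labels[name] = np.array(
                [x.decode() if isinstance(x, bytes) else x for x in arr], dtype=object
            )
        exp.merge_provenance = json.loads(f.attrs.get("merge_provenance", "{}"))
    return exp


def append_provenance(path, command: str, params: dict, seed=None) -> None:
    """Append a provenance record (command, params, seed, timestamp)."""
    rec = {
        "command": command,
        "params": _jsonable(params),
        "seed": seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with h5py.File(path, "a") as f:
        if "provenance" not in f:
            f.create_dataset("provenance", shape=(0,), maxshape=(None,), dtype=_STR)
        _append(f["provenance"], rec)


def read_provenance(path) -> list[dict]:
    with h5py.File(path, "r") as f:
        if "provenance" not in f:
            return []
        return [json.loads(x.decode() if isinstance(x, bytes) else x) for x in f["provenance"][()]]


def container_checksum(path) -> str:
    """SHA-256 over all datasets and attributes, excluding provenance
    timestamps."""
    h = hashlib.sha256()
    with h5py.File(path, "r") as f:

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                h.update(name.encode())
                if name == "provenance":
                    for rec in obj[()]:
                        d = json.loads(rec.decode() if isinstance(rec, bytes) else rec)
                        d.pop("timestamp", None)
                        h.update(json.dumps(d, sort_keys=True).encode())
                else:
                    arr = obj[()]
                    if arr.dtype.kind == "O":
                        for x in arr:
                            h.update(x if isinstance(x, bytes) else str(x).encode())
                    else:
                        h.update(np.ascontiguousarray(arr).tobytes())
            for key in sorted(obj.attrs):
                h.update(key.encode())
                h.update(str(obj.attrs[key]).encode())

        # hash root attrs too
        for key in sorted(f.attrs):
            h.update(key.encode())
            h.update(str(f.attrs[key]).encode())
        f.visititems(visit)
    return h.hexdigest()
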