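"""Readers and writers for counts, density archives and vine structures.

Counts travel as delimited text (rows = trials, columns = neurons, header
row with labels) or as a numpy archive; both readers validate that entries
are non-negative integers.  Density grids are stored in a compressed numpy
archive together with JSON metadata (pair labels, tree level, estimator
kind, grid size).  Vine structures serialize to JSON with indices into the
density archive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import PairCopulaModel
from .vine import VineEdge, VineStructure

__all__ = [
    "read_counts",
    "write_counts",
    "save_density_archive",
    "load_density_archive",
    "vine_to_dict",
    "vine_from_dict",
    "save_vine",
    "load_vine",
]


def _validate_count_array(arr) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError("counts must be a 2-D trials x neurons matrix")
    vals = arr.astype(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("counts contain non-finite entries")
    if np.any(vals != np.round(vals)) or np.any(vals < 0):
        raise ValueError("counts must be non-negative integers")
    return vals.astype(np.int64)


def read_counts(path) -> tuple[np.ndarray, list]:
    """Load a count matrix; returns (counts, column labels)."""
    path = Path(path)
    if path.suffix in (".npz", ".npy"):
        if path.suffix == ".npz":
            with np.load(path, allow_pickle=False) as z:
                arr = z["counts"]
                labels = [str(x) for x in z["labels"]] if "labels" in z else None
        else:
            arr = np.load(path, allow_pickle=False)
            labels = None
        counts = _validate_count_array(arr)
        if labels is None:
            labels = [f"n{j}" for j in range(counts.shape[1])]
        return counts, labels
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return _validate_count_array(df.to_numpy()), [str(c) for c in df.columns]


def write_counts(path, counts, labels=None) -> None:
    path = Path(path)
    counts = _validate_count_array(counts)
    if labels is None:
        labels = [f"n{j}" for j in range(counts.shape[1])]
    if path.suffix == ".npz":
        np.savez_compressed(path, counts=counts,
                            labels=np.asarray(labels, dtype=str))
    else:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        pd.DataFrame(counts, columns=labels).to_csv(path, sep=sep, index=False)


def save_density_archive(path, grids, meta) -> None:
    """Store a stack of G x G grids with per-grid metadata records."""
    grids = np.asarray(grids, dtype=float)
    if grids.ndim == 2:
        grids = grids[None]
    if len(meta) != len(grids):
        raise ValueError("need one metadata record per grid")
    np.savez_compressed(path, grids=grids,
                        meta=np.frombuffer(json.dumps(list(meta)).encode(),
                                           dtype=np.uint8))


def load_density_archive(path) -> tuple[np.ndarray, list]:
    with np.load(path, allow_pickle=False) as z:
        grids = z["grids"]
        meta = json.loads(bytes(z["meta"]).decode())
    return grids, meta


def vine_to_dict(vine: VineStructure) -> dict:
    """JSON-serializable description of a fitted vine.

    Non-independence models are referenced by their position in the
    companion density archive (``grid_index`` in edge records).
    """
    edges = []
    gi = 0
    for e in vine.edges:
        rec = {
            "tree": e.tree, "root": e.root, "partner": e.partner,
            "conditioning": list(e.conditioning), "independent": e.independent,
            "p_value": e.p_value, "kind": e.model.kind,
            "grid_index": None,
        }
        if not e.independent:
            rec["grid_index"] = gi
            gi += 1
        edges.append(rec)
    return {
        "schema": "cvine-v1",
        "order": [int(v) for v in vine.order],
        "d": vine.d,
        "n_obs": vine.n_obs,
        "edges": edges,
    }


def vine_from_dict(doc: dict, grids=None) -> VineStructure:
    if doc.get("schema") != "cvine-v1":
        raise ValueError("not a cvine-v1 document")
    vine = VineStructure(order=np.asarray(doc["order"], dtype=int),
                         d=doc["d"], n_obs=doc["n_obs"])
    for rec in doc["edges"]:
        if rec["independent"]:
            model = PairCopulaModel(kind="independence")
        else:
            grid = None
            if grids is not None and rec["grid_index"] is not None:
                grid = np.asarray(grids[rec["grid_index"]], dtype=float)
            model = PairCopulaModel(kind=rec["kind"], G=grid.shape[0] if grid is not None else 100,
                                    _grid=grid)
        vine.edges.append(VineEdge(
            tree=rec["tree"], root=rec["root"], partner=rec["partner"],
            conditioning=tuple(rec["conditioning"]),
            independent=rec["independent"], p_value=rec["p_value"],
            model=model))
    return vine


def save_vine(json_path, vine: VineStructure, archive_path=None) -> None:
    doc = vine_to_dict(vine)
    if archive_path is not None:
        models = [e for e in vine.edges if not e.independent]
        if models:
            save_density_archive(
                archive_path,
                [e.model.grid for e in models],
                [{"root": e.root, "partner": e.partner, "tree": e.tree,
                  "kind": e.model.kind, "G": e.model.G} for e in models])
        doc["density_archive"] = str(archive_path)
    Path(json_path).write_text(json.dumps(doc, indent=1))


def load_vine(json_path) -> VineStructure:
    doc = json.loads(Path(json_path).read_text())
    grids = None
    if doc.get("density_archive"):
        try:
            grids, _ = load_density_archive(doc["density_archive"])
        except FileNotFoundError:
            grids = None
    return vine_from_dict(doc, grids)
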