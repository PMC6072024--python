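"""Persistence of the type-instance network description.

Per network ``<name>`` four files are written:

* ``<name>_nodes.h5``       — column datasets ``node_id``, ``node_type_id``
  plus one dataset per per-instance property (positions as ``x, y, z`` μm);
* ``<name>_node_types.csv`` — one row per node type, all shared properties;
* ``<name>_edges.h5``       — ``source_node_id``, ``target_node_id``,
  ``edge_type_id``, ``nsyns``;
* ``<name>_edge_types.csv`` — one row per edge type.

The big per-instance tables hold nothing but ids and per-instance arrays;
every shared value lives exactly once in a small human-editable CSV, so
changing, say, a synaptic weight for a whole edge type is a one-cell CSV
edit that leaves the HDF5 tables byte-identical.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Any, Dict, List, Optional

import h5py
import numpy as np
import pandas as pd

from .netbuild import MODEL_TYPES, Network

__all__ = ["NetworkFileSet", "save_network", "load_network", "validate"]

MANDATORY_NODE_KEYS = ("model_type", "model_template", "dynamics_params")
MANDATORY_EDGE_KEYS = ("syn_weight", "delay", "model_template",
                       "dynamics_params")


@dataclass
class NetworkFileSet:
    """Paths of the four files describing one network."""
    name: str
    nodes_file: str
    node_types_file: str
    edges_file: str
    edge_types_file: str

    @classmethod
    def in_directory(cls, directory: str, name: str) -> "NetworkFileSet":
        j = os.path.join
        return cls(name=name,
                   nodes_file=j(directory, f"{name}_nodes.h5"),
                   node_types_file=j(directory, f"{name}_node_types.csv"),
                   edges_file=j(directory, f"{name}_edges.h5"),
                   edge_types_file=j(directory, f"{name}_edge_types.csv"))

    def exists(self) -> bool:
        return all(os.path.exists(p) for p in
                   (self.nodes_file, self.node_types_file,
                    self.edges_file, self.edge_types_file))


def save_network(net: Network, directory: str) -> NetworkFileSet:
    """Write the four-file description of ``net`` into ``directory``."""
    findings = net.validate_integrity()
    if findings:
        raise ValueError("network fails integrity validation: "
                         + "; ".join(findings))
    os.makedirs(directory, exist_ok=True)
    fs = NetworkFileSet.in_directory(directory, net.name)

    with h5py.File(fs.nodes_file, "w") as f:
        g = f.create_group(net.name)
        g.create_dataset("node_id", data=np.arange(net.n_nodes,
                                                   dtype=np.int64))
        g.create_dataset("node_type_id", data=net._node_type_ids)
        for name in sorted(net._instance_props):
            g.create_dataset(name, data=net._instance_props[name])

    _write_type_csv(fs.node_types_file, "node_type_id", net.node_types)

    with h5py.File(fs.edges_file, "w") as f:
        g = f.create_group(net.name)
        order = np.lexsort((net.edge_table["source_node_id"],
                            net.edge_table["target_node_id"],
                            net.edge_table["edge_type_id"]))
        for col, data in net.edge_table.items():
            g.create_dataset(col, data=data[order])

    _write_type_csv(fs.edge_types_file, "edge_type_id", net.edge_types)
    return fs


def load_network(fileset: NetworkFileSet) -> Network:
    """Reconstruct a :class:`Network` from files (no rule re-execution)."""
    net = Network(fileset.name)
    net.node_types = _read_type_csv(fileset.node_types_file, "node_type_id")
    net.edge_types = _read_type_csv(fileset.edge_types_file, "edge_type_id")

    with h5py.File(fileset.nodes_file, "r") as f:
        g = f[fileset.name]
        net._node_type_ids = np.asarray(g["node_type_id"], dtype=np.int64)
        node_ids = np.asarray(g["node_id"], dtype=np.int64)
        if not np.array_equal(node_ids, np.arange(node_ids.size)):
            raise ValueError(
                f"{fileset.nodes_file}: node_id must be contiguous 0..N-1")
        for name in g:
            if name in ("node_id", "node_type_id"):
                continue
            net._instance_props[name] = np.asarray(g[name], dtype=float)

    with h5py.File(fileset.edges_file, "r") as f:
        g = f[fileset.name]
        for col in net.edge_table:
            net.edge_table[col] = np.asarray(g[col], dtype=np.int64)

    dangling = [int(t) for t in np.unique(net._node_type_ids)
                if int(t) not in net.node_types] if net.n_nodes else []
    dangling += [int(t) for t in np.unique(net.edge_table["edge_type_id"])
                 if int(t) not in net.edge_types] if net.n_edges else []
    if dangling:
        raise ValueError(
            f"{fileset.name}: dangling type ids {sorted(set(dangling))} "
            "referenced by instance tables but missing from type CSVs")
    return net


def validate(fileset: NetworkFileSet,
             for_simulation: bool = True) -> List[str]:
    """Schema/consistency report for a file set; empty iff loadable and,
    when ``for_simulation``, simulatable (mandatory keys present)."""
    findings: List[str] = []
    for p in (fileset.nodes_file, fileset.node_types_file,
              fileset.edges_file, fileset.edge_types_file):
        if not os.path.exists(p):
            findings.append(f"missing file {p}")
    if findings:
        return findings
    try:
        net = load_network(fileset)
    except Exception as exc:
        return [f"load failed: {exc}"]

    for ntid, props in net.node_types.items():
        mt = props.get("model_type")
        if mt is not None and mt not in MODEL_TYPES:
            findings.append(f"node type {ntid}: unknown model_type {mt!r}")
        if for_simulation:
            for key in MANDATORY_NODE_KEYS:
                if _absent(props.get(key)):
                    findings.append(f"node type {ntid}: missing {key}")
            if mt == "biophysical" and _absent(props.get("morphology_file")):
                findings.append(f"node type {ntid}: biophysical node type "
                                "lacks morphology_file")
    biophysical_types = {ntid for ntid, p in net.node_types.items()
                         if p.get("model_type") == "biophysical"}
    target_types_by_etid: Dict[int, set] = {}
    if net.n_edges:
        tt = net._node_type_ids[net.edge_table["target_node_id"]]
        for etid in np.unique(net.edge_table["edge_type_id"]):
            mask = net.edge_table["edge_type_id"] == etid
            target_types_by_etid[int(etid)] = set(np.unique(tt[mask]).tolist())
    for etid, props in net.edge_types.items():
        if "delay" in props and not _absent(props["delay"]) \
                and float(props["delay"]) < 0:
            findings.append(f"edge type {etid}: negative delay "
                            f"{props['delay']}")
        dr = props.get("distance_range")
        if dr is not None and not _absent(dr):
            if len(dr) != 2 or not (0 <= dr[0] <= dr[1]):
                findings.append(f"edge type {etid}: malformed "
                                f"distance_range {dr!r}")
        if for_simulation:
            for key in MANDATORY_EDGE_KEYS:
                if _absent(props.get(key)):
                    findings.append(f"edge type {etid}: missing {key}")
            targets_biophys = target_types_by_etid.get(etid, set()) \
                & biophysical_types
            ts = props.get("target_sections")
            if targets_biophys and (_absent(ts) or len(ts) == 0):
                findings.append(
                    f"edge type {etid}: empty target_sections but targets "
                    "biophysical nodes")
    return findings


# --------------------------------------------------------------- CSV helpers

def _serialize(value: Any) -> Any:
    if isinstance(value, (list, tuple, np.ndarray)):
        return json.dumps(list(np.asarray(value).tolist()))
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if value is None or isinstance(value, (str, int, float, bool)):
        return value
    raise TypeError(f"cannot serialize property value {value!r} "
                    f"of type {type(value).__name__}")


def _write_type_csv(path: str, id_col: str,
                    types: Dict[int, Dict[str, Any]]) -> None:
    rows = []
    for tid in sorted(types):
        row = {id_col: tid}
        for k, v in types[tid].items():
            try:
                row[k] = _serialize(v)
            except TypeError as exc:
                raise TypeError(f"type {tid}, property {k!r}: {exc}") from None
        rows.append(row)
    columns = [id_col] + sorted({k for r in rows for k in r} - {id_col})
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, na_rep="")


def _parse_cell(value: Any) -> Any:
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value[:1] in "[{":
        try:
            return json.loads(value)
        except json.JSONDecodeError:
            return value
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.bool_):
        return bool(value)
    return value


def _read_type_csv(path: str, id_col: str) -> Dict[int, Dict[str, Any]]:
    df = pd.read_csv(path)
    if id_col not in df.columns:
        raise ValueError(f"{path}: missing column {id_col}")
    types: Dict[int, Dict[str, Any]] = {}
    for _, row in df.iterrows():
        tid = int(row[id_col])
        props = {}
        for k in df.columns:
            if k == id_col:
                continue
            v = _parse_cell(row[k])
            if v is not None:
                props[k] = v
        types[tid] = props
    return types


def _absent(v: Any) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))
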