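"""High-level network construction.

A network is built in two passes, mirroring how large heterogeneous models
are specified in practice:

1. ``add_nodes`` appends a *group* of cells sharing type-level properties
   (model kind, template, parameter file, morphology) while per-cell values
   (positions, tuning angles) are given as arrays.  Each call creates one
   node type; the cells get contiguous global ids (gids).
2. ``add_edges`` registers a *rule*: a pair of node queries plus a
   connection callable.  Rules are deferred; ``build_edges(seed)``
   enumerates the query cross-product and asks the callable for the number
   of synapses (``nsyns``) of each pair.  Pairs with ``nsyns >= 1`` become
   edge instances referencing the rule's edge type.

This "type-instance" split keeps the large per-instance tables free of
anything shared: editing a type property (say ``syn_weight``) never touches
the instance tables.

All randomness inside connection rules draws from a counter-based stream
keyed by ``(seed, edge_type_id, source_gid, target_gid)``, so a build is a
pure function of (specification, seed) — independent of iteration order and
of how the pair loop might be chunked across processes.
"""

from __future__ import annotations

import inspect
from typing import Any, Callable, Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np

from .registry import has_weight_function
from .streams import TAG_EDGE, pair_stream

__all__ = [
    "Network",
    "NodeView",
    "create_network",
    "distance_tapered_probability",
]

MODEL_TYPES = ("biophysical", "intfire")
RESERVED_NODE_KEYS = ("node_id", "node_type_id")
SECTION_NAMES = ("somatic", "axonal", "basal", "apical")


class NodeView:
    """Read-only merged view of one node's type- and instance-level properties.

    Instance values win on name collision (collisions are rejected at
    ``add_nodes`` time, so this is moot in valid networks).  Missing
    properties raise ``KeyError``; queries treat that as a non-match.
    """

    __slots__ = ("_net", "node_id")

    def __init__(self, net: "Network", node_id: int):
        self._net = net
        self.node_id = int(node_id)

    @property
    def node_type_id(self) -> int:
        return int(self._net._node_type_ids[self.node_id])

    def __getitem__(self, name: str) -> Any:
        if name == "node_id":
            return self.node_id
        if name == "node_type_id":
            return self.node_type_id
        inst = self._net._instance_props
        if name in inst:
            v = inst[name][self.node_id]
            if not (isinstance(v, float) and np.isnan(v)):
                return v
        tp = self._net.node_types[self.node_type_id]
        if name in tp:
            return tp[name]
        raise KeyError(name)

    def get(self, name: str, default: Any = None) -> Any:
        try:
            return self[name]
        except KeyError:
            return default

    def __contains__(self, name: str) -> bool:
        return self.get(name, _MISSING) is not _MISSING

    @property
    def position(self) -> np.ndarray:
        """Soma position as a length-3 array (μm); KeyError when absent."""
        return np.array([self["x"], self["y"], self["z"]], dtype=float)

    def __repr__(self) -> str:  # pragma: no cover
        return f"NodeView(gid={self.node_id}, node_type_id={self.node_type_id})"


_MISSING = object()


class _EdgeRule:
    __slots__ = (
        "edge_type_id",
        "source_query",
        "target_query",
        "connection_rule",
        "connection_params",
        "source_network",
    )

    def __init__(self, edge_type_id, source_query, target_query,
                 connection_rule, connection_params, source_network):
        self.edge_type_id = edge_type_id
        self.source_query = source_query
        self.target_query = target_query
        self.connection_rule = connection_rule
        self.connection_params = dict(connection_params or {})
        self.source_network = source_network


class Network:
    """In-memory network: node/edge instances plus node/edge type tables."""

    def __init__(self, name: str):
        if not isinstance(name, str) or not name:
            raise ValueError("network name must be a nonempty string")
        self.name = name
        self.node_types: Dict[int, Dict[str, Any]] = {}
        self.edge_types: Dict[int, Dict[str, Any]] = {}
        self._node_type_ids = np.zeros(0, dtype=np.int64)
        # name -> float array over all gids; NaN encodes "absent on this node"
        self._instance_props: Dict[str, np.ndarray] = {}
        self._edge_rules: List[_EdgeRule] = []
        # columnar edge instance tables
        self.edge_table: Dict[str, np.ndarray] = _empty_edge_table()
        self.provenance: Dict[str, Any] = {}

    # ------------------------------------------------------------------ nodes

    @property
    def n_nodes(self) -> int:
        return int(self._node_type_ids.size)

    @property
    def n_edges(self) -> int:
        return int(self.edge_table["edge_type_id"].size)

    def add_nodes(self, N: int,
                  per_node_props: Optional[Mapping[str, np.ndarray]] = None,
                  **shared_props: Any) -> int:
        """Append ``N`` nodes sharing ``shared_props``; returns the node type id.

        ``per_node_props`` maps property name to an array of length ``N``
        (``positions`` may be an ``(N, 3)`` array of x, y, z in μm, stored
        as three scalar properties).
        """
        if not isinstance(N, (int, np.integer)) or N < 1:
            raise ValueError(f"N must be a positive integer, got {N!r}")
        per_node_props = dict(per_node_props or {})
        if "positions" in per_node_props:
            pos = np.asarray(per_node_props.pop("positions"), dtype=float)
            if pos.shape != (N, 3) or not np.all(np.isfinite(pos)):
                raise ValueError(
                    f"positions must be a finite ({N}, 3) array, got shape "
                    f"{pos.shape}")
            per_node_props["x"] = pos[:, 0]
            per_node_props["y"] = pos[:, 1]
            per_node_props["z"] = pos[:, 2]
        for key in RESERVED_NODE_KEYS:
            if key in shared_props or key in per_node_props:
                raise ValueError(f"property name {key!r} is reserved")
        overlap = set(shared_props) & set(per_node_props)
        if overlap:
            raise ValueError(
                f"properties {sorted(overlap)} appear both at type level and "
                "per node; pick one level")
        for name in list(shared_props) + list(per_node_props):
            if not isinstance(name, str) or not name:
                raise ValueError("property names must be nonempty strings")
        if "model_type" in shared_props and \
                shared_props["model_type"] not in MODEL_TYPES:
            raise ValueError(
                f"model_type must be one of {MODEL_TYPES}, got "
                f"{shared_props['model_type']!r}")
        arrays = {}
        for name, arr in per_node_props.items():
            a = np.asarray(arr, dtype=float)
            if a.shape != (N,):
                raise ValueError(
                    f"per-node property {name!r} has shape {a.shape}, "
                    f"expected ({N},)")
            arrays[name] = a
        # collision of a new instance name against an existing type's shared
        # name (or vice versa) is rejected: one flat namespace per network
        for ntid, props in self.node_types.items():
            both = set(props) & set(arrays)
            if both:
                raise ValueError(
                    f"per-node properties {sorted(both)} collide with "
                    f"type-level properties of node type {ntid}")
        for name in shared_props:
            if name in self._instance_props:
                raise ValueError(
                    f"type-level property {name!r} collides with an existing "
                    "per-node property")

        node_type_id = len(self.node_types)
        self.node_types[node_type_id] = dict(shared_props)
        old_n = self.n_nodes
        self._node_type_ids = np.concatenate(
            [self._node_type_ids, np.full(N, node_type_id, dtype=np.int64)])
        for name, col in self._instance_props.items():
            self._instance_props[name] = np.concatenate(
                [col, np.full(N, np.nan)])
        for name, a in arrays.items():
            if name not in self._instance_props:
                self._instance_props[name] = np.full(old_n + N, np.nan)
            self._instance_props[name][old_n:old_n + N] = a
        return node_type_id

    def node(self, gid: int) -> NodeView:
        if not 0 <= gid < self.n_nodes:
            raise IndexError(f"gid {gid} out of range [0, {self.n_nodes})")
        return NodeView(self, gid)

    def nodes(self) -> Iterable[NodeView]:
        for gid in range(self.n_nodes):
            yield NodeView(self, gid)

    def query_nodes(self, predicate) -> List[NodeView]:
        """Nodes matching ``predicate``, ascending gid.

        ``predicate`` is either a mapping of property → required value
        (equality match) or a callable over a :class:`NodeView`.  A
        predicate touching a property a node lacks is a non-match, never an
        error — heterogeneous populations must be queryable.
        """
        if predicate is None or predicate is True:
            return list(self.nodes())
        if isinstance(predicate, Mapping):
            items = list(predicate.items())

            def match(n: NodeView) -> bool:
                return all(n.get(k, _MISSING) == v for k, v in items)
        else:
            def match(n: NodeView) -> bool:
                try:
                    return bool(predicate(n))
                except KeyError:
                    return False
        return [n for n in self.nodes() if match(n)]

    # ------------------------------------------------------------------ edges

    def add_edges(self, source=None, target=None,
                  connection_rule: Callable[..., int] | None = None,
                  connection_params: Optional[Mapping[str, Any]] = None,
                  source_network: Optional["Network"] = None,
                  **edge_type_props: Any) -> int:
        """Register a deferred connection rule; returns the new edge type id.

        ``source``/``target`` are node queries (see :meth:`query_nodes`);
        ``source_network`` lets an external population (e.g. a thalamic
        input) project onto this network.  Nothing is enumerated until
        :meth:`build_edges`.
        """
        if connection_rule is None:
            raise ValueError("connection_rule is required")
        props = dict(edge_type_props)
        if "delay" in props and float(props["delay"]) < 0:
            raise ValueError(f"delay must be >= 0 ms, got {props['delay']}")
        if "distance_range" in props:
            dr = list(props["distance_range"])
            if len(dr) != 2 or not (0 <= dr[0] <= dr[1]):
                raise ValueError(
                    f"distance_range must be [d_min, d_max] with "
                    f"0 <= d_min <= d_max, got {props['distance_range']!r}")
        if "target_sections" in props:
            bad = set(props["target_sections"]) - set(SECTION_NAMES)
            if bad:
                raise ValueError(
                    f"unknown target_sections {sorted(bad)}; valid: "
                    f"{SECTION_NAMES}")
        wf = props.get("weight_function")
        if wf is not None and not has_weight_function(wf):
            raise ValueError(f"unknown weight_function {wf!r}")
        edge_type_id = len(self.edge_types)
        props["source_population"] = (
            source_network.name if source_network is not None else self.name)
        self.edge_types[edge_type_id] = props
        self._edge_rules.append(_EdgeRule(
            edge_type_id, source, target, connection_rule,
            connection_params, source_network))
        return edge_type_id

    def build_edges(self, seed: int = 0) -> int:
        """Instantiate all registered rules; returns the total edge count.

        Pair iteration is (target gid ascending, source gid ascending); the
        result is nevertheless iteration-order independent because every
        pair draws from its own ``(seed, edge_type_id, source_gid,
        target_gid)`` stream.
        """
        if not self._edge_rules:
            raise ValueError("no edge rules registered; call add_edges first")
        cols: Dict[str, list] = {k: [] for k in _empty_edge_table()}
        for rule in self._edge_rules:
            src_net = rule.source_network or self
            sources = src_net.query_nodes(rule.source_query)
            targets = self.query_nodes(rule.target_query)
            wants_rng = _accepts_rng(rule.connection_rule)
            for tgt in targets:
                for src in sources:
                    kwargs = dict(rule.connection_params)
                    if wants_rng:
                        kwargs["rng"] = pair_stream(
                            seed, TAG_EDGE, rule.edge_type_id,
                            src.node_id, tgt.node_id)
                    nsyns = rule.connection_rule(src, tgt, **kwargs)
                    if not isinstance(nsyns, (int, np.integer)):
                        raise TypeError(
                            f"connection rule of edge type "
                            f"{rule.edge_type_id} returned {nsyns!r} for "
                            f"pair ({src.node_id}->{tgt.node_id}); an "
                            "integer nsyns >= 0 is required")
                    if nsyns < 0:
                        raise ValueError(
                            f"connection rule of edge type "
                            f"{rule.edge_type_id} returned negative nsyns "
                            f"for pair ({src.node_id}->{tgt.node_id})")
                    if nsyns >= 1:
                        cols["source_node_id"].append(src.node_id)
                        cols["target_node_id"].append(tgt.node_id)
                        cols["edge_type_id"].append(rule.edge_type_id)
                        cols["nsyns"].append(int(nsyns))
        self.edge_table = {
            k: np.asarray(v, dtype=np.int64) for k, v in cols.items()}
        self.provenance = {
            "seed": int(seed),
            "rules": [getattr(r.connection_rule, "__name__", "<callable>")
                      for r in self._edge_rules],
        }
        return self.n_edges

    # -------------------------------------------------------------- integrity

    def validate_integrity(self) -> List[str]:
        """Referential-integrity findings; empty list when consistent."""
        findings = []
        used = np.unique(self._node_type_ids) if self.n_nodes else []
        for ntid in used:
            if int(ntid) not in self.node_types:
                findings.append(f"dangling node_type_id {int(ntid)}")
        et = self.edge_table
        for etid in np.unique(et["edge_type_id"]) if self.n_edges else []:
            if int(etid) not in self.edge_types:
                findings.append(f"dangling edge_type_id {int(etid)}")
        if self.n_edges:
            if et["target_node_id"].min(initial=0) < 0 or \
                    (et["target_node_id"] >= self.n_nodes).any():
                findings.append("edge target gid out of range")
            if (et["nsyns"] < 1).any():
                findings.append("edge with nsyns < 1")
        return findings


def create_network(name: str) -> Network:
    """Create an empty named network."""
    return Network(name)


def _empty_edge_table() -> Dict[str, np.ndarray]:
    return {k: np.zeros(0, dtype=np.int64)
            for k in ("source_node_id", "target_node_id",
                      "edge_type_id", "nsyns")}


def _accepts_rng(fn: Callable) -> bool:
    try:
        params = inspect.signature(fn).parameters
    except (TypeError, ValueError):  # builtins, numpy ufuncs
        return False
    if "rng" in params:
        return True
    return any(p.kind is inspect.Parameter.VAR_KEYWORD
               for p in params.values())


# ------------------------------------------------------------ example rules

def distance_tapered_probability(source: NodeView, target: NodeView,
                                 p0: float, sigma: float,
                                 nsyns_range: Sequence[int] = (1, 1),
                                 *, rng: np.random.Generator) -> int:
    """Gaussian distance-dependent connection rule.

    Connects with probability ``p0 * exp(-d² / (2 σ²))`` where ``d`` is the
    planar (x, z) distance between the somata in μm; a connected pair gets
    a uniform integer ``nsyns`` in ``nsyns_range``.
    """
    if not 0.0 <= p0 <= 1.0:
        raise ValueError(f"p0 must be in [0, 1], got {p0}")
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    lo, hi = int(nsyns_range[0]), int(nsyns_range[1])
    if not 1 <= lo <= hi:
        raise ValueError(f"nsyns_range must satisfy 1 <= lo <= hi, "
                         f"got {nsyns_range!r}")
    try:
        sp, tp = source.position, target.position
    except KeyError:
        raise ValueError(
            f"distance rule requires positions on both nodes "
            f"(pair {source.node_id}->{target.node_id})") from None
    dx, dz = sp[0] - tp[0], sp[2] - tp[2]
    p = p0 * float(np.exp(-(dx * dx + dz * dz) / (2.0 * sigma * sigma)))
    if rng.random() >= p:
        return 0
    return int(rng.integers(lo, hi + 1))
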