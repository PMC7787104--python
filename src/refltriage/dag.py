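"""Typed hypothesis DAG: nodes are hypotheses about the crystal, edges
add information. Backed by networkx for the graph algorithms."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["DagNode", "Dag", "NODE_KINDS"]

NODE_KINDS = (
    "crystal",
    "data",
    "anisotropy",
    "tncs_order",
    "tncs_correction",
    "twinning",
    "spacegroup",
    "spacegroup_expansion",
)

# stage partial order: each kind lists the kinds its parents may have
_ALLOWED_PARENTS = {
    "crystal": (),
    "data": ("crystal",),
    "anisotropy": ("data",),
    "tncs_order": ("anisotropy",),
    "tncs_correction": ("tncs_order",),
    "twinning": ("tncs_correction", "tncs_order"),
    "spacegroup": ("twinning",),
    "spacegroup_expansion": ("twinning",),
}


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


@dataclass
class DagNode:
    id: str
    kind: str
    payload: dict = field(default_factory=dict)
    parents: list[str] = field(default_factory=list)
    rank: float = 0.0


def content_id(kind: str, payload_key: dict | str, parents: list[str]) -> str:
    """Deterministic node id from the hypothesis content (kind, the
    stage's defining parameters and the parent ids), so re-running a
    stage regenerates the same id."""
    blob = json.dumps(
        {"kind": kind, "key": _jsonable(payload_key), "parents": sorted(parents)},
        sort_keys=True,
    )
    digest = hashlib.sha256(blob.encode()).hexdigest()[:10]
    return f"{kind}-{digest}"


class Dag:
    def __init__(self):
        self._g = nx.DiGraph()

    # -- construction -------------------------------------------------
    def add_node(
        self,
        kind: str,
        payload: dict | None = None,
        parents: list[str] | None = None,
        rank: float = 0.0,
        node_id: str | None = None,
        id_key=None,
    ) -> str:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        parents = list(parents or [])
        payload = dict(payload or {})
        for p in parents:
            if p not in self._g:
                raise KeyError(f"unknown parent node {p!r}")
        nid = node_id or content_id(kind, id_key if id_key is not None else payload, parents)
        if nid in self._g:
            raise ValueError(f"duplicate node id {nid!r}")
        self._g.add_node(nid, kind=kind, payload=payload, rank=float(rank))
        for p in parents:
            self._g.add_edge(p, nid)
        if not nx.is_directed_acyclic_graph(self._g):  # atomic rollback
            self._g.remove_node(nid)
            raise ValueError("insertion would create a directed cycle")
        return nid

    def add_edge(self, parent: str, child: str):
        if parent not in self._g or child not in self._g:
            raise KeyError("both endpoints must exist")
        self._g.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(self._g):
            self._g.remove_edge(parent, child)
            raise ValueError("edge would create a directed cycle")

    # -- access -------------------------------------------------------
    def __contains__(self, node_id: str) -> bool:
        return node_id in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def node(self, node_id: str) -> DagNode:
        data = self._g.nodes[node_id]
        return DagNode(
            id=node_id,
            kind=data["kind"],
            payload=data["payload"],
            parents=sorted(self._g.predecessors(node_id)),
            rank=data["rank"],
        )

    def nodes(self) -> list[DagNode]:
        return [self.node(n) for n in sorted(self._g.nodes)]

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    def roots(self) -> list[str]:
        return sorted(n for n in self._g if self._g.in_degree(n) == 0)

    def set_rank(self, node_id: str, rank: float):
        self._g.nodes[node_id]["rank"] = float(rank)

    # -- algorithms ---------------------------------------------------
    def topological_sort(self) -> list[str]:
        """Parents before children; ties broken by node id."""
        return list(nx.lexicographical_topological_sort(self._g))

    def shortest_path(self, a: str, b: str) -> list[str] | None:
        """Minimum-edge directed path a -> b; among equal-length paths the
        lexicographically smallest; None when unreachable."""
        if a not in self._g or b not in self._g:
            raise KeyError("both endpoints must exist")
        if a == b:
            return [a]
        # BFS layers with lexicographic parent choice
        best_path = {a: (0, (a,))}
        frontier = [a]
        while frontier:
            nxt = []
            for u in sorted(frontier):
                du, pu = best_path[u]
                for v in sorted(self._g.successors(u)):
                    cand = (du + 1, pu + (v,))
                    if v not in best_path or cand < best_path[v]:
                        best_path[v] = cand
                        nxt.append(v)
            frontier = nxt
        if b not in best_path:
            return None
        return list(best_path[b][1])

    def leaf_hypotheses(self) -> list[DagNode]:
        leaves = [n for n in self._g if self._g.out_degree(n) == 0]
        nodes = [self.node(n) for n in leaves]
        nodes.sort(key=lambda nd: (-nd.rank, nd.id))
        return nodes

    # -- serialization ------------------------------------------------
    def serialize(self) -> str:
        doc = {
            "format": "refltriage-dag/1",
            "nodes": [
                {
                    "id": nd.id,
                    "kind": nd.kind,
                    "payload": _jsonable(nd.payload),
                    "rank": nd.rank,
                }
                for nd in self.nodes()
            ],
            "edges": [[a, b] for a, b in self.edges()],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def deserialize(cls, text: str) -> "Dag":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed dag document at line {exc.lineno}: {exc.msg}")
        if doc.get("format") != "refltriage-dag/1":
            raise ValueError("malformed dag document at line 1: bad format tag")
        dag = cls()
        for nd in doc["nodes"]:
            dag._g.add_node(nd["id"], kind=nd["kind"], payload=nd["payload"],
                            rank=float(nd.get("rank", 0.0)))
        for a, b in doc["edges"]:
            dag._g.add_edge(a, b)
        if not nx.is_directed_acyclic_graph(dag._g):
            raise ValueError("malformed dag document: contains a cycle")
        return dag

    def to_dot(self) -> str:
        lines = ["digraph hypotheses {"]
        for nd in self.nodes():
            label = f"{nd.kind}\\n{nd.id}"
            lines.append(f'  "{nd.id}" [label="{label}"];')
        for a, b in self.edges():
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)
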