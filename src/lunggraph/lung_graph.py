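"""Assembly of the per-patient 10-node lung graph.

Topology is purely anatomical and never depends on image content: a fixed
airway tree (trachea root -> carina -> main bronchi -> lobes) plus one
tumor node attached to every lobe the tumor overlaps.

Fixed tree edges: ROOT-CENTER, CENTER-LEFT, CENTER-RIGHT, LEFT-LUL,
LEFT-LLL, RIGHT-RUL, RIGHT-RML, RIGHT-RLL.  Whether lobes hang off the
distal bronchus points or directly off the carina is an open modelling
choice; the bronchus-mediated tree above is this package's convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from lunggraph.features import NodeFeature
from lunggraph.roles import CANONICAL_ROLE_ORDER, LOBE_ROLES, ROLE_INDEX, NodeRole

#: The fixed anatomical tree over the nine non-tumor nodes.
FIXED_TREE_EDGES: tuple[tuple[NodeRole, NodeRole], ...] = (
    (NodeRole.ROOT, NodeRole.CENTER),
    (NodeRole.CENTER, NodeRole.LEFT),
    (NodeRole.CENTER, NodeRole.RIGHT),
    (NodeRole.LEFT, NodeRole.LUL),
    (NodeRole.LEFT, NodeRole.LLL),
    (NodeRole.RIGHT, NodeRole.RUL),
    (NodeRole.RIGHT, NodeRole.RML),
    (NodeRole.RIGHT, NodeRole.RLL),
)


def build_topology(tumor_lobes: list[NodeRole]) -> list[tuple[NodeRole, NodeRole]]:
    """Edge list: fixed anatomical tree + one TUMOR edge per host lobe.

    Edges are undirected, stored once, ordered lexicographically by
    canonical role index for determinism.
    """
    if not tumor_lobes:
        raise ValueError("tumor_lobes must be nonempty")
    seen = set()
    for lobe in tumor_lobes:
        if lobe not in LOBE_ROLES:
            raise ValueError(f"{lobe!r} is not a lobe role")
        if lobe in seen:
            raise ValueError(f"duplicate tumor lobe {lobe!r}")
        seen.add(lobe)
    edges = list(FIXED_TREE_EDGES) + [(NodeRole.TUMOR, lobe) for lobe in tumor_lobes]
    canon = [tuple(sorted(e, key=lambda r: ROLE_INDEX[r])) for e in edges]
    canon.sort(key=lambda e: (ROLE_INDEX[e[0]], ROLE_INDEX[e[1]]))
    return canon


@dataclass
class LungGraph:
    """10 role-tagged nodes, anatomical edges, a 10x96 feature block."""

    edges: list[tuple[NodeRole, NodeRole]]
    features: np.ndarray  # (10, NODE_DIM), rows in canonical role order
    patient_id: str = ""
    label: Optional[int] = None  # 1 = death within 5 years
    tumor_lobes: list[NodeRole] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape[0] != len(CANONICAL_ROLE_ORDER):
            raise ValueError(
                f"feature block must have {len(CANONICAL_ROLE_ORDER)} rows, "
                f"got {self.features.shape[0]}"
            )
        if not np.all(np.isfinite(self.features)):
            raise ValueError("graph features must be finite")
        self._validate_edges()

    def _validate_edges(self) -> None:
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {a!r}-{b!r}")
            seen.add(key)

    @property
    def n_nodes(self) -> int:
        return len(CANONICAL_ROLE_ORDER)

    @property
    def roles(self) -> tuple[NodeRole, ...]:
        return CANONICAL_ROLE_ORDER

    def neighbors(self, role: NodeRole) -> list[NodeRole]:
        """Neighbors of a node in canonical role order."""
        nbrs = set()
        for a, b in self.edges:
            if a == role:
                nbrs.add(b)
            elif b == role:
                nbrs.add(a)
        return sorted(nbrs, key=lambda r: ROLE_INDEX[r])

    def neighbor_indices(self) -> list[list[int]]:
        """Per-node neighbor index lists (canonical order), for message passing."""
        return [
            [ROLE_INDEX[n] for n in self.neighbors(role)]
            for role in CANONICAL_ROLE_ORDER
        ]

    def is_connected(self) -> bool:
        adj = self.neighbor_indices()
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_nodes

    def topology_key(self) -> tuple:
        """Hashable edge signature; graphs sharing it can be batched together."""
        return tuple((a.value, b.value) for a, b in self.edges)


def build_graph(
    features: dict[NodeRole, NodeFeature],
    tumor_lobes: list[NodeRole],
    patient_id: str = "",
    label: Optional[int] = None,
) -> LungGraph:
    """Assemble a LungGraph from per-role node features and tumor lobe membership."""
    for role in CANONICAL_ROLE_ORDER:
        if role not in features:
            raise ValueError(f"missing node feature for role {role.value}")
    block = np.stack([features[role].vector for role in CANONICAL_ROLE_ORDER])
    edges = build_topology(tumor_lobes)
    g = LungGraph(
        edges=edges,
        features=block,
        patient_id=patient_id,
        label=label,
        tumor_lobes=sorted(tumor_lobes, key=lambda r: ROLE_INDEX[r]),
    )
    assert g.is_connected()
    return g


# ---------------------------------------------------------------------------
# Serialization: JSON with full-precision features (float64 repr round-trips)
# ---------------------------------------------------------------------------


def serialize_graph(g: LungGraph) -> str:
    payload = {
        "schema": "lunggraph/v1",
        "patient_id": g.patient_id,
        "label": g.label,
        "tumor_lobes": [r.value for r in g.tumor_lobes],
        "edges": [[a.value, b.value] for a, b in g.edges],
        "nodes": [
            {"role": role.value, "feature": g.features[i].tolist()}
            for i, role in enumerate(CANONICAL_ROLE_ORDER)
        ],
    }
    return json.dumps(payload)


def deserialize_graph(text: str) -> LungGraph:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupted graph payload: {exc}") from exc
    if payload.get("schema") != "lunggraph/v1":
        raise ValueError("corrupted graph payload: unknown schema")
    try:
        by_role = {NodeRole(n["role"]): n["feature"] for n in payload["nodes"]}
        if set(by_role) != set(CANONICAL_ROLE_ORDER):
            raise ValueError("corrupted graph payload: wrong role set")
        block = np.array([by_role[r] for r in CANONICAL_ROLE_ORDER], dtype=np.float64)
        if block.shape[1] == 0:
            raise ValueError("corrupted graph payload: empty features")
        edges = [tuple(NodeRole(r) for r in e) for e in payload["edges"]]
        canon = [tuple(sorted(e, key=lambda r: ROLE_INDEX[r])) for e in edges]
        canon.sort(key=lambda e: (ROLE_INDEX[e[0]], ROLE_INDEX[e[1]]))
        return LungGraph(
            edges=canon,
            features=block,
            patient_id=payload.get("patient_id", ""),
            label=payload.get("label"),
            tumor_lobes=[NodeRole(r) for r in payload.get("tumor_lobes", [])],
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"corrupted graph payload: {exc}") from exc


def save_graph(g: LungGraph, path: str | Path) -> None:
    Path(path).write_text(serialize_graph(g))


def load_graph(path: str | Path) -> LungGraph:
    return deserialize_graph(Path(path).read_text())
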