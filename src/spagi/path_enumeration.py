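"""Shortest receptor-to-TF path enumeration and background construction.

For every (receptor, TF) pair one minimum-weight path is kept.  A path is
*complete* when it runs receptor layer(s) -> kinase layer(s) -> TF with 3 to 7
nodes, at most 2 leading receptors and at most 5 kinases.  All complete paths
sharing a root receptor form that receptor's pathway; the collection over all
receptors is the background used downstream.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable

from .ppi_graph import ROLE_KINASE, ROLE_RECEPTOR, ROLE_TF, SignalingGraph

DEFAULT_MAX_NODES = 3, 7  # inclusive node-count bounds of a complete path
DEFAULT_MAX_R_LAYERS = 2
DEFAULT_MAX_K_LAYERS = 5


@dataclass(frozen=True, order=True)
class SignalingPath:
    """An ordered receptor -> ... -> TF node chain with its role labelling."""

    nodes: tuple
    roles: tuple
    total_weight: int

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.roles):
            raise ValueError("nodes and roles must have equal length")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"path is not simple: {self.nodes}")

    @property
    def receptor(self) -> str:
        return self.nodes[0]

    @property
    def terminal_tf(self) -> str:
        return self.nodes[-1]


@dataclass
class PathwayBackground:
    """Complete paths grouped by root receptor (one pathway per receptor)."""

    pathways: dict = field(default_factory=dict)

    @classmethod
    def from_paths(cls, paths: Iterable[SignalingPath]) -> "PathwayBackground":
        grouped: dict = {}
        for p in paths:
            grouped.setdefault(p.receptor, []).append(p)
        out = {}
        for receptor in sorted(grouped):
            ps = sorted(grouped[receptor], key=lambda p: p.nodes)
            tfs = [p.terminal_tf for p in ps]
            if len(set(tfs)) != len(tfs):
                raise ValueError(f"pathway {receptor} has several paths to one TF")
            out[receptor] = tuple(ps)
        return cls(pathways=out)

    def all_paths(self) -> list:
        return [p for r in sorted(self.pathways) for p in self.pathways[r]]

    @property
    def n_paths(self) -> int:
        return sum(len(ps) for ps in self.pathways.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, PathwayBackground):
            return NotImplemented
        return self.pathways == other.pathways


def validate_path(
    path: SignalingPath,
    max_nodes: int = DEFAULT_MAX_NODES[1],
    max_r_layers: int = DEFAULT_MAX_R_LAYERS,
    max_k_layers: int = DEFAULT_MAX_K_LAYERS,
) -> bool:
    """True iff the labelled path is complete: node count in [3, max_nodes],
    a leading receptor run of at most ``max_r_layers``, a middle kinase run of
    1..``max_k_layers`` and exactly one trailing TF."""
    n = len(path.nodes)
    if not DEFAULT_MAX_NODES[0] <= n <= max_nodes:
        return False
    roles = list(path.roles)
    r_run = 0
    while r_run < n and roles[r_run] == ROLE_RECEPTOR:
        r_run += 1
    k_run = 0
    while r_run + k_run < n and roles[r_run + k_run] == ROLE_KINASE:
        k_run += 1
    if r_run + k_run != n - 1 or roles[-1] != ROLE_TF:
        return False
    return 1 <= r_run <= max_r_layers and 1 <= k_run <= max_k_layers


def _label_nodes(
    sgraph: SignalingGraph,
    nodes: tuple,
    max_nodes: int,
    max_r_layers: int,
    max_k_layers: int,
):
    """Find a role labelling R^a K^b TF consistent with node roles and edge
    categories, preferring the smallest receptor run.  Returns None if the
    node chain admits no complete-path labelling."""
    n = len(nodes)
    if not DEFAULT_MAX_NODES[0] <= n <= max_nodes:
        return None
    g = sgraph.graph
    node_roles = [g.nodes[v]["roles"] for v in nodes]
    if ROLE_TF not in node_roles[-1]:
        return None
    for a in range(1, min(max_r_layers, n - 2) + 1):
        b = n - 1 - a
        if not 1 <= b <= max_k_layers:
            continue
        labels = (ROLE_RECEPTOR,) * a + (ROLE_KINASE,) * b + (ROLE_TF,)
        if any(labels[i] not in node_roles[i] for i in range(n)):
            continue
        ok = all(
            (labels[i], labels[i + 1]) in g.edges[nodes[i], nodes[i + 1]]["categories"]
            for i in range(n - 1)
        )
        if ok:
            return labels
    return None


def _lex_dijkstra(graph, source: str) -> dict:
    """Single-source shortest paths with ties broken by lexicographically
    smallest node sequence.  Returns node -> (distance, path tuple)."""
    best: dict = {}
    heap = [(0, (source,))]
    while heap:
        dist, path = heapq.heappop(heap)
        v = path[-1]
        if v in best:
            continue
        best[v] = (dist, path)
        for w in graph[v]:
            if w in best:
                continue
            heapq.heappush(heap, (dist + graph.edges[v, w]["weight"], path + (w,)))
    return best


def _strict_layered_paths(
    sgraph: SignalingGraph,
    receptor: str,
    max_nodes: int,
    max_r_layers: int,
    max_k_layers: int,
) -> dict:
    """Cheapest constraint-satisfying labelled path to every reachable TF,
    by depth-bounded search over role-layered states (depth <= max_nodes
    keeps this tractable).  Returns tf -> (weight, nodes, roles)."""
    g = sgraph.graph
    best: dict = {}

    def record(weight, nodes, roles):
        tf = nodes[-1]
        key = (weight, nodes)
        if tf not in best or key < (best[tf][0], best[tf][1]):
            best[tf] = (weight, nodes, roles)

    def expand(node, role, r_cnt, k_cnt, weight, nodes, roles, onpath):
        if len(nodes) >= max_nodes:
            return
        for nxt in g[node]:
            if nxt in onpath:
                continue
            cats = g.edges[node, nxt]["categories"]
            if role == ROLE_RECEPTOR:
                # kinase branch first so equal-key duplicates keep the
                # smallest-receptor-run labelling (matches _label_nodes)
                if (ROLE_RECEPTOR, ROLE_KINASE) in cats:
                    expand(
                        nxt, ROLE_KINASE, r_cnt, 1,
                        weight + g.edges[node, nxt]["weight"],
                        nodes + (nxt,), roles + (ROLE_KINASE,), onpath | {nxt},
                    )
                if (ROLE_RECEPTOR, ROLE_RECEPTOR) in cats and r_cnt < max_r_layers:
                    expand(
                        nxt, ROLE_RECEPTOR, r_cnt + 1, 0,
                        weight + g.edges[node, nxt]["weight"],
                        nodes + (nxt,), roles + (ROLE_RECEPTOR,), onpath | {nxt},
                    )
            elif role == ROLE_KINASE:
                if (ROLE_KINASE, ROLE_TF) in cats and len(nodes) + 1 <= max_nodes:
                    record(
                        weight + g.edges[node, nxt]["weight"],
                        nodes + (nxt,), roles + (ROLE_TF,),
                    )
                if (ROLE_KINASE, ROLE_KINASE) in cats and k_cnt < max_k_layers:
                    expand(
                        nxt, ROLE_KINASE, r_cnt, k_cnt + 1,
                        weight + g.edges[node, nxt]["weight"],
                        nodes + (nxt,), roles + (ROLE_KINASE,), onpath | {nxt},
                    )

    expand(receptor, ROLE_RECEPTOR, 1, 0, 0, (receptor,), (ROLE_RECEPTOR,), {receptor})
    return best


def shortest_rk_tf_paths(
    sgraph: SignalingGraph,
    max_nodes: int = DEFAULT_MAX_NODES[1],
    max_r_layers: int = DEFAULT_MAX_R_LAYERS,
    max_k_layers: int = DEFAULT_MAX_K_LAYERS,
    strict_layered: bool = False,
) -> PathwayBackground:
    """Background of one minimum-weight complete path per (receptor, TF) pair.

    Default mode mirrors the two-step procedure: run plain weighted
    shortest-path search (Dijkstra, lexicographic tie-break), then keep the
    paths that admit a complete labelling; pairs whose globally shortest path
    is not complete are dropped.  With ``strict_layered=True`` the search is
    performed over role-layered states so the returned path is the cheapest
    *complete* path for the pair, if any exists.
    """
    paths = []
    for receptor in sgraph.receptors:
        if strict_layered:
            found = _strict_layered_paths(
                sgraph, receptor, max_nodes, max_r_layers, max_k_layers
            )
            for tf in sorted(found):
                weight, nodes, roles = found[tf]
                paths.append(SignalingPath(nodes=nodes, roles=roles, total_weight=weight))
        else:
            best = _lex_dijkstra(sgraph.graph, receptor)
            for target in sorted(best):
                if target == receptor:
                    continue
                if ROLE_TF not in sgraph.roles_of(target):
                    continue
                dist, nodes = best[target]
                roles = _label_nodes(sgraph, nodes, max_nodes, max_r_layers, max_k_layers)
                if roles is None:
                    continue
                paths.append(SignalingPath(nodes=nodes, roles=roles, total_weight=dist))
    return PathwayBackground.from_paths(paths)


def remove_housekeeping_paths(
    background: PathwayBackground, hk: Iterable
) -> PathwayBackground:
    """Drop paths whose members are *all* housekeeping genes; receptors left
    without paths are removed."""
    hk = {s.upper() for s in hk}
    kept = {}
    for receptor, ps in background.pathways.items():
        survivors = tuple(p for p in ps if not set(p.nodes) <= hk)
        if survivors:
            kept[receptor] = survivors
    return PathwayBackground(pathways=kept)
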