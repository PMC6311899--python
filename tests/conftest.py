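"""Shared fixtures: the toy network T1, the query profile E1, random
role-labelled graphs, and the planted-signal benchmark spec."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from spagi.activity_scoring import ExpressionProfile
from spagi.path_enumeration import shortest_rk_tf_paths
from spagi.ppi_graph import (
    Interaction,
    build_signaling_graph,
    filter_interactions,
    load_molecule_roles,
)
from spagi.synthetic_data import SyntheticSpec, generate_network

T1_INTERACTIONS = [
    ("R2", "R1", 720),
    ("R1", "K1", 900),
    ("K1", "K2", 750),
    ("K1", "TF1", 800),
    ("K2", "TF2", 900),
]


@pytest.fixture
def t1_roles():
    return load_molecule_roles(["R1", "R2"], ["K1", "K2"], ["TF1", "TF2"])


@pytest.fixture
def t1_graph(t1_roles):
    interactions = [Interaction(a, b, s) for a, b, s in T1_INTERACTIONS]
    return build_signaling_graph(interactions, t1_roles)


@pytest.fixture
def t1_background(t1_graph):
    return shortest_rk_tf_paths(t1_graph)


@pytest.fixture
def e1_profile():
    return ExpressionProfile(
        values={"R1": 5, "K1": 4, "K2": 2, "TF1": 6, "TF2": 1.0, "R2": 0.5},
        cutoff=1.5,
    )


def small_random_graph(seed: int):
    """A random role-labelled signaling graph with at most 30 nodes."""
    spec = SyntheticSpec(
        n_receptors=4,
        n_kinases=8,
        n_tfs=5,
        edge_density={"rr": 0.25, "rk": 0.25, "kk": 0.25, "ktf": 0.3},
        score_range=(700, 999),
        seed=seed,
    )
    interactions, roles = generate_network(spec)
    return build_signaling_graph(filter_interactions(interactions, 700), roles)


def planted_spec(seed: int, gap_sd: float = 4.0) -> SyntheticSpec:
    """Benchmark spec: 20 receptors, 40 kinases, 30 TFs, 3 planted receptors
    each wired to 5 routes, active mean ``gap_sd`` noise SDs above the
    expressed mean."""
    sd = 0.4
    return SyntheticSpec(
        n_receptors=20,
        n_kinases=40,
        n_tfs=30,
        planted_receptors=("R001", "R002", "R003"),
        n_planted_routes=5,
        noise_sd=sd,
        expressed_mean=3.0,
        active_mean=3.0 + gap_sd * sd,
        silent_mean=0.3,
        expressed_fraction=0.35,
        edge_density={"rr": 0.015, "rk": 0.025, "kk": 0.03, "ktf": 0.04},
        seed=seed,
    )


PLANTED_HIGH_THRESHOLD = 3.0 + 2 * 0.4  # two noise SDs above the expressed mean


# ---------------------------------------------------------------------------
# independent brute-force oracle for complete shortest paths
# ---------------------------------------------------------------------------

def _oracle_labelings(graph: nx.DiGraph, nodes, max_nodes=7, max_r=2, max_k=5):
    """All (r_run, k_run) splits under which the node chain is a complete
    path, checked directly against node roles and edge categories."""
    n = len(nodes)
    if n < 3 or n > max_nodes:
        return []
    out = []
    for r_run in range(1, max_r + 1):
        k_run = n - 1 - r_run
        if not 1 <= k_run <= max_k:
            continue
        labels = ["R"] * r_run + ["K"] * k_run + ["TF"]
        if any(labels[i] not in graph.nodes[nodes[i]]["roles"] for i in range(n)):
            continue
        if all(
            (labels[i], labels[i + 1])
            in graph.edges[nodes[i], nodes[i + 1]]["categories"]
            for i in range(n - 1)
        ):
            out.append(tuple(labels))
    return out


def oracle_background(sgraph, max_nodes=7, max_r=2, max_k=5) -> dict:
    """(receptor, tf) -> (weight, nodes, roles) for the lexicographically
    first minimum-weight complete simple path, by exhaustive enumeration."""
    g = sgraph.graph
    receptors = sgraph.receptors
    tfs = sgraph.tfs
    best = {}
    for r, t in itertools.product(receptors, tfs):
        if r == t or not g.has_node(r) or not g.has_node(t):
            continue
        candidates = []
        for nodes in nx.all_simple_paths(g, r, t, cutoff=max_nodes - 1):
            nodes = tuple(nodes)
            labelings = _oracle_labelings(g, nodes, max_nodes, max_r, max_k)
            if not labelings:
                continue
            weight = sum(
                g.edges[nodes[i], nodes[i + 1]]["weight"] for i in range(len(nodes) - 1)
            )
            candidates.append((weight, nodes, labelings[0]))
        if candidates:
            best[(r, t)] = min(candidates, key=lambda c: (c[0], c[1]))
    return best
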