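"""Role-constrained signaling graph construction from scored protein interactions.

The graph connects receptors (R), kinases (K) and transcription factors (TF)
with directed, weighted edges.  Only four edge categories are permitted:

* ``R -> R`` from a receptor with no direct kinase contact to one that has it,
* ``R -> K``,
* ``K -> K`` in both directions,
* ``K -> TF``.

Edge weights are ``1000 - combined_score`` so that higher-confidence
interactions are cheaper to traverse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

ROLE_RECEPTOR = "R"
ROLE_KINASE = "K"
ROLE_TF = "TF"

#: permitted (source role, target role) categories
EDGE_CATEGORIES = frozenset(
    {
        (ROLE_RECEPTOR, ROLE_RECEPTOR),
        (ROLE_RECEPTOR, ROLE_KINASE),
        (ROLE_KINASE, ROLE_KINASE),
        (ROLE_KINASE, ROLE_TF),
    }
)

_ROLE_NAMES = {"receptor": "receptor", "kinase": "kinase", "tf": "transcription factor"}


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass(frozen=True)
class MoleculeRoles:
    """Assignment of gene symbols to the R / K / TF roles.

    A symbol may carry several roles simultaneously (curated role lists
    overlap); all symbols are stored uppercase.
    """

    receptors: frozenset
    kinases: frozenset
    tfs: frozenset

    def __post_init__(self) -> None:
        for name, members in (
            ("receptor", self.receptors),
            ("kinase", self.kinases),
            ("tf", self.tfs),
        ):
            for sym in members:
                if not isinstance(sym, str) or not sym:
                    raise ValueError(f"{_ROLE_NAMES[name]} set contains a non-symbol entry: {sym!r}")
        if not (self.receptors | self.kinases | self.tfs):
            raise ValueError("all role sets are empty")

    @property
    def all_symbols(self) -> frozenset:
        return self.receptors | self.kinases | self.tfs

    def roles_of(self, symbol: str) -> frozenset:
        roles = set()
        if symbol in self.receptors:
            roles.add(ROLE_RECEPTOR)
        if symbol in self.kinases:
            roles.add(ROLE_KINASE)
        if symbol in self.tfs:
            roles.add(ROLE_TF)
        return frozenset(roles)


@dataclass(frozen=True, order=True)
class Interaction:
    """An undirected scored interaction between two distinct symbols."""

    a: str
    b: str
    combined_score: int

    def __post_init__(self) -> None:
        a = _normalize(self.a)
        b = _normalize(self.b)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        if not a or not b:
            raise ValueError("interaction endpoint symbol is empty")
        if a == b:
            raise ValueError(f"self-interaction rejected: {a}")
        score = self.combined_score
        if not isinstance(score, int) or isinstance(score, bool):
            raise ValueError(f"combined_score must be an integer, got {score!r}")
        if not 1 <= score <= 999:
            raise ValueError(f"combined_score {score} outside [1, 999] for pair ({a}, {b})")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class SignalingGraph:
    """Directed weighted graph over role-labelled nodes.

    ``graph`` is a :class:`networkx.DiGraph` whose nodes carry a ``roles``
    frozenset attribute and whose edges carry integer ``weight`` (in
    ``[1, 999]``) and a ``categories`` frozenset of permitted
    (source role, target role) pairs justifying the edge.
    ``n_discarded`` counts input interactions that produced no edge.
    """

    graph: nx.DiGraph
    n_discarded: int = 0

    def roles_of(self, node: str) -> frozenset:
        return self.graph.nodes[node]["roles"]

    def nodes_with_role(self, role: str) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if role in d["roles"])

    @property
    def receptors(self) -> list:
        return self.nodes_with_role(ROLE_RECEPTOR)

    @property
    def tfs(self) -> list:
        return self.nodes_with_role(ROLE_TF)

    def __eq__(self, other) -> bool:  # structural equality, used by tests
        if not isinstance(other, SignalingGraph):
            return NotImplemented
        if self.n_discarded != other.n_discarded:
            return False
        g, h = self.graph, other.graph
        if set(g.nodes) != set(h.nodes):
            return False
        if any(g.nodes[n]["roles"] != h.nodes[n]["roles"] for n in g.nodes):
            return False
        if set(g.edges) != set(h.edges):
            return False
        return all(
            g.edges[e]["weight"] == h.edges[e]["weight"]
            and g.edges[e]["categories"] == h.edges[e]["categories"]
            for e in g.edges
        )


def _clean_symbol_list(entries: Iterable, role_name: str) -> frozenset:
    cleaned = set()
    for lineno, entry in enumerate(entries, start=1):
        if not isinstance(entry, str):
            raise ValueError(
                f"{role_name} list line {lineno}: expected a gene symbol, got {entry!r}"
            )
        sym = _normalize(entry)
        if sym:
            cleaned.add(sym)
    if not cleaned:
        raise ValueError(f"{role_name} list empty")
    return frozenset(cleaned)


def load_molecule_roles(
    receptor_list: Iterable,
    kinase_list: Iterable,
    tf_list: Iterable,
) -> MoleculeRoles:
    """Build :class:`MoleculeRoles` from three raw symbol lists.

    Symbols are uppercased and deduplicated; blank entries are dropped.
    An empty list (after cleaning) raises ``ValueError`` naming the role.
    """
    return MoleculeRoles(
        receptors=_clean_symbol_list(receptor_list, "receptor"),
        kinases=_clean_symbol_list(kinase_list, "kinase"),
        tfs=_clean_symbol_list(tf_list, "transcription factor"),
    )


def filter_interactions(
    interactions: Sequence[Interaction], min_score: int = 700
) -> list:
    """Keep high-confidence interactions (``combined_score >= min_score``).

    Duplicates of the same unordered pair are collapsed to the maximum
    score; the first-seen orientation and position are kept.
    """
    if not 1 <= min_score <= 999:
        raise ValueError(f"min_score {min_score} outside [1, 999]")
    best: dict = {}
    order: list = []
    for it in interactions:
        if it.combined_score < min_score:
            continue
        key = it.pair
        if key not in best:
            best[key] = it
            order.append(key)
        elif it.combined_score > best[key].combined_score:
            prev = best[key]
            best[key] = Interaction(prev.a, prev.b, it.combined_score)
    return [best[k] for k in order]


def _check_one_to_one(mapping: Mapping) -> dict:
    out = {}
    seen_targets: dict = {}
    for src, dst in mapping.items():
        s, d = _normalize(src), _normalize(dst)
        if s in out:
            raise ValueError(f"mapping not one-to-one: {s} mapped twice")
        if d in seen_targets:
            raise ValueError(f"mapping not one-to-one: {d} is the target of both "
                             f"{seen_targets[d]} and {s}")
        out[s] = d
        seen_targets[d] = s
    return out


def merge_species(
    interactions_a: Sequence[Interaction],
    interactions_b: Sequence[Interaction],
    ortholog_map: Mapping | None = None,
) -> list:
    """Union two interaction sets on a shared namespace, keeping the larger
    score for pairs present in both.

    ``ortholog_map`` maps symbols of the second set onto the namespace of the
    first and must be one-to-one; without it symbols are matched by identity.
    Symbols absent from the map pass through unchanged.  The result is in a
    canonical sorted order, so the operation is symmetric in its inputs.
    """
    translate = _check_one_to_one(ortholog_map) if ortholog_map else {}

    def canonical(it: Interaction) -> Interaction:
        a, b = sorted((it.a, it.b))
        return Interaction(a, b, it.combined_score)

    best: dict = {}
    for it in interactions_a:
        it = canonical(it)
        prev = best.get(it.pair)
        if prev is None or it.combined_score > prev.combined_score:
            best[it.pair] = it
    for it in interactions_b:
        a = translate.get(it.a, it.a)
        b = translate.get(it.b, it.b)
        it = canonical(Interaction(a, b, it.combined_score))
        prev = best.get(it.pair)
        if prev is None or it.combined_score > prev.combined_score:
            best[it.pair] = it
    return sorted(best.values())


def _directed_categories(
    source: str,
    target: str,
    roles: MoleculeRoles,
    k_connected_receptors: frozenset,
) -> frozenset:
    """Permitted (source role, target role) categories for the directed pair."""
    cats = set()
    src_roles = roles.roles_of(source)
    dst_roles = roles.roles_of(target)
    if ROLE_KINASE in src_roles and ROLE_KINASE in dst_roles:
        cats.add((ROLE_KINASE, ROLE_KINASE))
    if ROLE_RECEPTOR in src_roles and ROLE_KINASE in dst_roles:
        cats.add((ROLE_RECEPTOR, ROLE_KINASE))
    if ROLE_KINASE in src_roles and ROLE_TF in dst_roles:
        cats.add((ROLE_KINASE, ROLE_TF))
    if (
        ROLE_RECEPTOR in src_roles
        and ROLE_RECEPTOR in dst_roles
        and source not in k_connected_receptors
        and target in k_connected_receptors
    ):
        cats.add((ROLE_RECEPTOR, ROLE_RECEPTOR))
    return frozenset(cats)


def build_signaling_graph(
    interactions: Sequence[Interaction], roles: MoleculeRoles
) -> SignalingGraph:
    """Turn confidence-filtered interactions into the directed signaling graph.

    For every undirected interaction each directed orientation is emitted if
    at least one permitted category applies; the edge weight is
    ``1000 - combined_score``.  An R->R edge is only emitted from a receptor
    with no interaction partner in the kinase set towards a receptor that has
    one (a node's own kinase role does not make it kinase-connected).
    Interactions admitting no category are counted in ``n_discarded``.
    """
    # receptors that have a direct interaction partner in the kinase set
    k_connected = set()
    for it in interactions:
        if it.a in roles.receptors and it.b in roles.kinases and it.b != it.a:
            k_connected.add(it.a)
        if it.b in roles.receptors and it.a in roles.kinases and it.a != it.b:
            k_connected.add(it.b)
    k_connected = frozenset(k_connected)

    g = nx.DiGraph()
    n_discarded = 0
    for it in interactions:
        weight = 1000 - it.combined_score
        emitted = False
        for u, v in ((it.a, it.b), (it.b, it.a)):
            cats = _directed_categories(u, v, roles, k_connected)
            if not cats:
                continue
            emitted = True
            if g.has_edge(u, v):
                data = g.edges[u, v]
                data["weight"] = min(data["weight"], weight)
                data["categories"] = data["categories"] | cats
            else:
                g.add_edge(u, v, weight=weight, categories=cats)
        if not emitted:
            n_discarded += 1
    for node in g.nodes:
        g.nodes[node]["roles"] = roles.roles_of(node)
    return SignalingGraph(graph=g, n_discarded=n_discarded)
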