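"""Readers for the plain-text formats used across the pipeline.

All inputs are UTF-8 text, tab- or whitespace-separated, with ``#`` comment
lines ignored where noted; Windows line endings are accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ..housekeeping import ExpressionPanel, HousekeepingSet
from ..path_enumeration import PathwayBackground, SignalingPath
from ..ppi_graph import Interaction, SignalingGraph, _check_one_to_one

import networkx as nx


def _lines(path) -> list:
    text = Path(path).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").split("\n")


def read_gene_list(path) -> list:
    """One symbol per line; blanks and ``#`` comments skipped; empty file is
    an error."""
    symbols = []
    for line in _lines(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(line.upper())
    if not symbols:
        raise ValueError(f"gene list {path} is empty")
    return symbols


def read_ppi_tsv(path) -> list:
    """Three columns ``protein1 protein2 combined_score``; an optional header
    line is auto-detected (non-integer third field on the first data line)."""
    interactions = []
    header_allowed = True
    for lineno, line in enumerate(_lines(path), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 3:
            raise ValueError(f"{path} line {lineno}: expected 3 columns, got {len(fields)}")
        if header_allowed:
            header_allowed = False
            try:
                int(fields[2])
            except ValueError:
                continue  # header line
        try:
            score = int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: non-integer score {fields[2]!r}") from exc
        try:
            interactions.append(Interaction(fields[0], fields[1], score))
        except ValueError as exc:
            raise ValueError(f"{path} line {lineno}: {exc}") from exc
    if not interactions:
        raise ValueError(f"PPI file {path} contains no interactions")
    return interactions


def read_ortholog_map(path) -> dict:
    """Two-column TSV ``symbol_a symbol_b``; returns the b->a translation and
    enforces one-to-one-ness."""
    mapping = {}
    for lineno, line in enumerate(_lines(path), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) != 2:
            raise ValueError(f"{path} line {lineno}: expected 2 columns")
        a, b = fields[0].upper(), fields[1].upper()
        if b in mapping:
            raise ValueError(f"mapping not one-to-one: {b} mapped twice ({path} line {lineno})")
        mapping[b] = a
    _check_one_to_one(mapping)
    return mapping


def read_expression_tsv(path) -> pd.DataFrame:
    """Genes x samples matrix; header row of sample ids required, first
    column gene symbols.  Duplicate symbols and non-numeric cells are
    reported with their location."""
    rows = [ln for ln in _lines(path) if ln.strip() and not ln.lstrip().startswith("#")]
    if len(rows) < 2:
        raise ValueError(f"expression file {path} needs a header and at least one gene row")
    header = rows[0].rstrip("\n").split("\t")
    samples = header[1:]
    if not samples:
        raise ValueError(f"expression file {path} has no sample columns")
    genes, data = [], []
    seen = set()
    for lineno, line in enumerate(rows[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ValueError(
                f"{path} line {lineno}: expected {len(samples) + 1} columns, got {len(fields)}"
            )
        gene = fields[0].strip().upper()
        if gene in seen:
            raise ValueError(f"{path}: duplicate gene symbol {gene}")
        seen.add(gene)
        values = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                v = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path} line {lineno} column {col}: non-numeric value {cell!r}"
                ) from exc
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{path} line {lineno} column {col}: non-finite value")
            values.append(v)
        genes.append(gene)
        data.append(values)
    return pd.DataFrame(data, index=genes, columns=samples)


def read_panel_tsv(path) -> ExpressionPanel:
    return ExpressionPanel(values=read_expression_tsv(path))


def read_groups(spec: str | None, path=None) -> dict:
    """Replicate grouping either as ``sample=condition,...`` or a two-column
    TSV ``sample<TAB>condition``."""
    groups = {}
    if path is not None:
        for lineno, line in enumerate(_lines(path), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 2:
                raise ValueError(f"{path} line {lineno}: expected 2 columns")
            groups[fields[0]] = fields[1]
    elif spec:
        for item in spec.split(","):
            if "=" not in item:
                raise ValueError(f"bad group assignment {item!r} (want sample=condition)")
            sample, condition = item.split("=", 1)
            groups[sample.strip()] = condition.strip()
    return groups


def read_housekeeping(path) -> HousekeepingSet:
    """One symbol per line, or two columns ``symbol prevalence``."""
    genes, prevalence = set(), {}
    for lineno, line in enumerate(_lines(path), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        sym = fields[0].upper()
        genes.add(sym)
        if len(fields) > 1:
            prevalence[sym] = float(fields[1])
    return HousekeepingSet(genes=frozenset(genes), prevalence=prevalence)


def read_graph_json(path) -> SignalingGraph:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    g = nx.DiGraph()
    for node, roles in payload["nodes"].items():
        g.add_node(node, roles=frozenset(roles))
    for source, target, weight, categories in payload["edges"]:
        g.add_edge(
            source,
            target,
            weight=int(weight),
            categories=frozenset(tuple(c) for c in categories),
        )
    return SignalingGraph(graph=g, n_discarded=int(payload.get("n_discarded", 0)))


def _path_from_fields(nodes_field: str, weight_field: str, roles_field: str | None):
    nodes = tuple(nodes_field.split(">"))
    if roles_field:
        roles = tuple(roles_field.split(">"))
    else:
        # legacy 4-column rows: assume the canonical single-receptor labelling
        roles = ("R",) + ("K",) * (len(nodes) - 2) + ("TF",)
    return SignalingPath(nodes=nodes, roles=roles, total_weight=int(weight_field))


def read_background_tsv(path) -> PathwayBackground:
    paths = []
    for lineno, line in enumerate(_lines(path), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if fields[0] == "receptor":  # header
            continue
        if len(fields) not in (4, 5):
            raise ValueError(f"{path} line {lineno}: expected 4 or 5 columns")
        receptor, nodes_field, weight_field, terminal = fields[:4]
        roles_field = fields[4] if len(fields) == 5 else None
        p = _path_from_fields(nodes_field, weight_field, roles_field)
        if p.receptor != receptor or p.terminal_tf != terminal:
            raise ValueError(f"{path} line {lineno}: inconsistent path endpoints")
        paths.append(p)
    return PathwayBackground.from_paths(paths)


def read_background_json(path) -> PathwayBackground:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    paths = [
        SignalingPath(
            nodes=tuple(entry["nodes"]),
            roles=tuple(entry["roles"]),
            total_weight=int(entry["total_weight"]),
        )
        for entry in payload["paths"]
    ]
    return PathwayBackground.from_paths(paths)
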