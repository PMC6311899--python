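"""Writers mirroring the readers; every reader/writer pair round-trips."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ..activity_scoring import PathwayActivity, activity_table
from ..housekeeping import ExpressionPanel, HousekeepingSet
from ..path_enumeration import PathwayBackground
from ..permutation_fpr import FPRResult
from ..ppi_graph import Interaction, SignalingGraph


def write_gene_list(symbols: Iterable, path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in symbols), encoding="utf-8")


def write_ppi_tsv(interactions: Sequence[Interaction], path, header: bool = True) -> None:
    lines = ["protein1\tprotein2\tcombined_score"] if header else []
    lines += [f"{it.a}\t{it.b}\t{it.combined_score}" for it in interactions]
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def write_panel_tsv(panel: ExpressionPanel, path) -> None:
    write_expression_tsv(panel.values, path)


def write_housekeeping(
    hk: HousekeepingSet, path, with_prevalence: bool = False
) -> None:
    lines = []
    for gene in sorted(hk.genes):
        if with_prevalence:
            lines.append(f"{gene}\t{hk.prevalence.get(gene, 0.0):.6g}")
        else:
            lines.append(gene)
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")


def write_graph_json(sgraph: SignalingGraph, path) -> None:
    g = sgraph.graph
    payload = {
        "nodes": {n: sorted(g.nodes[n]["roles"]) for n in sorted(g.nodes)},
        "edges": [
            [u, v, g.edges[u, v]["weight"], sorted(map(list, g.edges[u, v]["categories"]))]
            for u, v in sorted(g.edges)
        ],
        "n_discarded": sgraph.n_discarded,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def write_background_tsv(background: PathwayBackground, path) -> None:
    """Columns: receptor, ``>``-joined path, total weight, terminal TF and
    the ``>``-joined role labelling (the extra column keeps the file
    self-contained for round-tripping)."""
    lines = ["receptor\tpath\ttotal_weight\tterminal_tf\troles"]
    for p in background.all_paths():
        lines.append(
            f"{p.receptor}\t{'>'.join(p.nodes)}\t{p.total_weight}\t"
            f"{p.terminal_tf}\t{'>'.join(p.roles)}"
        )
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")


def write_background_json(background: PathwayBackground, path) -> None:
    payload = {
        "paths": [
            {
                "nodes": list(p.nodes),
                "roles": list(p.roles),
                "total_weight": p.total_weight,
            }
            for p in background.all_paths()
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def write_ranked_tsv(activities: Sequence[PathwayActivity], path) -> None:
    table = activity_table(activities)
    lines = ["receptor\tn\tactivity_score"]
    for receptor, row in table.iterrows():
        lines.append(f"{receptor}\t{int(row['n'])}\t{row['activity_score']:.10g}")
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")


def write_path_detail_tsv(activities: Sequence[PathwayActivity], path) -> None:
    lines = ["receptor\tpath\tp_i"]
    for act in activities:
        for p, prop in zip(act.paths, act.proportions):
            lines.append(f"{act.receptor}\t{'>'.join(p.nodes)}\t{prop:.10g}")
    Path(path).write_text("".join(f"{ln}\n" for ln in lines), encoding="utf-8")


def write_fpr_json(result: FPRResult, path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=1) + "\n", encoding="utf-8")
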