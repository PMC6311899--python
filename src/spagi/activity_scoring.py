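"""Pathway activity scoring against a query expression profile.

The background is reduced to *potential* paths (every member expressed at or
above the cutoff), each path gets an active-molecule proportion ``p_i``
(fraction of members at or above the high-expression threshold), and every
pathway is scored ``A_s = sum(p_i) / n`` where ``n`` is its number of
retained paths — equal, by construction, to its number of downstream TFs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .housekeeping import DEFAULT_EXPRESSION_CUTOFF
from .path_enumeration import PathwayBackground

KDE_GRID_POINTS = 512
MIN_EXPRESSED_FOR_KDE = 10


@dataclass
class ExpressionProfile:
    """Averaged log-scale expression values for one condition."""

    values: dict
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF
    high_threshold: float | None = None

    def __post_init__(self) -> None:
        clean = {}
        for gene, value in self.values.items():
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"invalid expression value for {gene}: {value}")
            clean[str(gene).strip().upper()] = v
        self.values = clean
        if self.high_threshold is not None and self.high_threshold < self.cutoff:
            raise ValueError("high_threshold must be >= cutoff")

    def is_expressed(self, gene: str) -> bool:
        return self.values.get(gene, -np.inf) >= self.cutoff

    def expressed_values(self) -> np.ndarray:
        arr = np.array(sorted(self.values.values()), dtype=float)
        return arr[arr >= self.cutoff]


@dataclass(frozen=True)
class PathwayActivity:
    """Per-pathway activity record: root receptor, TF count n, per-path
    active proportions p_i and the activity score A_s."""

    receptor: str
    n: int
    proportions: tuple
    activity_score: float
    paths: tuple = ()


def average_replicates(
    matrix: pd.DataFrame,
    groups: Mapping,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
) -> dict:
    """Collapse replicate columns to one profile per condition (per-gene
    arithmetic mean).  Every column must appear in ``groups``."""
    for sample in matrix.columns:
        if sample not in groups:
            raise ValueError(f"sample {sample!r} missing from replicate grouping")
    conditions: dict = {}
    for sample, condition in groups.items():
        if sample in matrix.columns:
            conditions.setdefault(condition, []).append(sample)
    out = {}
    for condition in sorted(conditions):
        cols = conditions[condition]
        means = matrix[cols].mean(axis=1)
        out[condition] = ExpressionProfile(
            values={g: float(v) for g, v in means.items()}, cutoff=cutoff
        )
    return out


def filter_potential_paths(
    background: PathwayBackground, profile: ExpressionProfile
) -> PathwayBackground:
    """Keep only paths whose every member is expressed in the profile; genes
    absent from the profile count as not expressed."""
    kept = {}
    for receptor, paths in background.pathways.items():
        survivors = tuple(
            p for p in paths if all(profile.is_expressed(node) for node in p.nodes)
        )
        if survivors:
            kept[receptor] = survivors
    return PathwayBackground(pathways=kept)


def default_high_threshold(profile: ExpressionProfile) -> float:
    """Peak of the expression distribution of expressed genes, located as the
    mode of a Gaussian KDE evaluated on a 512-point grid over the observed
    range.  Callers may always override with an explicit number."""
    values = profile.expressed_values()
    if values.size < MIN_EXPRESSED_FOR_KDE:
        raise ValueError(
            f"only {values.size} expressed genes (need >= {MIN_EXPRESSED_FOR_KDE}); "
            "pass an explicit high threshold"
        )
    lo, hi = float(values.min()), float(values.max())
    if np.allclose(values, values[0]):
        return float(values[0])
    kde = gaussian_kde(values)
    grid = np.linspace(lo, hi, KDE_GRID_POINTS)
    return float(grid[int(np.argmax(kde(grid)))])


def pathway_activity(
    potential: PathwayBackground,
    profile: ExpressionProfile,
    high_threshold: float,
) -> list:
    """Score every pathway of an already-filtered background.

    ``p_i`` is the fraction of path members at or above ``high_threshold``;
    ``A_s`` is the mean of the ``p_i`` over the pathway's ``n`` paths.
    """
    activities = []
    for receptor in sorted(potential.pathways):
        paths = potential.pathways[receptor]
        proportions = tuple(
            sum(profile.values.get(node, -np.inf) >= high_threshold for node in p.nodes)
            / len(p.nodes)
            for p in paths
        )
        n = len(paths)
        assert n == len({p.terminal_tf for p in paths}), "one path per TF violated"
        activities.append(
            PathwayActivity(
                receptor=receptor,
                n=n,
                proportions=proportions,
                activity_score=sum(proportions) / n,
                paths=paths,
            )
        )
    return activities


def rank_pathways(activities: Sequence[PathwayActivity]) -> list:
    """Sort by activity score descending, ties by n descending, then by
    receptor symbol ascending."""
    return sorted(
        activities, key=lambda a: (-a.activity_score, -a.n, a.receptor)
    )


def activity_table(activities: Sequence[PathwayActivity]) -> pd.DataFrame:
    """(n, A_s) table keyed by receptor, in ranked order, for plotting."""
    ranked = rank_pathways(activities)
    return pd.DataFrame(
        {
            "receptor": [a.receptor for a in ranked],
            "n": [a.n for a in ranked],
            "activity_score": [a.activity_score for a in ranked],
        }
    ).set_index("receptor")


def select_high_ranked(
    activities: Sequence[PathwayActivity],
    score_quantile: float = 0.75,
    min_tfs: int = 5,
) -> list:
    """Pathways with A_s at or above the ``score_quantile`` quantile of all
    A_s values and at least ``min_tfs`` downstream TFs."""
    if not 0 < score_quantile < 1:
        raise ValueError(f"score_quantile {score_quantile} outside (0, 1)")
    if not activities:
        return []
    scores = np.array([a.activity_score for a in activities], dtype=float)
    threshold = float(np.quantile(scores, score_quantile))
    return [
        a
        for a in rank_pathways(activities)
        if a.activity_score >= threshold and a.n >= min_tfs
    ]


def plot_activity(activities: Sequence[PathwayActivity], path: str) -> None:
    """Scatter of n versus A_s, one point per pathway, saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = activity_table(activities)
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(table["n"], table["activity_score"], s=18, alpha=0.7)
    for receptor, row in table.head(10).iterrows():
        ax.annotate(receptor, (row["n"], row["activity_score"]), fontsize=7)
    ax.set_xlabel("number of downstream TFs (n)")
    ax.set_ylabel("activity score (A_s)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
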