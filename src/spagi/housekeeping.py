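"""Housekeeping gene identification from a multi-tissue expression panel.

A gene is housekeeping when it is expressed (``value >= cutoff``, default 1.5
on a log2(FPKM+1) scale) in at least a given fraction (default 75%) of the
panel samples.  Per-species sets are combined by union under a one-to-one
ortholog mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .ppi_graph import _check_one_to_one

DEFAULT_EXPRESSION_CUTOFF = 1.5
DEFAULT_PREVALENCE = 0.75


@dataclass
class ExpressionPanel:
    """Genes x samples matrix of non-negative log-scale expression values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        df = df.copy()
        df.index = [str(g).strip().upper() for g in df.index]
        if len(set(df.index)) != len(df.index):
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol in panel: {dup}")
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("panel contains non-finite values")
        if (arr < 0).any():
            raise ValueError("panel contains negative values")
        self.values = df

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class HousekeepingSet:
    """Housekeeping symbols with the prevalence fraction that earned each one."""

    genes: frozenset
    prevalence: dict = field(default_factory=dict)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes


def expressed_in_sample(
    panel: ExpressionPanel, sample: str, cutoff: float = DEFAULT_EXPRESSION_CUTOFF
) -> set:
    """Genes whose value in ``sample`` meets or exceeds ``cutoff``."""
    if sample not in panel.values.columns:
        raise KeyError(f"unknown sample id: {sample}")
    col = panel.values[sample]
    return set(col.index[col >= cutoff])


def identify_housekeeping(
    panel: ExpressionPanel,
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF,
    prevalence: float = DEFAULT_PREVALENCE,
) -> HousekeepingSet:
    """Genes expressed in at least ``prevalence`` of the panel samples."""
    if not 0 < prevalence <= 1:
        raise ValueError(f"prevalence {prevalence} outside (0, 1]")
    if panel.n_samples < 2:
        raise ValueError("panel must have at least 2 samples")
    frac = (panel.values >= cutoff).sum(axis=1) / panel.n_samples
    members = frac[frac >= prevalence]
    return HousekeepingSet(
        genes=frozenset(members.index),
        prevalence={g: float(members[g]) for g in members.index},
    )


def combine_housekeeping(
    set_a: HousekeepingSet,
    set_b: HousekeepingSet,
    ortholog_map: Mapping | None = None,
) -> HousekeepingSet:
    """Union of two housekeeping sets on a shared namespace; provenance keeps
    the maximum prevalence seen for each symbol."""
    translate = _check_one_to_one(ortholog_map) if ortholog_map else {}
    prevalence: dict = dict(set_a.prevalence)
    genes = set(set_a.genes)
    for g in set_b.genes:
        mapped = translate.get(g, g)
        genes.add(mapped)
        p = set_b.prevalence.get(g, 0.0)
        prevalence[mapped] = max(prevalence.get(mapped, 0.0), p)
    return HousekeepingSet(genes=frozenset(genes), prevalence=prevalence)
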