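"""Synthetic role-labelled networks, expression panels and query profiles.

Stands in for the external PPI / tissue-panel / RNA-seq inputs so the whole
pipeline can be exercised and benchmarked offline.  Planted receptors are
wired to explicit receptor->kinase->TF routes whose members are later sampled
as highly expressed, giving a known ground truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .housekeeping import DEFAULT_EXPRESSION_CUTOFF, ExpressionPanel
from .ppi_graph import Interaction, MoleculeRoles

_DEFAULT_DENSITY = {"rr": 0.05, "rk": 0.08, "kk": 0.08, "ktf": 0.10}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``edge_density`` keys are the four permitted interaction categories
    (``rr``, ``rk``, ``kk``, ``ktf``).  Expression means are on the log2
    scale and must satisfy silent < expressed < active.
    """

    n_receptors: int = 10
    n_kinases: int = 20
    n_tfs: int = 15
    edge_density: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITY))
    score_range: tuple = (700, 999)
    planted_receptors: tuple = ()
    n_planted_routes: int = 3
    hk_fraction: float = 0.2
    expressed_mean: float = 3.0
    active_mean: float = 6.0
    silent_mean: float = 0.2
    noise_sd: float = 0.5
    expressed_fraction: float = 0.5
    n_panel_samples: int = 12
    n_replicates: int = 3
    cutoff: float = DEFAULT_EXPRESSION_CUTOFF
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_receptors, self.n_kinases, self.n_tfs) < 1:
            raise ValueError("need at least one receptor, kinase and TF")
        lo, hi = self.score_range
        if not (1 <= lo <= hi <= 999):
            raise ValueError(f"score_range {self.score_range} outside [1, 999]")
        for key, frac in list(self.edge_density.items()) + [
            ("hk_fraction", self.hk_fraction),
            ("expressed_fraction", self.expressed_fraction),
        ]:
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {key}={frac} outside [0, 1]")
        if not self.silent_mean < self.expressed_mean < self.active_mean:
            raise ValueError("means must satisfy silent < expressed < active")
        self.planted_receptors = tuple(str(r).upper() for r in self.planted_receptors)
        unknown = set(self.planted_receptors) - set(self.receptor_names)
        if unknown:
            raise ValueError(f"planted receptors not in generated set: {sorted(unknown)}")
        if self.planted_receptors and self.n_planted_routes > min(
            self.n_kinases, self.n_tfs
        ):
            raise ValueError("n_planted_routes exceeds available kinases or TFs")

    @property
    def receptor_names(self) -> list:
        return [f"R{i:03d}" for i in range(1, self.n_receptors + 1)]

    @property
    def kinase_names(self) -> list:
        return [f"K{i:03d}" for i in range(1, self.n_kinases + 1)]

    @property
    def tf_names(self) -> list:
        return [f"T{i:03d}" for i in range(1, self.n_tfs + 1)]

    @property
    def suggested_high_threshold(self) -> float:
        """Midpoint between the expressed and active means; lies above the
        peak of the expressed-gene distribution whenever the separation
        exceeds the noise."""
        return (self.expressed_mean + self.active_mean) / 2.0


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def planted_routes(spec: SyntheticSpec) -> dict:
    """Receptor -> tuple of (receptor, kinase, tf) routes, drawn
    deterministically from the spec seed."""
    rng = _rng(spec, 0)
    routes: dict = {}
    for receptor in sorted(spec.planted_receptors):
        kinases = rng.choice(spec.kinase_names, size=spec.n_planted_routes, replace=False)
        tfs = rng.choice(spec.tf_names, size=spec.n_planted_routes, replace=False)
        routes[receptor] = tuple(
            (receptor, str(k), str(t)) for k, t in zip(kinases, tfs)
        )
    return routes


def generate_network(spec: SyntheticSpec):
    """Interactions plus role assignment; every planted receptor is
    guaranteed a 3-node receptor->kinase->TF route at the maximum score."""
    roles = MoleculeRoles(
        receptors=frozenset(spec.receptor_names),
        kinases=frozenset(spec.kinase_names),
        tfs=frozenset(spec.tf_names),
    )
    lo, hi = spec.score_range
    interactions: dict = {}

    def add(a: str, b: str, score: int) -> None:
        key = frozenset((a, b))
        prev = interactions.get(key)
        if prev is None or score > prev.combined_score:
            interactions[key] = Interaction(a, b, score)

    for routes in planted_routes(spec).values():
        for r, k, t in routes:
            add(r, k, hi)
            add(k, t, hi)

    rng = _rng(spec, 1)
    categories = {
        "rr": [
            (a, b)
            for i, a in enumerate(spec.receptor_names)
            for b in spec.receptor_names[i + 1 :]
        ],
        "rk": [(a, b) for a in spec.receptor_names for b in spec.kinase_names],
        "kk": [
            (a, b)
            for i, a in enumerate(spec.kinase_names)
            for b in spec.kinase_names[i + 1 :]
        ],
        "ktf": [(a, b) for a in spec.kinase_names for b in spec.tf_names],
    }
    for cat in sorted(categories):
        density = spec.edge_density.get(cat, 0.0)
        pairs = categories[cat]
        keep = rng.random(len(pairs)) < density
        scores = rng.integers(lo, hi + 1, size=len(pairs))
        for (a, b), kept, score in zip(pairs, keep, scores):
            if kept and frozenset((a, b)) not in interactions:
                add(a, b, int(score))
    ordered = sorted(interactions.values())
    return ordered, roles


def generate_expression(
    interactions: Sequence[Interaction],
    roles: MoleculeRoles,
    spec: SyntheticSpec,
):
    """Query expression matrix (genes x replicates) plus the ground truth.

    Members of planted routes draw from Normal(active_mean, noise_sd); other
    genes flip a coin between the expressed and silent distributions.  All
    draws are truncated at zero.  The truth record carries the per-gene
    class partition, the planted receptors and a suggested high-expression
    threshold (midpoint of the expressed and active means).
    """
    genes = sorted(roles.all_symbols)
    active_genes = {
        g for routes in planted_routes(spec).values() for route in routes for g in route
    }
    rng = _rng(spec, 2)
    classes = {}
    for g in genes:
        if g in active_genes:
            classes[g] = "active"
        else:
            classes[g] = (
                "expressed" if rng.random() < spec.expressed_fraction else "silent"
            )
    means = {
        "active": spec.active_mean,
        "expressed": spec.expressed_mean,
        "silent": spec.silent_mean,
    }
    columns = [f"S{i}" for i in range(1, spec.n_replicates + 1)]
    data = np.empty((len(genes), spec.n_replicates))
    for i, g in enumerate(genes):
        draws = rng.normal(means[classes[g]], spec.noise_sd, size=spec.n_replicates)
        data[i] = np.maximum(draws, 0.0)
    matrix = pd.DataFrame(data, index=genes, columns=columns)
    truth = {
        "planted_receptors": sorted(spec.planted_receptors),
        "planted_routes": {
            r: [list(route) for route in routes]
            for r, routes in planted_routes(spec).items()
        },
        "classes": classes,
        "cutoff": spec.cutoff,
        "suggested_high_threshold": spec.suggested_high_threshold,
    }
    return matrix, truth


def generate_panel(roles: MoleculeRoles, spec: SyntheticSpec):
    """Multi-tissue panel plus the exact intended housekeeping set.

    Housekeeping genes are expressed (>= cutoff) in at least 75% of the
    samples, all others in strictly fewer, so ``identify_housekeeping`` at
    the default prevalence recovers the set exactly.
    """
    if spec.n_panel_samples < 2:
        raise ValueError("panel needs at least 2 samples")
    genes = sorted(roles.all_symbols)
    n = spec.n_panel_samples
    m = math.ceil(0.75 * n)  # smallest count meeting the 75% prevalence rule
    rng = _rng(spec, 3)
    n_hk = int(round(spec.hk_fraction * len(genes)))
    hk_genes = set(rng.choice(genes, size=n_hk, replace=False)) if n_hk else set()
    data = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        if g in hk_genes:
            n_expr = int(rng.integers(m, n + 1))
        else:
            n_expr = int(rng.integers(0, m))
        expressed_cols = rng.choice(n, size=n_expr, replace=False)
        row = rng.uniform(0.0, spec.cutoff, size=n)  # below cutoff
        row[expressed_cols] = spec.cutoff + rng.uniform(0.0, 6.5, size=n_expr)
        data[i] = row
    panel = ExpressionPanel(
        values=pd.DataFrame(data, index=genes, columns=[f"P{j}" for j in range(1, n + 1)])
    )
    return panel, frozenset(str(g) for g in hk_genes)


def spec_from_mapping(mapping: Mapping) -> SyntheticSpec:
    """Build a spec from a flat mapping (e.g. parsed YAML); unknown keys are
    rejected, list-valued fields are coerced to tuples."""
    allowed = set(SyntheticSpec.__dataclass_fields__)
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown synthetic spec keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if "score_range" in kwargs:
        kwargs["score_range"] = tuple(kwargs["score_range"])
    if "planted_receptors" in kwargs:
        kwargs["planted_receptors"] = tuple(kwargs["planted_receptors"])
    return SyntheticSpec(**kwargs)
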