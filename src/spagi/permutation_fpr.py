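"""Permutation-based false-positive-rate assessment.

Gene labels are shuffled against the expression values (conserving the value
multiset), the full filter -> threshold -> score -> select pipeline is re-run,
and the count of high-ranked pathways from each permuted profile is divided
by the count from the original profile.  The mean of these ratios over the
repetitions is the reported false positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .activity_scoring import (
    ExpressionProfile,
    default_high_threshold,
    filter_potential_paths,
    pathway_activity,
    select_high_ranked,
)
from .path_enumeration import PathwayBackground

DEFAULT_REPETITIONS = 10


@dataclass
class FPRResult:
    n_high_original: int
    n_high_permuted: list
    ratios: list
    mean_fpr: float
    seeds: list

    def to_dict(self) -> dict:
        return {
            "n_high_original": self.n_high_original,
            "n_high_permuted": list(self.n_high_permuted),
            "ratios": list(self.ratios),
            "mean_fpr": self.mean_fpr,
            "seeds": list(self.seeds),
        }


def permute_profile(profile: ExpressionProfile, seed: int) -> ExpressionProfile:
    """Reassign the profile's values to its genes by a uniform random
    permutation; the value multiset is conserved exactly."""
    genes = sorted(profile.values)
    values = np.array([profile.values[g] for g in genes], dtype=float)
    rng = np.random.default_rng(seed)
    permuted = values[rng.permutation(len(values))]
    return ExpressionProfile(
        values=dict(zip(genes, permuted.tolist())),
        cutoff=profile.cutoff,
        high_threshold=profile.high_threshold,
    )


def count_high_ranked(
    background: PathwayBackground,
    profile: ExpressionProfile,
    score_quantile: float = 0.75,
    min_tfs: int = 5,
    high_threshold: float | None = None,
) -> int:
    """Number of high-ranked pathways the pipeline calls on a profile."""
    potential = filter_potential_paths(background, profile)
    if not potential.pathways:
        return 0
    if high_threshold is None:
        high_threshold = default_high_threshold(profile)
    activities = pathway_activity(potential, profile, high_threshold)
    return len(select_high_ranked(activities, score_quantile, min_tfs))


def derive_seeds(master_seed: int, repetitions: int) -> list:
    """Deterministic per-repetition seeds from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(repetitions)
    return [int(s) for s in state]


def false_positive_rate(
    background: PathwayBackground,
    profile: ExpressionProfile,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int = 0,
    score_quantile: float = 0.75,
    min_tfs: int = 5,
    high_threshold: float | None = None,
    permuter: Callable = permute_profile,
) -> FPRResult:
    """Run the scoring pipeline on the original profile and on ``repetitions``
    gene-label permutations of it, and report per-repetition count ratios.

    The high-expression threshold is recomputed per profile when not given
    explicitly (the value multiset is conserved by permutation, so the
    recomputed threshold is unchanged).  ``permuter`` is injectable so tests
    can substitute the identity permutation.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    n_original = count_high_ranked(
        background, profile, score_quantile, min_tfs, high_threshold
    )
    if n_original == 0:
        raise ValueError("FPR undefined (division by zero): no high-ranked pathway "
                         "in the original profile")
    seeds = derive_seeds(seed, repetitions)
    n_permuted = [
        count_high_ranked(
            background, permuter(profile, s), score_quantile, min_tfs, high_threshold
        )
        for s in seeds
    ]
    ratios = [n / n_original for n in n_permuted]
    return FPRResult(
        n_high_original=n_original,
        n_high_permuted=n_permuted,
        ratios=ratios,
        mean_fpr=float(np.mean(ratios)),
        seeds=seeds,
    )
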