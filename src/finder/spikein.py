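"""Spike-in precision/recall evaluation of feature signatures.

A curated positive variant set is diluted with randomly drawn decoy
variants to a fixed prior (positives / total), mimicking a candidate pool
where the prevalence of true functional variants is known.  Each signature
(a feature combination) is then scored for precision and recall against the
positives, and the draw is repeated over permutations — only the decoys are
re-drawn; the positives stay fixed.

Decoys that happen to be genuinely functional are still treated as
negatives, which biases precision conservatively (downward).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .benchmark import Combination, MembershipMatrix, build_membership, combo_members, score_combination
from .genome_io import FeatureTrack, VariantSet

__all__ = ["SpikeInDesign", "SpikeInResult", "prior_probability", "run_spikein"]


@dataclass(frozen=True)
class SpikeInDesign:
    """Spike-in experiment parameters.

    Defaults: 210 curated positives diluted with 4000 random decoys over
    10 permutations, giving a positive prior close to 0.05.
    """

    n_positives: int = 210
    n_decoys: int = 4000
    n_permutations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positives <= 0 or self.n_decoys <= 0 or self.n_permutations <= 0:
            raise ValueError("all spike-in counts must be positive")

    @property
    def prior(self) -> float:
        return prior_probability(self.n_positives, self.n_decoys)


def prior_probability(n_positives: int, n_decoys: int) -> float:
    """Prevalence of true positives in the diluted candidate set."""
    if n_positives <= 0 or n_decoys <= 0:
        raise ValueError("counts must be positive")
    return n_positives / (n_positives + n_decoys)


@dataclass
class SpikeInResult:
    """Mean/SD precision and recall per signature over permutations."""

    summary: pd.DataFrame  # signature, mean/sd precision, mean/sd recall
    per_permutation: pd.DataFrame
    design: SpikeInDesign


def run_spikein(
    positives: VariantSet,
    decoy_pool: VariantSet,
    design: SpikeInDesign,
    tracks: Sequence[FeatureTrack],
    signatures: Sequence[Combination],
) -> SpikeInResult:
    """Score signatures on positives diluted with random decoys.

    Per permutation, ``n_decoys`` decoys are drawn from the pool without
    replacement and combined with the fixed positives; truth = the
    positives.  Raises if the decoy pool shares ids with the positives
    (a contaminated truth set).
    """
    if len(decoy_pool) < design.n_decoys:
        raise ValueError("decoy pool smaller than n_decoys")
    shared = positives.id_set() & decoy_pool.id_set()
    if shared:
        raise ValueError(f"decoy pool shares {len(shared)} id(s) with positives")

    # membership computed once for positives and for the full pool; each
    # permutation only re-indexes pool rows
    mm_pos = build_membership(positives, tracks)
    mm_pool = build_membership(decoy_pool, tracks)
    pos_members = {str(s): combo_members(mm_pos, s) for s in signatures}
    pool_members = {str(s): combo_members(mm_pool, s) for s in signatures}
    n_pos = len(positives)

    rows = []
    for perm in range(design.n_permutations):
        rng = np.random.default_rng([design.seed, perm])
        idx = rng.choice(len(decoy_pool), size=design.n_decoys, replace=False)
        candidate = VariantSet(
            pd.concat([positives.df, decoy_pool.df.iloc[idx]], ignore_index=True),
            label="spikein",
        )
        truth_flags = np.zeros(len(candidate), dtype=bool)
        truth_flags[:n_pos] = True
        for sig in signatures:
            members = np.concatenate([pos_members[str(sig)], pool_members[str(sig)][idx]])
            m = score_combination(candidate, members, positives, combination=sig)
            rows.append(
                {
                    "permutation": perm,
                    "signature": str(sig),
                    "precision": m.precision,
                    "recall": m.recall,
                }
            )
    per_perm = pd.DataFrame(rows)
    summary = (
        per_perm.groupby("signature", sort=False)
        .agg(
            mean_precision=("precision", "mean"),
            sd_precision=("precision", lambda x: x.std(ddof=1)),
            mean_recall=("recall", "mean"),
            sd_recall=("recall", lambda x: x.std(ddof=1)),
            n_permutations=("permutation", "count"),
        )
        .reset_index()
    )
    return SpikeInResult(summary=summary, per_permutation=per_perm, design=design)
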