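"""Centrality in open chromatin: summit windows, cores, and footprint distances.

Open-chromatin (DHS) intervals carry a summit — the point of maximal
accessibility — and a consensus core sub-interval.  These operations test
whether proximity to the summit predicts functional variants: windows of
±25/±50/±100 bp around summits (clipped to the parent interval, since a
window should not extend into closed chromatin) are scored as precision
fold change over the unfiltered candidate set, and footprint-to-summit
signed distances summarize where DNA-binding protection sits relative to
the accessibility peak.  "Up/downstream" is genomic left/right — DHS have
no strand; negative means left of the summit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import fold_change, score_combination
from .genome_io import (
    FeatureTrack,
    SummitTrack,
    VariantSet,
    intersect_variants,
    merge_track,
    nearest_signed_distance,
)

__all__ = [
    "WindowSpec",
    "make_window_track",
    "centrality_precision",
    "FootprintDistanceResult",
    "footprint_summit_distribution",
]

DEFAULT_HALF_WIDTHS = (25, 50, 100)


@dataclass(frozen=True)
class WindowSpec:
    """Either the stored consensus core, or a ±half_width summit window."""

    mode: str  # "core" | "summit_window"
    half_width: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"core", "summit_window"}:
            raise ValueError(f"unknown window mode {self.mode!r}")
        if self.mode == "summit_window" and self.half_width < 0:
            raise ValueError("half_width must be >= 0")

    def label(self) -> str:
        return "core" if self.mode == "core" else f"summit±{self.half_width}"


def make_window_track(st: SummitTrack, spec: WindowSpec) -> FeatureTrack:
    """Build the window track for one spec (merged output).

    ``summit_window`` mode returns ``[summit0 - w, summit0 + w + 1)`` per
    interval — w bases either side of the summit base, inclusive — clipped
    to the parent interval.
    """
    df = st.df
    if spec.mode == "core":
        out = pd.DataFrame(
            {"chrom": df["chrom"], "start": df["core_start"], "end": df["core_end"]}
        )
    else:
        s0 = df["summit"] - 1
        start = np.maximum(s0 - spec.half_width, df["start"])
        end = np.minimum(s0 + spec.half_width + 1, df["end"])
        out = pd.DataFrame({"chrom": df["chrom"], "start": start, "end": end})
    return merge_track(FeatureTrack(spec.label(), out))


def centrality_precision(
    candidate: VariantSet,
    window_tracks: Mapping[str, FeatureTrack],
    truth_sets: Sequence[VariantSet],
) -> pd.DataFrame:
    """Precision fold change of each window track over the bare candidate set.

    The baseline is the precision of the candidate set with no feature
    filter (all-members).  Empty window tracks yield missing fold changes.
    """
    rows = []
    all_members = np.ones(len(candidate), dtype=bool)
    for truth in truth_sets:
        base = score_combination(candidate, all_members, truth).precision
        for name, track in window_tracks.items():
            if len(track) == 0:
                rows.append(
                    {"window": name, "truth": truth.label, "precision": math.nan,
                     "fold_change": math.nan}
                )
                continue
            members = intersect_variants(candidate, track)
            p = score_combination(candidate, members, truth).precision
            rows.append(
                {"window": name, "truth": truth.label, "precision": p,
                 "fold_change": fold_change(p, base)}
            )
    return pd.DataFrame(rows)


@dataclass
class FootprintDistanceResult:
    """Signed summit→nearest-footprint distances plus the beyond-max count."""

    distances: np.ndarray  # summits with a footprint within max_distance
    n_beyond: int  # summits with no footprint within max_distance (incl. no-footprint chroms)
    max_distance: int

    def histogram(self, bins: int = 41) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(
            self.distances, bins=bins, range=(-self.max_distance, self.max_distance)
        )


def footprint_summit_distribution(
    footprints: FeatureTrack, st: SummitTrack, max_distance: int = 1000
) -> FootprintDistanceResult:
    """Distance from each DHS summit to its nearest footprint.

    Zero when the summit base lies inside a footprint; summits farther than
    ``max_distance`` from any footprint (or on chromosomes with none) are
    excluded from the distance vector and counted in ``n_beyond``.
    """
    d = nearest_signed_distance(st.summit_positions(), footprints)
    within = ~np.isnan(d) & (np.abs(d) <= max_distance)
    return FootprintDistanceResult(
        distances=d[within], n_beyond=int((~within).sum()), max_distance=max_distance
    )
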