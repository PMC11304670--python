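"""LD expansion and footprint∩eRNA prioritization of GWAS variants.

The end-to-end prioritization step: GWAS lead variants are optionally
expanded through a pre-fetched linkage-disequilibrium table (linked
variants within a distance window at R² and MAF thresholds), then filtered
to the variants that co-localize with **both** DNase footprints and eRNA —
the high-precision signature.  Reported alongside are the expansion fold
(expanded / leads), the reduction fold (input / prioritized), and per-trait
precision/recall summaries against a combined molQTL truth set.

Thresholds default to the TopLD-style query: R² ≥ 0.7 (inclusive), window
500 kb (unsigned lead-to-linked distance), MAF ≥ 1%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .benchmark import Combination, build_membership, combo_members, score_combination
from .genome_io import FeatureTrack, SchemaError, VariantSet, intersect_variants

__all__ = [
    "LD_COLUMNS",
    "read_ld_table",
    "expand_ld",
    "PrioritizeResult",
    "prioritize",
    "trait_pr_summary",
]

LD_COLUMNS = ["lead_id", "linked_id", "chrom", "pos", "r2", "maf"]


def read_ld_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a lead→linked LD table (TSV).

    Rows violating the invariants (R² outside [0,1], MAF outside (0,0.5],
    pos < 1) are rejected with a warning.  Duplicate (lead, linked) pairs
    keep the maximum-R² record.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(LD_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: LD table missing column(s) {sorted(missing)}")
    ok = (
        df["r2"].between(0, 1)
        & (df["maf"] > 0)
        & (df["maf"] <= 0.5)
        & (df["pos"] >= 1)
    )
    if (~ok).any():
        warnings.warn(f"rejected {int((~ok).sum())} invalid LD row(s)", stacklevel=2)
        df = df[ok]
    df = (
        df.sort_values("r2", ascending=False, kind="mergesort")
        .drop_duplicates(["lead_id", "linked_id"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return df


def expand_ld(
    leads: VariantSet,
    ld: pd.DataFrame,
    r2_min: float = 0.7,
    window: int = 500_000,
    maf_min: float = 0.01,
) -> VariantSet:
    """Expand lead variants with their LD-linked variants.

    Every input lead is retained.  A linked variant is added when its R² is
    ≥ ``r2_min`` (inclusive), its unsigned distance to the lead position is
    ≤ ``window``, and its MAF is ≥ ``maf_min``.  The output is deduplicated
    by id keeping the maximum-R² provenance, sorted by (chrom, pos), and
    carries provenance columns ``source`` (lead | ld), ``lead_id``, ``r2``.
    Leads without a position are kept but cannot anchor window filtering
    (warned).
    """
    lead_df = leads.df.copy()
    lead_pos = lead_df.set_index("id")["pos"]
    no_pos = lead_pos.isna()
    if no_pos.any():
        warnings.warn(
            f"{int(no_pos.sum())} lead(s) without positions excluded from window filtering",
            stacklevel=2,
        )

    linked = ld[ld["lead_id"].isin(lead_pos.index)].copy()
    linked = linked[(linked["r2"] >= r2_min) & (linked["maf"] >= maf_min)]
    anchor = linked["lead_id"].map(lead_pos)
    linked = linked[anchor.notna() & ((linked["pos"] - anchor).abs() <= window)]

    lead_out = lead_df[["id", "chrom", "pos", "pvalue", "trait", "maf"]].copy()
    lead_out["source"] = "lead"
    lead_out["lead_id"] = lead_out["id"]
    lead_out["r2"] = 1.0
    linked_out = pd.DataFrame(
        {
            "id": linked["linked_id"].astype(str),
            "chrom": linked["chrom"].astype(str),
            "pos": linked["pos"].astype(np.int64),
            "pvalue": np.nan,
            "trait": None,
            "maf": linked["maf"],
            "source": "ld",
            "lead_id": linked["lead_id"].astype(str),
            "r2": linked["r2"],
        }
    )
    frames = [lead_out] + ([linked_out] if len(linked_out) else [])
    both = pd.concat(frames, ignore_index=True)
    # leads first, then max r2, so a variant that is itself a lead stays a lead
    both["_is_lead"] = (both["source"] == "lead").astype(int)
    both = (
        both.sort_values(["_is_lead", "r2"], ascending=[False, False], kind="mergesort")
        .drop_duplicates("id", keep="first")
        .drop(columns="_is_lead")
        .sort_values(["chrom", "pos"], kind="mergesort")
        .reset_index(drop=True)
    )
    return VariantSet(both, label=f"{leads.label}+LD" if leads.label else "expanded")


@dataclass
class PrioritizeResult:
    """Variants co-localizing with both tracks, plus the reduction fold."""

    variants: VariantSet
    n_input: int
    n_prioritized: int
    reduction_fold: float  # n_input / n_prioritized; missing when none pass

    @property
    def table(self) -> pd.DataFrame:
        return self.variants.df


def prioritize(
    vs: VariantSet, footprints: FeatureTrack, erna: FeatureTrack
) -> PrioritizeResult:
    """Keep variants overlapping BOTH footprints and eRNA.

    Symmetric in the two tracks.  The returned table carries boolean
    ``in_footprint`` / ``in_eRNA`` provenance columns (both true for every
    retained row, by construction).
    """
    in_fp = intersect_variants(vs, footprints)
    in_er = intersect_variants(vs, erna)
    keep = in_fp & in_er
    out = vs.df.loc[keep].copy()
    out["in_footprint"] = True
    out["in_eRNA"] = True
    n_in, n_out = len(vs), int(keep.sum())
    fold = n_in / n_out if n_out > 0 else math.nan
    return PrioritizeResult(
        variants=VariantSet(out.reset_index(drop=True), label=f"{vs.label}|prioritized"),
        n_input=n_in,
        n_prioritized=n_out,
        reduction_fold=fold,
    )


def trait_pr_summary(
    trait_sets: Mapping[str, VariantSet],
    signatures: Sequence[Combination],
    tracks: Sequence[FeatureTrack],
    combined_truth: VariantSet,
) -> pd.DataFrame:
    """Mean precision/recall per signature across traits, with 95% CI.

    Each trait's (GWAS + LD) variant set is scored per signature against
    the combined molQTL truth set; across traits the mean and a
    normal-approximation CI (mean ± 1.96·SE, SE = SD/√n) are reported.
    Missing per-trait values (empty signature membership) are excluded.
    Requires at least two traits.
    """
    if len(trait_sets) < 2:
        raise ValueError("trait summary requires >= 2 traits")
    per_trait = []
    for trait, vs in trait_sets.items():
        mm = build_membership(vs, tracks)
        for sig in signatures:
            m = score_combination(vs, combo_members(mm, sig), combined_truth, combination=sig)
            per_trait.append(
                {"trait": trait, "signature": str(sig), "precision": m.precision,
                 "recall": m.recall}
            )
    df = pd.DataFrame(per_trait)

    rows = []
    for sig, sub in df.groupby("signature", sort=False):
        row: dict[str, float | str] = {"signature": sig}
        for metric in ("precision", "recall"):
            vals = sub[metric].dropna().to_numpy()
            if len(vals) == 0:
                row.update({f"mean_{metric}": math.nan, f"ci_lo_{metric}": math.nan,
                            f"ci_hi_{metric}": math.nan, f"n_traits_{metric}": 0})
                continue
            mean = vals.mean()
            se = vals.std(ddof=1) / math.sqrt(len(vals)) if len(vals) > 1 else 0.0
            row.update(
                {
                    f"mean_{metric}": float(mean),
                    f"ci_lo_{metric}": float(mean - 1.96 * se),
                    f"ci_hi_{metric}": float(mean + 1.96 * se),
                    f"n_traits_{metric}": len(vals),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
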