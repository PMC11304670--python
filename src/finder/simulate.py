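"""Self-contained synthetic data with the structure the benchmark assumes.

The generator emulates the statistical shape of a merged multi-biosource
compendium of active-regulatory-element tracks and of the variant sets
benchmarked against them:

* six marker tracks with a realistic coverage hierarchy — broad,
  high-coverage ATAC and H3K27ac; intermediate DHS (with summits and
  consensus cores) and ChIP; short, sparse DNase footprints nested inside
  DHS near their summits; eRNA intervals placed around DHS summits;
* a GWAS-style variant set in which a configurable *functional fraction*
  is planted preferentially inside the footprint∩eRNA signature;
* three molQTL truth sets (bQTL/raQTL/caQTL) drawn from the functional
  variants with per-assay detection probabilities and a cross-assay
  overlap control that is near-zero by default, so the three sets are
  almost disjoint;
* a common-SNV pool (MAF ≥ 1%) for random-subset nulls and spike-ins;
* LD blocks around lead variants, with an optional recovery-test mode that
  plants exactly one linked variant per block inside the signature.

Interval lengths are log-normal, parameterized by median and dispersion.
Everything is driven by one integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome_io import (
    FeatureTrack,
    SummitTrack,
    VariantSet,
    complement_track,
    coverage_fraction,
    intersect_tracks,
    intersect_variants,
    merge_track,
    write_bed,
    write_summits,
    write_variants,
)

__all__ = [
    "MarkerConfig",
    "SimConfig",
    "TrackSim",
    "VariantSim",
    "LDSim",
    "simulate_tracks",
    "simulate_variants",
    "simulate_ld",
    "export_ground_truth",
    "simulate_run",
]

MARKER_NAMES = ("DHS", "footprint", "ATAC", "ChIP", "eRNA", "H3K27ac")
ASSAYS = ("bQTL", "raQTL", "caQTL")


@dataclass
class MarkerConfig:
    """Per-marker interval generation settings.

    ``dhs_bias`` is the fraction of intervals centered near DHS summits
    (with Gaussian offset ``placement_sd``); the rest are uniform.  For the
    footprint marker the biased fraction is additionally constrained to lie
    *inside* its parent DHS interval (the nesting rule).
    """

    n_biosources: int = 3
    median_length: int = 300
    length_dispersion: float = 0.4
    target_coverage: float = 0.1
    dhs_bias: float = 0.0
    placement_sd: float = 300.0


def _default_markers() -> dict[str, MarkerConfig]:
    return {
        "DHS": MarkerConfig(4, 200, 0.35, 0.12),
        "footprint": MarkerConfig(2, 20, 0.25, 0.035, dhs_bias=0.9, placement_sd=40.0),
        "ATAC": MarkerConfig(6, 450, 0.5, 0.60, dhs_bias=0.35, placement_sd=400.0),
        "ChIP": MarkerConfig(5, 300, 0.4, 0.25, dhs_bias=0.7, placement_sd=250.0),
        "eRNA": MarkerConfig(2, 300, 0.4, 0.02, dhs_bias=0.9, placement_sd=300.0),
        "H3K27ac": MarkerConfig(5, 900, 0.5, 0.50, dhs_bias=0.35, placement_sd=600.0),
    }


@dataclass
class SimConfig:
    """Full simulation configuration; ``seed`` is mandatory and drives all draws."""

    seed: int
    genome: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    )
    markers: dict[str, MarkerConfig] = field(default_factory=_default_markers)
    core_median_length: int = 37
    core_length_dispersion: float = 0.15
    # variants
    n_gwas_variants: int = 2000
    functional_fraction: float = 0.25
    placement_prob: float = 0.8  # P(functional variant placed in footprint∩eRNA)
    detection_prob: dict[str, float] = field(
        default_factory=lambda: {"bQTL": 0.7, "raQTL": 0.45, "caQTL": 0.6}
    )
    assay_affinity: dict[str, float] = field(
        default_factory=lambda: {"bQTL": 0.4, "raQTL": 0.25, "caQTL": 0.35}
    )
    cross_assay_overlap: float = 0.05
    n_common_snv_pool: int = 5000
    pool_functional_fraction: float = 0.1
    n_traits: int = 6
    # planted-precision mode (overrides the molQTL machinery for the GWAS set)
    planted_signature_precision: float | None = None
    signature_fraction: float = 0.15
    background_truth_rate: float = 0.05
    # LD
    n_ld_blocks: int = 20
    linked_per_block: int = 15
    ld_window: int = 500_000
    ld_recovery_test: bool = False

    def __post_init__(self) -> None:
        for name, mc in self.markers.items():
            if not 0 < mc.target_coverage <= 0.85:
                raise ValueError(
                    f"{name}: target coverage {mc.target_coverage} infeasible "
                    "(must be in (0, 0.85])"
                )
        probs = [
            self.functional_fraction, self.placement_prob, self.cross_assay_overlap,
            self.pool_functional_fraction, self.signature_fraction, self.background_truth_rate,
            *self.detection_prob.values(), *self.assay_affinity.values(),
        ]
        if self.planted_signature_precision is not None:
            probs.append(self.planted_signature_precision)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "markers" in d:
            d["markers"] = {k: MarkerConfig(**v) for k, v in d["markers"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# position/length sampling helpers
# ---------------------------------------------------------------------------

def _chrom_arrays(genome: Mapping[str, int]) -> tuple[list[str], np.ndarray]:
    chroms = sorted(genome)
    sizes = np.array([genome[c] for c in chroms], dtype=np.int64)
    return chroms, sizes


def _sample_lengths(rng: np.random.Generator, n: int, median: int, sigma: float) -> np.ndarray:
    ln = np.round(median * np.exp(sigma * rng.standard_normal(n))).astype(np.int64)
    return np.maximum(ln, 1)


def _sample_uniform_intervals(
    rng: np.random.Generator, genome: Mapping[str, int], lengths: np.ndarray
) -> pd.DataFrame:
    chroms, sizes = _chrom_arrays(genome)
    ci = rng.choice(len(chroms), size=len(lengths), p=sizes / sizes.sum())
    max_start = np.maximum(sizes[ci] - lengths, 1)
    starts = (rng.random(len(lengths)) * max_start).astype(np.int64)
    ends = np.minimum(starts + lengths, sizes[ci])
    return pd.DataFrame({"chrom": np.array(chroms)[ci], "start": starts, "end": ends})


def _sample_track_positions(
    rng: np.random.Generator, track: FeatureTrack, n: int
) -> pd.DataFrame:
    """n 1-based positions uniform over the covered bases of a merged track."""
    df = track.df
    lengths = (df["end"] - df["start"]).to_numpy(np.int64)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("cannot sample positions from an empty track")
    offs = (rng.random(n) * total).astype(np.int64)
    cum = np.cumsum(lengths)
    k = np.searchsorted(cum, offs, side="right")
    within = offs - (cum[k] - lengths[k])
    pos = df["start"].to_numpy(np.int64)[k] + within + 1
    return pd.DataFrame({"chrom": df["chrom"].to_numpy()[k], "pos": pos})


def _sample_genome_positions(
    rng: np.random.Generator, genome: Mapping[str, int], n: int
) -> pd.DataFrame:
    chroms, sizes = _chrom_arrays(genome)
    whole = FeatureTrack.from_arrays("genome", chroms, [0] * len(chroms), sizes)
    return _sample_track_positions(rng, whole, n)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackSim:
    """Simulated marker tracks: merged masters, per-biosource tracks, summits."""

    merged: dict[str, FeatureTrack]
    biosources: dict[str, list[FeatureTrack]]
    summits: SummitTrack

    def signature(self) -> FeatureTrack:
        """The footprint∩eRNA intersection track."""
        return intersect_tracks(self.merged["footprint"], self.merged["eRNA"], name="footprint&eRNA")


def _generate_marker(
    rng: np.random.Generator,
    name: str,
    mc: MarkerConfig,
    genome: Mapping[str, int],
    summits: SummitTrack | None,
) -> pd.DataFrame:
    """Accumulate candidate intervals until the merged coverage target is met."""
    total_bp = sum(genome.values())
    target_bp = mc.target_coverage * total_bp
    mean_len = mc.median_length * float(np.exp(mc.length_dispersion**2 / 2))
    n_est = int(np.ceil(-np.log1p(-mc.target_coverage) * total_bp / mean_len))
    batch = max(16, n_est // 12)
    pieces: list[pd.DataFrame] = []
    covered = 0
    for attempt in range(60):
        lengths = _sample_lengths(rng, batch, mc.median_length, mc.length_dispersion)
        n_biased = int(round(mc.dhs_bias * batch)) if summits is not None else 0
        parts = []
        if n_biased:
            sdf = summits.df
            pick = rng.integers(0, len(sdf), size=n_biased)
            centers = (
                sdf["summit"].to_numpy(np.int64)[pick]
                - 1
                + np.round(rng.normal(0, mc.placement_sd, n_biased)).astype(np.int64)
            )
            ln = lengths[:n_biased]
            starts = centers - ln // 2
            if name == "footprint":
                # nesting rule: keep the footprint inside its parent DHS interval
                p_start = sdf["start"].to_numpy(np.int64)[pick]
                p_end = sdf["end"].to_numpy(np.int64)[pick]
                starts = np.clip(starts, p_start, np.maximum(p_end - ln, p_start))
                ends = np.minimum(starts + ln, p_end)
            else:
                chroms_map = {c: genome[c] for c in genome}
                csize = sdf["chrom"].to_numpy()[pick]
                cs = np.array([chroms_map[c] for c in csize], dtype=np.int64)
                starts = np.clip(starts, 0, np.maximum(cs - ln, 0))
                ends = np.minimum(starts + ln, cs)
            part = pd.DataFrame(
                {"chrom": sdf["chrom"].to_numpy()[pick], "start": starts, "end": ends}
            )
            parts.append(part[part["end"] > part["start"]])
        if batch - n_biased > 0:
            parts.append(_sample_uniform_intervals(rng, genome, lengths[n_biased:]))
        pieces.append(pd.concat(parts, ignore_index=True))
        merged = merge_track(FeatureTrack(name, pd.concat(pieces, ignore_index=True)))
        covered = merged.total_bp()
        if covered >= target_bp:
            return pd.concat(pieces, ignore_index=True)
    raise ValueError(
        f"{name}: coverage target {mc.target_coverage:.3f} infeasible "
        f"(reached {covered / total_bp:.3f}); placement region may be saturated"
    )


def simulate_tracks(cfg: SimConfig) -> TrackSim:
    """Generate the six marker tracks plus the DHS summit track.

    DHS is generated first; its merged intervals receive summits (uniform
    within the central third) and consensus cores (log-normal length around
    the summit, clipped to the interval).  Markers with ``dhs_bias`` place
    that fraction of their intervals around the summits; footprints nest
    inside their parent DHS.  The realized merged coverage of every marker
    meets its target (the accumulation loop guarantees it or raises).
    """
    rng = np.random.default_rng([cfg.seed, 0])
    unknown = set(cfg.markers) - set(MARKER_NAMES)
    if unknown:
        raise ValueError(f"unknown marker(s): {sorted(unknown)}")

    candidates: dict[str, pd.DataFrame] = {}
    candidates["DHS"] = _generate_marker(rng, "DHS", cfg.markers["DHS"], cfg.genome, None)
    dhs_merged = merge_track(FeatureTrack("DHS", candidates["DHS"]))

    # summits + cores on the merged DHS intervals
    d = dhs_merged.df
    span = (d["end"] - d["start"]).to_numpy(np.int64)
    lo = d["start"].to_numpy(np.int64) + span // 3
    width = np.maximum(span - 2 * (span // 3), 1)
    summit0 = lo + (rng.random(len(d)) * width).astype(np.int64)
    core_len = _sample_lengths(rng, len(d), cfg.core_median_length, cfg.core_length_dispersion)
    core_start = np.maximum(summit0 - core_len // 2, d["start"].to_numpy(np.int64))
    core_end = np.minimum(core_start + core_len, d["end"].to_numpy(np.int64))
    core_start = np.minimum(core_start, np.maximum(summit0, core_end - 1))
    summits = SummitTrack(
        pd.DataFrame(
            {
                "chrom": d["chrom"],
                "start": d["start"],
                "end": d["end"],
                "summit": summit0 + 1,
                "core_start": core_start,
                "core_end": core_end,
            }
        )
    )

    for name in ("footprint", "eRNA", "ChIP", "ATAC", "H3K27ac"):
        candidates[name] = _generate_marker(rng, name, cfg.markers[name], cfg.genome, summits)

    merged: dict[str, FeatureTrack] = {}
    biosources: dict[str, list[FeatureTrack]] = {}
    for name, cand in candidates.items():
        merged[name] = merge_track(FeatureTrack(name, cand))
        nb = cfg.markers[name].n_biosources
        # every candidate interval belongs to >= 1 biosource, so the union of
        # biosource tracks reproduces the master exactly
        primary = rng.integers(0, nb, size=len(cand))
        extra = rng.random((len(cand), nb)) < 0.25
        tracks = []
        for b in range(nb):
            keep = (primary == b) | extra[:, b]
            tracks.append(
                merge_track(FeatureTrack(f"{name}_bs{b + 1}", cand.loc[keep]))
            )
        biosources[name] = tracks

    return TrackSim(merged=merged, biosources=biosources, summits=summits)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass
class VariantSim:
    """Simulated variant sets plus the planted ground truth."""

    gwas: VariantSet
    molqtl: dict[str, VariantSet]
    pool: VariantSet
    truth: pd.DataFrame  # id, origin, functional, placement, per-assay flags


def _assign_assays(
    rng: np.random.Generator, functional: np.ndarray, cfg: SimConfig
) -> dict[str, np.ndarray]:
    """Per-assay membership for functional variants.

    Each functional variant has a primary assay drawn from the affinity
    distribution and is detected there with that assay's detection
    probability; it additionally enters each *other* assay with probability
    ``cross_assay_overlap × detection``, so pairwise overlap is directly
    controlled (0 → disjoint sets).
    """
    n = len(functional)
    affin = np.array([cfg.assay_affinity[a] for a in ASSAYS], dtype=float)
    affin = affin / affin.sum()
    primary = rng.choice(len(ASSAYS), size=n, p=affin)
    out = {}
    for k, assay in enumerate(ASSAYS):
        det = cfg.detection_prob[assay]
        is_primary = primary == k
        p = np.where(is_primary, det, cfg.cross_assay_overlap * det)
        out[assay] = functional & (rng.random(n) < p)
    return out


def simulate_variants(cfg: SimConfig, tracks: TrackSim) -> VariantSim:
    """Generate the GWAS set, molQTL truth sets, and the common-SNV pool.

    Default mode: a ``functional_fraction`` of GWAS variants is functional;
    each functional variant lands inside footprint∩eRNA with probability
    ``placement_prob`` (else uniform), and enters the molQTL sets through
    the assay-affinity machinery.  The pool follows the same rules with its
    own functional fraction and carries MAF ≥ 1%.

    Planted-precision mode (``planted_signature_precision`` = π): a
    ``signature_fraction`` of GWAS variants is placed uniformly *inside*
    the signature and is functional with probability exactly π; all other
    GWAS variants are placed strictly outside the signature.  The precision
    of the footprint∩eRNA signature against the molQTL union is then a
    Binomial(n_signature, π) proportion by construction.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    signature = tracks.signature()
    if len(signature) == 0:
        raise ValueError("footprint∩eRNA signature region is empty")

    def build_set(prefix: str, n: int, functional_fraction: float, planted: bool):
        if planted:
            n_sig = int(round(cfg.signature_fraction * n))
            in_sig = np.zeros(n, dtype=bool)
            in_sig[:n_sig] = True
            functional = np.zeros(n, dtype=bool)
            functional[:n_sig] = rng.random(n_sig) < cfg.planted_signature_precision
            functional[n_sig:] = rng.random(n - n_sig) < cfg.background_truth_rate
        else:
            n_func = int(round(functional_fraction * n))
            functional = np.zeros(n, dtype=bool)
            functional[:n_func] = True
            in_sig = np.zeros(n, dtype=bool)
            in_sig[:n_func] = rng.random(n_func) < cfg.placement_prob
        pos = pd.DataFrame({"chrom": [""] * n, "pos": np.zeros(n, dtype=np.int64)})
        k_sig = int(in_sig.sum())
        if k_sig:
            placed = _sample_track_positions(rng, signature, k_sig)
            pos.loc[in_sig, ["chrom", "pos"]] = placed.to_numpy()
        rest = ~in_sig
        k_rest = int(rest.sum())
        if k_rest:
            if planted:
                outside = complement_track(signature, cfg.genome)
                placed = _sample_track_positions(rng, outside, k_rest)
            else:
                placed = _sample_genome_positions(rng, cfg.genome, k_rest)
            pos.loc[rest, ["chrom", "pos"]] = placed.to_numpy()
        return pos, functional, in_sig

    planted_mode = cfg.planted_signature_precision is not None

    g_pos, g_func, g_sig = build_set("rs", cfg.n_gwas_variants, cfg.functional_fraction, planted_mode)
    gwas_df = pd.DataFrame(
        {
            "id": [f"rs{100000 + i}" for i in range(cfg.n_gwas_variants)],
            "chrom": g_pos["chrom"],
            "pos": g_pos["pos"].astype(np.int64),
            "pvalue": 10.0 ** -(5.1 + 10 * rng.random(cfg.n_gwas_variants)),
            "trait": [f"trait_{k + 1}" for k in rng.integers(0, cfg.n_traits, cfg.n_gwas_variants)],
            "maf": np.round(0.01 + 0.49 * rng.random(cfg.n_gwas_variants), 4),
        }
    )
    gwas = VariantSet(gwas_df, label="gwas")
    # in planted mode the signature precision is defined against the molQTL
    # union, so every functional variant must be detected (by its primary
    # assay); detection thinning would scale the planted value down
    assay_cfg = (
        dataclasses.replace(cfg, detection_prob={a: 1.0 for a in ASSAYS})
        if planted_mode
        else cfg
    )
    g_assay = _assign_assays(rng, g_func, assay_cfg)

    p_pos, p_func, p_sig = build_set(
        "pool", cfg.n_common_snv_pool, cfg.pool_functional_fraction, False
    )
    pool_df = pd.DataFrame(
        {
            "id": [f"rs{500000 + i}" for i in range(cfg.n_common_snv_pool)],
            "chrom": p_pos["chrom"],
            "pos": p_pos["pos"].astype(np.int64),
            "pvalue": np.nan,
            "trait": None,
            "maf": np.round(0.01 + 0.49 * rng.random(cfg.n_common_snv_pool), 4),
        }
    )
    pool = VariantSet(pool_df, label="pool")
    p_assay = _assign_assays(rng, p_func, cfg)

    molqtl = {}
    for assay in ASSAYS:
        ids = np.concatenate(
            [gwas_df.loc[g_assay[assay], "id"].to_numpy(), pool_df.loc[p_assay[assay], "id"].to_numpy()]
        )
        sub = pd.concat(
            [gwas_df.loc[g_assay[assay]], pool_df.loc[p_assay[assay]]], ignore_index=True
        )
        molqtl[assay] = VariantSet(sub, label=assay)

    truth = pd.DataFrame(
        {
            "id": np.concatenate([gwas_df["id"], pool_df["id"]]),
            "origin": ["gwas"] * len(gwas_df) + ["pool"] * len(pool_df),
            "functional": np.concatenate([g_func, p_func]),
            "placement": np.where(
                np.concatenate([g_sig, p_sig]), "signature", "background"
            ),
        }
    )
    for assay in ASSAYS:
        truth[assay] = np.concatenate([g_assay[assay], p_assay[assay]])
    return VariantSim(gwas=gwas, molqtl=molqtl, pool=pool, truth=truth)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

@dataclass
class LDSim:
    """An LD table plus, in recovery mode, the planted variant per block."""

    table: pd.DataFrame  # lead_id, linked_id, chrom, pos, r2, maf
    leads: VariantSet
    planted: pd.DataFrame  # lead_id, planted_id (empty unless recovery mode)


def simulate_ld(cfg: SimConfig, gwas: VariantSet, tracks: TrackSim) -> LDSim:
    """Build LD blocks around lead variants drawn from the GWAS set.

    Each of ``n_ld_blocks`` leads gains ``linked_per_block`` linked
    variants within ``ld_window`` bp, with R² ~ U(0.2, 1) and MAF ≥ 1%.
    In recovery-test mode the leads are chosen outside the footprint∩eRNA
    signature, exactly one linked variant per block is placed inside the
    signature (with R² ≥ 0.75 so it survives the threshold), and all other
    linked variants are placed outside it.
    """
    if len(gwas) == 0:
        raise ValueError("gwas set is empty")
    rng = np.random.default_rng([cfg.seed, 2])
    signature = tracks.signature()
    sig_member = intersect_variants(gwas, signature)

    candidates = np.flatnonzero(~sig_member) if cfg.ld_recovery_test else np.arange(len(gwas))
    if len(candidates) < cfg.n_ld_blocks:
        raise ValueError("not enough lead candidates for the requested number of blocks")
    lead_idx = np.sort(rng.choice(candidates, size=cfg.n_ld_blocks, replace=False))
    leads = gwas.subset(lead_idx)

    sig_by_chrom = signature.by_chrom()
    rows = []
    planted_rows = []
    serial = 0
    for lead in leads.df.itertuples(index=False):
        size = cfg.genome[lead.chrom]
        lo = max(1, lead.pos - cfg.ld_window)
        hi = min(size, lead.pos + cfg.ld_window)
        n_linked = cfg.linked_per_block
        planted_slot = rng.integers(0, n_linked) if cfg.ld_recovery_test else -1

        window_track = FeatureTrack.from_arrays("win", [lead.chrom], [lo - 1], [hi])
        sig_in_window = intersect_tracks(window_track, signature)
        out_of_sig = intersect_tracks(window_track, complement_track(signature, cfg.genome))

        for j in range(n_linked):
            serial += 1
            linked_id = f"rs{900000 + serial}"
            if j == planted_slot:
                if len(sig_in_window) == 0:
                    raise ValueError(
                        f"no signature bases within {cfg.ld_window} bp of lead {lead.id}"
                    )
                p = _sample_track_positions(rng, sig_in_window, 1)
                pos = int(p["pos"].iloc[0])
                r2 = float(np.round(0.75 + 0.25 * rng.random(), 4))
                planted_rows.append({"lead_id": lead.id, "planted_id": linked_id})
            else:
                if cfg.ld_recovery_test:
                    p = _sample_track_positions(rng, out_of_sig, 1)
                    pos = int(p["pos"].iloc[0])
                else:
                    pos = int(rng.integers(lo, hi + 1))
                r2 = float(np.round(0.2 + 0.8 * rng.random(), 4))
            rows.append(
                {
                    "lead_id": lead.id,
                    "linked_id": linked_id,
                    "chrom": lead.chrom,
                    "pos": pos,
                    "r2": r2,
                    "maf": float(np.round(0.01 + 0.49 * rng.random(), 4)),
                }
            )
    return LDSim(
        table=pd.DataFrame(rows),
        leads=leads,
        planted=pd.DataFrame(planted_rows, columns=["lead_id", "planted_id"]),
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_ground_truth(vsim: VariantSim, path: str | Path) -> None:
    """Write the planted-structure table (one row per simulated variant)."""
    vsim.truth.to_csv(path, sep="\t", index=False, lineterminator="\n")


def simulate_run(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full generator and write all outputs into a directory.

    Emits merged and per-biosource BED tracks, the summit track, the GWAS /
    molQTL / pool variant TSVs, the LD table, the ground-truth table, and
    the resolved config (seed included).  Deterministic: the same config
    yields byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    tracks = simulate_tracks(cfg)
    vsim = simulate_variants(cfg, tracks)
    ldsim = simulate_ld(cfg, vsim.gwas, tracks)

    paths: dict[str, Path] = {}
    for name, track in tracks.merged.items():
        p = outdir / "tracks" / f"{name}.merged.bed"
        write_bed(track, p)
        paths[f"track:{name}"] = p
    for name, bs_tracks in tracks.biosources.items():
        for t in bs_tracks:
            p = outdir / "tracks" / f"{t.name}.bed"
            write_bed(t, p)
            paths[f"track:{t.name}"] = p
    p = outdir / "tracks" / "DHS.summits.bed"
    write_summits(tracks.summits, p)
    paths["summits"] = p

    write_variants(vsim.gwas, outdir / "gwas.tsv")
    paths["gwas"] = outdir / "gwas.tsv"
    for assay, vs in vsim.molqtl.items():
        write_variants(vs, outdir / f"molqtl_{assay}.tsv")
        paths[f"molqtl:{assay}"] = outdir / f"molqtl_{assay}.tsv"
    write_variants(vsim.pool, outdir / "snv_pool.tsv")
    paths["pool"] = outdir / "snv_pool.tsv"
    ldsim.table.to_csv(outdir / "ld.tsv", sep="\t", index=False, lineterminator="\n")
    paths["ld"] = outdir / "ld.tsv"
    if len(ldsim.planted):
        ldsim.planted.to_csv(outdir / "ld_planted.tsv", sep="\t", index=False, lineterminator="\n")
        paths["ld_planted"] = outdir / "ld_planted.tsv"
    export_ground_truth(vsim, outdir / "ground_truth.tsv")
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    cfg.to_yaml(outdir / "config.yaml")
    paths["config"] = outdir / "config.yaml"
    return paths
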