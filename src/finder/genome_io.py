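"""Genomic intervals, variant tables, and the overlap primitives.

Coordinate conventions
----------------------
Interval tracks use BED semantics: 0-based, half-open ``[start, end)``.
Variants are stored 1-based (the rsID/VCF convention) and converted to the
half-open point ``[pos-1, pos)`` for overlap purposes.  That conversion
happens in exactly one place (:func:`variant_points`), so the two coordinate
systems never meet anywhere else.

Merging requires at least one shared base pair: book-ended intervals
(``[0,10)`` and ``[10,20)``) share no base and are *not* merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "FeatureTrack",
    "Variant",
    "VariantSet",
    "SummitTrack",
    "GeneModel",
    "BedParseError",
    "SchemaError",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_variants",
    "write_variants",
    "dedup_by_id",
    "merge_track",
    "coverage_fraction",
    "intersect_variants",
    "intersect_tracks",
    "jaccard",
    "nearest_signed_distance",
    "complement_track",
    "read_summits",
    "write_summits",
    "read_gene_model",
    "annotate_variants",
    "variant_points",
]


class BedParseError(ValueError):
    """Raised for malformed interval files (names the offending line)."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks a mandatory column."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class FeatureTrack:
    """A named, sorted collection of genomic intervals for one marker.

    Parameters
    ----------
    name
        Marker label (``DHS``, ``footprint``, ``ATAC``, ``ChIP``, ``eRNA``,
        ``H3K27ac``, or arbitrary).
    df
        DataFrame with at least ``chrom``, ``start``, ``end`` columns.
        Extra columns are preserved but ignored by all overlap logic.
    """

    def __init__(self, name: str, df: pd.DataFrame):
        if not {"chrom", "start", "end"}.issubset(df.columns):
            raise SchemaError("track requires chrom/start/end columns")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError("negative interval start")
            if (df["end"] <= df["start"]).any():
                raise ValueError("interval with end <= start")
        self.name = name
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_arrays(
        cls,
        name: str,
        chroms: Sequence[str] | np.ndarray,
        starts: Sequence[int] | np.ndarray,
        ends: Sequence[int] | np.ndarray,
    ) -> "FeatureTrack":
        return cls(name, pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}))

    @classmethod
    def from_intervals(cls, name: str, intervals: Iterable[GenomicInterval]) -> "FeatureTrack":
        ivs = list(intervals)
        return cls.from_arrays(
            name,
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
        )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTrack):
            return NotImplemented
        a = self.df[["chrom", "start", "end"]]
        b = other.df[["chrom", "start", "end"]]
        return a.equals(b)

    def total_bp(self) -> int:
        """Summed interval length (over possibly overlapping intervals)."""
        return int((self.df["end"] - self.df["start"]).sum())

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in self.df[["chrom", "start", "end"]].itertuples(index=False)
        ]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, in sorted order."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=True):
            out[str(chrom)] = (
                sub["start"].to_numpy(np.int64),
                sub["end"].to_numpy(np.int64),
            )
        return out


@dataclass(frozen=True)
class Variant:
    """A point variant; ``pos`` is 1-based."""

    id: str
    chrom: str
    pos: int
    pvalue: float | None = None
    trait: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty variant id")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")


_VARIANT_COLS = ["id", "chrom", "pos", "pvalue", "trait", "maf"]


class VariantSet:
    """An ordered collection of identified variants with optional annotations.

    Backed by a DataFrame with columns ``id, chrom, pos, pvalue, trait, maf``
    (missing annotations are NaN/None).  Positions are 1-based.
    """

    def __init__(self, df: pd.DataFrame, label: str = ""):
        df = df.copy()
        for col in _VARIANT_COLS:
            if col not in df.columns:
                df[col] = np.nan
        if len(df):
            df["pos"] = df["pos"].astype(np.int64)
            if (df["pos"] < 1).any():
                raise ValueError("variant pos must be >= 1")
            if df["id"].isna().any() or (df["id"].astype(str) == "").any():
                raise ValueError("empty variant id")
            df["id"] = df["id"].astype(str)
            df["chrom"] = df["chrom"].astype(str)
        self.df = df[_VARIANT_COLS + [c for c in df.columns if c not in _VARIANT_COLS]].reset_index(
            drop=True
        )
        self.label = label

    @classmethod
    def from_variants(cls, variants: Iterable[Variant], label: str = "") -> "VariantSet":
        rows = [
            (v.id, v.chrom, v.pos, v.pvalue, v.trait, v.maf) for v in variants
        ]
        return cls(pd.DataFrame(rows, columns=_VARIANT_COLS), label=label)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Series:
        return self.df["id"]

    def id_set(self) -> set[str]:
        return set(self.df["id"])

    def subset(self, mask_or_index) -> "VariantSet":
        return VariantSet(self.df.loc[mask_or_index].reset_index(drop=True), label=self.label)


def variant_points(vs: VariantSet) -> pd.DataFrame:
    """Variants as 0-based half-open points ``[pos-1, pos)``.

    The single place where the 1-based variant convention is converted to
    interval coordinates.
    """
    df = vs.df[["id", "chrom", "pos"]].copy()
    df["start"] = df["pos"] - 1
    df["end"] = df["pos"]
    return df


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED3+ file into a sorted :class:`FeatureTrack`.

    Extra columns beyond the first three are preserved (as ``col4``,
    ``col5``, ...) but ignored by overlap logic.  Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    path = Path(path)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    extras: list[list[str]] = []
    n_extra = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise BedParseError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            extras.append(fields[3:])
            n_extra = max(n_extra, len(fields) - 3)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    for j in range(n_extra):
        df[f"col{j + 4}"] = [row[j] if j < len(row) else "" for row in extras]
    return FeatureTrack(name if name is not None else path.stem, df)


def write_bed(track: FeatureTrack, path: str | Path) -> None:
    """Write a track as sorted, tab-separated BED3 (extra columns dropped)."""
    df = track.df[["chrom", "start", "end"]]
    df.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file -> mapping."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected chrom<TAB>length")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_variants(
    path: str | Path,
    dialect: str = "tsv",
    pvalue_threshold: float = 1e-5,
    inclusive_threshold: bool = False,
    label: str | None = None,
) -> VariantSet:
    """Read a variant table.

    Parameters
    ----------
    dialect
        ``tsv``: header with columns ``id, chrom, pos`` and optionally
        ``pvalue, trait, maf``.
        ``vcf``: standard VCF; only CHROM/POS/ID are parsed.
        ``gwas_catalog``: association-table columns ``id, chrom, pos,
        pvalue, trait``; rows are filtered on the association p value.
    pvalue_threshold, inclusive_threshold
        For the ``gwas_catalog`` dialect only.  The default keeps rows with
        ``p < 1e-5`` (strict); set ``inclusive_threshold`` for ``p <= t``.
    """
    path = Path(path)
    if dialect == "vcf":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    raise SchemaError(f"{path}: VCF row with < 3 fields")
                rows.append((fields[2], fields[0], int(fields[1])))
        df = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
        return VariantSet(df, label=label or path.stem)

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {sorted(missing)}")
    if dialect == "gwas_catalog":
        if "pvalue" not in df.columns:
            raise SchemaError(f"{path}: gwas_catalog dialect requires a pvalue column")
        if inclusive_threshold:
            df = df[df["pvalue"] <= pvalue_threshold]
        else:
            df = df[df["pvalue"] < pvalue_threshold]
    elif dialect != "tsv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    return VariantSet(df.reset_index(drop=True), label=label or path.stem)


def write_variants(vs: VariantSet, path: str | Path) -> None:
    vs.df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def dedup_by_id(vs: VariantSet) -> VariantSet:
    """Collapse to one record per variant id, keeping the first occurrence.

    A duplicate id with a conflicting position triggers a warning; the first
    record wins.
    """
    df = vs.df
    dup = df.duplicated("id", keep="first")
    if dup.any():
        first_pos = df.drop_duplicates("id", keep="first").set_index("id")["pos"]
        conflicts = df.loc[dup]
        bad = conflicts[conflicts["pos"].to_numpy() != first_pos.loc[conflicts["id"]].to_numpy()]
        if len(bad):
            warnings.warn(
                f"{len(bad)} duplicate variant id(s) with conflicting positions; "
                "keeping first occurrence",
                stacklevel=2,
            )
    return VariantSet(df.loc[~dup].reset_index(drop=True), label=vs.label)


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_track(track: FeatureTrack) -> FeatureTrack:
    """Merge intervals that share at least one base pair.

    Book-ended intervals (zero shared bases) are kept separate.  Idempotent;
    total covered bp is preserved.
    """
    if len(track) == 0:
        return FeatureTrack(track.name, track.df[["chrom", "start", "end"]])
    chroms_out: list[str] = []
    starts_out: list[int] = []
    ends_out: list[int] = []
    for chrom, (starts, ends) in track.by_chrom().items():
        # running max of end; a new block begins where start >= max(previous ends)
        run_end = np.maximum.accumulate(ends)
        new_block = np.ones(len(starts), dtype=bool)
        new_block[1:] = starts[1:] >= run_end[:-1]
        block = np.cumsum(new_block) - 1
        n_blocks = block[-1] + 1
        merged_start = np.zeros(n_blocks, dtype=np.int64)
        merged_start[block[new_block]] = starts[new_block]
        merged_end = np.zeros(n_blocks, dtype=np.int64)
        np.maximum.at(merged_end, block, ends)
        chroms_out.extend([chrom] * n_blocks)
        starts_out.extend(merged_start.tolist())
        ends_out.extend(merged_end.tolist())
    return FeatureTrack.from_arrays(track.name, chroms_out, starts_out, ends_out)


def covered_bp(track: FeatureTrack) -> int:
    """Number of distinct bases covered (merges internally)."""
    return merge_track(track).total_bp()


def coverage_fraction(track: FeatureTrack, genome_sizes: Mapping[str, int]) -> float:
    """Fraction of the genome covered by the (merged) track.

    Raises if the track names a chromosome absent from ``genome_sizes``.
    """
    merged = merge_track(track)
    unknown = set(merged.df["chrom"]) - set(genome_sizes)
    if unknown:
        raise ValueError(f"track chromosome(s) not in genome: {sorted(unknown)}")
    total = sum(genome_sizes.values())
    if total <= 0:
        raise ValueError("genome has zero total length")
    return merged.total_bp() / total


def intersect_variants(vs: VariantSet, track: FeatureTrack) -> np.ndarray:
    """Boolean membership vector: variant i overlaps some track interval.

    A variant at 1-based ``pos`` occupies ``[pos-1, pos)``; with a merged,
    sorted track the test is a binary search per variant.  Equivalent to the
    all-pairs overlap check.
    """
    merged = merge_track(track)
    member = np.zeros(len(vs), dtype=bool)
    if len(vs) == 0 or len(merged) == 0:
        return member
    pts = variant_points(vs)
    by_chrom = merged.by_chrom()
    for chrom, idx in pts.groupby("chrom").groups.items():
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        p0 = pts.loc[idx, "start"].to_numpy(np.int64)
        k = np.searchsorted(starts, p0, side="right") - 1
        ok = k >= 0
        ok[ok] = p0[ok] < ends[k[ok]]
        member[np.asarray(idx, dtype=np.intp)] = ok
    return member


def intersect_tracks(a: FeatureTrack, b: FeatureTrack, name: str | None = None) -> FeatureTrack:
    """Base-pair intersection of two tracks (merged output)."""
    am, bm = merge_track(a), merge_track(b)
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    b_by = bm.by_chrom()
    for chrom, (a_s, a_e) in am.by_chrom().items():
        if chrom not in b_by:
            continue
        b_s, b_e = b_by[chrom]
        i = j = 0
        while i < len(a_s) and j < len(b_s):
            lo = max(a_s[i], b_s[j])
            hi = min(a_e[i], b_e[j])
            if lo < hi:
                chroms.append(chrom)
                starts.append(int(lo))
                ends.append(int(hi))
            if a_e[i] <= b_e[j]:
                i += 1
            else:
                j += 1
    return FeatureTrack.from_arrays(name or f"{a.name}&{b.name}", chroms, starts, ends)


def jaccard(a: FeatureTrack, b: FeatureTrack) -> float:
    """Base-pair Jaccard index |A∩B| / |A∪B| of two merged tracks.

    Defined as 0 when both tracks are empty.
    """
    am, bm = merge_track(a), merge_track(b)
    cov_a, cov_b = am.total_bp(), bm.total_bp()
    union_track = merge_track(
        FeatureTrack(
            "union",
            pd.concat(
                [am.df[["chrom", "start", "end"]], bm.df[["chrom", "start", "end"]]],
                ignore_index=True,
            ),
        )
    )
    union = union_track.total_bp()
    if union == 0:
        return 0.0
    inter = cov_a + cov_b - union
    return inter / union


def nearest_signed_distance(
    positions: VariantSet | Mapping[str, Sequence[int]] | pd.DataFrame,
    track: FeatureTrack,
) -> np.ndarray:
    """Signed gap (bp) from each point to the nearest track interval.

    0 when the point lies inside an interval.  Positive when the nearest
    interval lies to the right of the point (downstream in genomic
    orientation), negative when it lies to the left.  Ties prefer downstream.
    Points on chromosomes absent from the track get NaN.

    ``positions`` may be a :class:`VariantSet` or a DataFrame with ``chrom``
    and 1-based ``pos`` columns.
    """
    if isinstance(positions, VariantSet):
        pts = positions.df[["chrom", "pos"]]
    else:
        pts = pd.DataFrame(positions)[["chrom", "pos"]]
    merged = merge_track(track)
    by_chrom = merged.by_chrom()
    out = np.full(len(pts), np.nan)
    for chrom, idx in pts.groupby("chrom").groups.items():
        if chrom not in by_chrom:
            continue
        starts, ends = by_chrom[chrom]
        pos = pts.loc[idx, "pos"].to_numpy(np.int64)
        p0 = pos - 1
        k = np.searchsorted(starts, p0, side="right") - 1
        inside = (k >= 0) & (p0 < ends[np.clip(k, 0, None)])
        # gap to nearest interval on the left (ends[k]) and right (starts[k+1])
        left_gap = np.where(k >= 0, p0 - ends[np.clip(k, 0, None)], np.iinfo(np.int64).max)
        right_idx = k + 1
        has_right = right_idx < len(starts)
        right_gap = np.where(
            has_right, starts[np.clip(right_idx, 0, len(starts) - 1)] - pos, np.iinfo(np.int64).max
        )
        dist = np.where(right_gap <= left_gap, right_gap.astype(float), -left_gap.astype(float))
        dist[inside] = 0.0
        out[np.asarray(idx, dtype=np.intp)] = dist
    return out


def complement_track(track: FeatureTrack, genome_sizes: Mapping[str, int]) -> FeatureTrack:
    """Bases of the genome not covered by the (merged) track."""
    merged = merge_track(track)
    by_chrom = merged.by_chrom()
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    for chrom in sorted(genome_sizes):
        size = genome_sizes[chrom]
        prev = 0
        if chrom in by_chrom:
            for s, e in zip(*by_chrom[chrom]):
                if s > prev:
                    chroms.append(chrom)
                    starts.append(prev)
                    ends.append(int(s))
                prev = max(prev, int(e))
        if prev < size:
            chroms.append(chrom)
            starts.append(prev)
            ends.append(size)
    return FeatureTrack.from_arrays(f"~{track.name}", chroms, starts, ends)


# ---------------------------------------------------------------------------
# Summits
# ---------------------------------------------------------------------------

class SummitTrack:
    """DHS intervals with a summit position and a consensus core per interval.

    Backed by a DataFrame with columns ``chrom, start, end, summit,
    core_start, core_end``; ``summit`` is 1-based and its base
    ``[summit-1, summit)`` lies inside the parent interval; the core is a
    sub-interval of the parent.
    """

    COLS = ["chrom", "start", "end", "summit", "core_start", "core_end"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLS) - set(df.columns)
        if missing:
            raise SchemaError(f"summit track missing column(s) {sorted(missing)}")
        df = df[self.COLS].copy()
        for c in self.COLS[1:]:
            df[c] = df[c].astype(np.int64)
        if len(df):
            if ((df["summit"] - 1 < df["start"]) | (df["summit"] - 1 >= df["end"])).any():
                raise ValueError("summit outside parent interval")
            if (
                (df["core_start"] < df["start"])
                | (df["core_end"] > df["end"])
                | (df["core_end"] <= df["core_start"])
            ).any():
                raise ValueError("core not contained in parent interval")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    def __len__(self) -> int:
        return len(self.df)

    def parent_track(self, name: str = "DHS") -> FeatureTrack:
        return FeatureTrack(name, self.df[["chrom", "start", "end"]])

    def summit_positions(self) -> pd.DataFrame:
        """DataFrame of chrom + 1-based summit pos (for distance queries)."""
        return pd.DataFrame({"chrom": self.df["chrom"], "pos": self.df["summit"]})


def read_summits(path: str | Path) -> SummitTrack:
    """Read a summit BED: chrom, start, end, summit offset[, core_start, core_end].

    The 4th column is the 0-based offset of the summit base from ``start``.
    When core columns are absent the core defaults to the summit base.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 4:
        raise SchemaError(f"{path}: summit BED requires >= 4 columns")
    df = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "start": raw[1].astype(np.int64),
            "end": raw[2].astype(np.int64),
        }
    )
    offset = raw[3].astype(np.int64)
    df["summit"] = df["start"] + offset + 1  # 1-based summit position
    if raw.shape[1] >= 6:
        df["core_start"] = raw[4].astype(np.int64)
        df["core_end"] = raw[5].astype(np.int64)
    else:
        df["core_start"] = df["summit"] - 1
        df["core_end"] = df["summit"]
    return SummitTrack(df)


def write_summits(st: SummitTrack, path: str | Path) -> None:
    out = st.df.copy()
    out["offset"] = out["summit"] - 1 - out["start"]
    out[["chrom", "start", "end", "offset", "core_start", "core_end"]].to_csv(
        path, sep="\t", header=False, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Gene models and annotation
# ---------------------------------------------------------------------------

@dataclass
class Transcript:
    name: str
    chrom: str
    strand: str
    tx_start: int  # 0-based
    tx_end: int
    cds_start: int  # cds_start == cds_end marks a non-coding transcript
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.name}: exon outside transcript bounds")

    @property
    def tss(self) -> int:
        """0-based coordinate of the transcription start base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        """0-based coordinate of the transcription termination base."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


class GeneModel:
    """A set of transcripts used for genomic-location annotation."""

    def __init__(self, transcripts: Sequence[Transcript]):
        self.transcripts = list(transcripts)
        self._by_chrom: dict[str, list[Transcript]] = {}
        for tx in self.transcripts:
            self._by_chrom.setdefault(tx.chrom, []).append(tx)

    def on_chrom(self, chrom: str) -> list[Transcript]:
        return self._by_chrom.get(chrom, [])


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a refFlat-style transcript TSV.

    Header columns: ``name, chrom, strand, tx_start, tx_end, cds_start,
    cds_end, exon_starts, exon_ends`` with exon coordinates as comma-joined
    0-based lists.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {
        "name", "chrom", "strand", "tx_start", "tx_end",
        "cds_start", "cds_end", "exon_starts", "exon_ends",
    }
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: gene model missing column(s) {sorted(missing)}")
    txs = []
    for row in df.itertuples(index=False):
        txs.append(
            Transcript(
                name=str(row.name),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                exon_starts=tuple(int(x) for x in str(row.exon_starts).split(",") if x != ""),
                exon_ends=tuple(int(x) for x in str(row.exon_ends).split(",") if x != ""),
            )
        )
    return GeneModel(txs)


# category precedence, highest first
CATEGORIES = ["promoter-TSS", "5'UTR", "3'UTR", "exon", "intron", "TTS", "intergenic"]
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}


def _classify_against_transcript(
    p0: int, tx: Transcript, promoter_up: int, promoter_down: int, tts_window: int
) -> list[str]:
    """All categories a 0-based point earns from one transcript."""
    cats: list[str] = []
    tss, tts = tx.tss, tx.tts
    if tx.strand == "+":
        prom_lo, prom_hi = tss - promoter_up, tss + promoter_down + 1
    else:
        prom_lo, prom_hi = tss - promoter_down, tss + promoter_up + 1
    if prom_lo <= p0 < prom_hi:
        cats.append("promoter-TSS")
    if tts - tts_window <= p0 <= tts + tts_window:
        cats.append("TTS")
    if tx.tx_start <= p0 < tx.tx_end:
        in_exon = any(s <= p0 < e for s, e in zip(tx.exon_starts, tx.exon_ends))
        if in_exon:
            if tx.cds_start == tx.cds_end:  # non-coding transcript
                cats.append("exon")
            elif p0 < tx.cds_start:
                cats.append("5'UTR" if tx.strand == "+" else "3'UTR")
            elif p0 >= tx.cds_end:
                cats.append("3'UTR" if tx.strand == "+" else "5'UTR")
            else:
                cats.append("exon")
        else:
            cats.append("intron")
    return cats


def annotate_variants(
    vs: VariantSet,
    gm: GeneModel,
    promoter_up: int = 1000,
    promoter_down: int = 100,
    tts_window: int = 100,
) -> pd.Series:
    """Assign one genomic-location category per variant.

    Precedence when categories from different transcripts disagree:
    promoter-TSS > 5'UTR > 3'UTR > exon > intron > TTS > intergenic.
    The promoter window spans ``promoter_up`` bp upstream to
    ``promoter_down`` bp downstream of the TSS (strand-aware); the TTS
    window is symmetric (±``tts_window`` bp).
    """
    out = []
    for row in vs.df.itertuples(index=False):
        p0 = row.pos - 1
        best = "intergenic"
        for tx in gm.on_chrom(row.chrom):
            for cat in _classify_against_transcript(
                p0, tx, promoter_up, promoter_down, tts_window
            ):
                if _PRECEDENCE[cat] < _PRECEDENCE[best]:
                    best = cat
        out.append(best)
    return pd.Series(out, index=vs.df.index, name="annotation")
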