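"""Precision benchmarking of feature combinations against molQTL truth sets.

The central objects are a variant × feature boolean :class:`MembershipMatrix`
and, per (feature combination, truth set), a confusion matrix summarized as
:class:`ComboMetrics`.  A *combination* matches a variant only when the
variant overlaps **every** member feature (AND semantics), so higher-order
combinations are monotonically more selective.

Precision (positive predictive value) is TP/(TP+FP): among candidate
variants that overlap the combination, the fraction that belong to the
truth set.  An empty denominator propagates as missing (NaN), never as 0.
Per truth set, precisions are standardized to Z-scores with the population
standard deviation, and the combination × truth-set Z matrix is clustered
with Ward-D2 linkage on Euclidean distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .genome_io import FeatureTrack, VariantSet, intersect_variants

__all__ = [
    "MembershipMatrix",
    "Combination",
    "ComboMetrics",
    "BenchmarkResult",
    "RandomNullResult",
    "build_membership",
    "enumerate_combinations",
    "combo_members",
    "score_combination",
    "zscore_precision",
    "cluster_combinations",
    "fold_change",
    "run_benchmark",
    "random_null_foldchange",
]


class MembershipMatrix:
    """Boolean variants × features overlap table.

    ``data`` is a DataFrame with unique variant ids as the index, feature
    names as columns, and boolean cells (variant i overlaps feature j).
    """

    def __init__(self, data: pd.DataFrame):
        if data.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        if data.index.duplicated().any():
            raise ValueError("duplicate variant ids")
        self.data = data.astype(bool)

    @property
    def variant_ids(self) -> pd.Index:
        return self.data.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def take(self, row_indexer) -> "MembershipMatrix":
        return MembershipMatrix(self.data.iloc[row_indexer])


@dataclass(frozen=True, order=True)
class Combination:
    """A non-empty subset of feature names; ``order`` is its size."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("combination must be non-empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in combination")
        object.__setattr__(self, "members", tuple(sorted(self.members)))

    @property
    def order(self) -> int:
        return len(self.members)

    def __str__(self) -> str:
        return "+".join(self.members)


@dataclass
class ComboMetrics:
    """Confusion counts and derived scores for one combination × truth set."""

    combination: Combination
    truth_label: str
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @property
    def precision(self) -> float:
        pos = self.TP + self.FP
        return self.TP / pos if pos > 0 else math.nan

    @property
    def recall(self) -> float:
        rel = self.TP + self.FN
        return self.TP / rel if rel > 0 else math.nan

    @property
    def predicted_negative_fraction(self) -> float:
        return (self.FN + self.TN) / self.n if self.n > 0 else math.nan


def build_membership(vs: VariantSet, tracks: Sequence[FeatureTrack]) -> MembershipMatrix:
    """Intersect a deduplicated variant set with each named track."""
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names among tracks")
    cols = {t.name: intersect_variants(vs, t) for t in tracks}
    return MembershipMatrix(pd.DataFrame(cols, index=pd.Index(vs.ids, name="id")))


def enumerate_combinations(
    features: Sequence[str], min_order: int = 1, max_order: int | None = None
) -> list[Combination]:
    """All feature subsets with ``min_order <= |subset| <= max_order``.

    Deterministic order: by subset size, then lexicographic.
    """
    features = sorted(features)
    if max_order is None:
        max_order = len(features)
    if not (1 <= min_order <= max_order <= len(features)):
        raise ValueError(f"invalid order bounds [{min_order}, {max_order}] for {len(features)} features")
    out: list[Combination] = []
    for k in range(min_order, max_order + 1):
        for combo in itertools.combinations(features, k):
            out.append(Combination(combo))
    return out


def combo_members(mm: MembershipMatrix, c: Combination) -> np.ndarray:
    """True where a variant overlaps every member feature of ``c``."""
    unknown = set(c.members) - set(mm.feature_names)
    if unknown:
        raise KeyError(f"unknown feature name(s): {sorted(unknown)}")
    return mm.data[list(c.members)].all(axis=1).to_numpy()


def score_combination(
    candidate: VariantSet,
    members: np.ndarray,
    truth: VariantSet,
    combination: Combination | None = None,
    truth_label: str | None = None,
) -> ComboMetrics:
    """Confusion matrix of a membership vector against a truth set.

    Truth matching is by variant id.  TP are candidate variants that both
    match the combination and belong to the truth set; FN are truth-set
    candidates the combination misses.
    """
    members = np.asarray(members, dtype=bool)
    if len(members) != len(candidate):
        raise ValueError("membership vector not aligned to candidate set")
    in_truth = candidate.ids.isin(truth.id_set()).to_numpy()
    tp = int(np.sum(members & in_truth))
    fp = int(np.sum(members & ~in_truth))
    fn = int(np.sum(~members & in_truth))
    tn = int(np.sum(~members & ~in_truth))
    return ComboMetrics(
        combination=combination if combination is not None else Combination(("signature",)),
        truth_label=truth_label if truth_label is not None else truth.label,
        TP=tp,
        FP=fp,
        FN=fn,
        TN=tn,
    )


def zscore_precision(precisions: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standardize precision values with the population SD.

    Missing (NaN) inputs are excluded from the mean/SD and returned as NaN.
    Raises on fewer than two non-missing values or zero SD (a degenerate
    benchmark where every combination scores alike).
    """
    p = np.asarray(precisions, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum() < 2:
        raise ValueError("need >= 2 non-missing precision values")
    mean = p[ok].mean()
    sd = p[ok].std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance across combinations; Z-scores undefined")
    z = np.full_like(p, np.nan)
    z[ok] = (p[ok] - mean) / sd
    return z


def cluster_combinations(z: pd.DataFrame, k: int = 4) -> tuple[pd.Series, np.ndarray]:
    """Hierarchical clustering of the combination × truth-set Z matrix.

    Agglomerative, Euclidean distance, Ward-D2 linkage (scipy's ``ward`` on
    raw observations matches R ``hclust(..., method="ward.D2")`` on a
    Euclidean distance matrix), cut into ``k`` flat clusters.  Rows with
    missing cells must be imputed or dropped beforehand.
    """
    if z.isna().any().any():
        raise ValueError("Z matrix contains missing cells; impute or drop rows first")
    if k > len(z):
        raise ValueError(f"k={k} exceeds number of rows {len(z)}")
    lk = linkage(z.to_numpy(float), method="ward")
    labels = fcluster(lk, t=k, criterion="maxclust")
    return pd.Series(labels, index=z.index, name="cluster"), lk


def fold_change(precision_with_feature: float, precision_baseline: float) -> float:
    """Precision ratio over the un-intersected candidate set.

    Missing when either input is missing or the baseline is zero.
    """
    if math.isnan(precision_with_feature) or math.isnan(precision_baseline):
        return math.nan
    if precision_baseline == 0:
        return math.nan
    return precision_with_feature / precision_baseline


@dataclass
class BenchmarkResult:
    """Full benchmark of all combinations against all truth sets."""

    metrics: pd.DataFrame  # long table: combination, truth, TP..TN, precision, ...
    zscores: pd.DataFrame  # combinations × truth sets
    clusters: pd.Series | None  # cluster label per combination
    linkage: np.ndarray | None


def run_benchmark(
    candidate: VariantSet,
    tracks: Sequence[FeatureTrack],
    truth_sets: Sequence[VariantSet],
    min_order: int = 1,
    max_order: int | None = None,
    n_clusters: int = 4,
    membership: MembershipMatrix | None = None,
) -> BenchmarkResult:
    """Score every feature combination against every truth set.

    Computes the membership matrix (unless supplied), confusion metrics per
    (combination, truth set), per-truth-set precision Z-scores, and a
    Ward-D2 clustering of the Z matrix (rows with missing precisions are
    dropped from clustering; ``clusters`` is None when fewer than
    ``n_clusters`` complete rows remain).
    """
    mm = membership if membership is not None else build_membership(candidate, tracks)
    combos = enumerate_combinations(mm.feature_names, min_order, max_order)
    rows = []
    for c in combos:
        members = combo_members(mm, c)
        for truth in truth_sets:
            m = score_combination(candidate, members, truth, combination=c)
            rows.append(
                {
                    "combination": str(c),
                    "order": c.order,
                    "truth": m.truth_label,
                    "TP": m.TP,
                    "FP": m.FP,
                    "FN": m.FN,
                    "TN": m.TN,
                    "precision": m.precision,
                    "recall": m.recall,
                    "predicted_negative_fraction": m.predicted_negative_fraction,
                }
            )
    metrics = pd.DataFrame(rows)
    pivot = metrics.pivot(index="combination", columns="truth", values="precision")
    # preserve enumeration order of combinations
    pivot = pivot.loc[[str(c) for c in combos]]
    z = pd.DataFrame(
        {t: zscore_precision(pivot[t].to_numpy()) for t in pivot.columns}, index=pivot.index
    )
    complete = z.dropna()
    clusters = lk = None
    if len(complete) >= n_clusters:
        clusters, lk = cluster_combinations(complete, n_clusters)
    return BenchmarkResult(metrics=metrics, zscores=z, clusters=clusters, linkage=lk)


@dataclass
class RandomNullResult:
    """Mean/SD fold change per (combination, truth) over random subsets."""

    summary: pd.DataFrame  # combination, truth, mean_fold_change, sd_fold_change, n_valid
    n_iterations: int
    sample_size: int
    seed: int


def random_null_foldchange(
    pool: VariantSet,
    sample_size: int,
    iterations: int,
    tracks: Sequence[FeatureTrack],
    combinations: Sequence[Combination],
    truth_sets: Sequence[VariantSet],
    seed: int,
) -> RandomNullResult:
    """Fold change of combination precision over random variant subsets.

    Per iteration, ``sample_size`` variants are drawn from ``pool`` without
    replacement; the baseline precision is the fraction of the sample in the
    truth set, and each combination's fold change is its precision over that
    baseline.  Iterations where a combination has no members (or the
    baseline is zero) contribute missing values for that combination.  The
    global seed expands to per-iteration seeds via a counter, so results are
    reproducible and insensitive to iteration chunking.
    """
    if len(pool) < sample_size:
        raise ValueError("pool smaller than sample_size")
    mm = build_membership(pool, tracks)
    member_cols = {str(c): combo_members(mm, c) for c in combinations}
    truth_flags = {t.label: pool.ids.isin(t.id_set()).to_numpy() for t in truth_sets}

    folds: dict[tuple[str, str], list[float]] = {
        (cn, tn): [] for cn in member_cols for tn in truth_flags
    }
    for it in range(iterations):
        rng = np.random.default_rng([seed, it])
        idx = rng.choice(len(pool), size=sample_size, replace=False)
        for tn, flags in truth_flags.items():
            in_truth = flags[idx]
            baseline = in_truth.mean()
            for cn, members in member_cols.items():
                m = members[idx]
                n_m = m.sum()
                if n_m == 0 or baseline == 0:
                    folds[(cn, tn)].append(math.nan)
                    continue
                precision = (m & in_truth).sum() / n_m
                folds[(cn, tn)].append(precision / baseline)

    rows = []
    n_pool = len(pool)
    for (cn, tn), values in folds.items():
        arr = np.asarray(values, dtype=float)
        ok = ~np.isnan(arr)
        # Whole-pool fold change and its delta-method SE under the null of
        # labels independent of features.  Subsets are drawn from a fixed
        # pool, so iteration means concentrate on the pool's realized fold
        # change; the pool-level SE is the binomial-scale fluctuation of
        # that realization around 1 and must enter any calibration check.
        members = member_cols[cn]
        flags = truth_flags[tn]
        m = int(members.sum())
        t = int(flags.sum())
        if m > 0 and t > 0:
            pool_fold = (flags[members].mean()) / (t / n_pool)
            p = t / n_pool
            null_var = (1 - p) / p * (1 / m - 1 / n_pool)
            null_se = math.sqrt(max(null_var, 0.0))
        else:
            pool_fold = math.nan
            null_se = math.nan
        rows.append(
            {
                "combination": cn,
                "truth": tn,
                "mean_fold_change": arr[ok].mean() if ok.any() else math.nan,
                "sd_fold_change": arr[ok].std(ddof=1) if ok.sum() > 1 else math.nan,
                "n_valid": int(ok.sum()),
                "pool_fold_change": pool_fold,
                "null_se": null_se,
            }
        )
    return RandomNullResult(
        summary=pd.DataFrame(rows),
        n_iterations=iterations,
        sample_size=sample_size,
        seed=seed,
    )
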