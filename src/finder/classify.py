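"""Random-forest classification of molQTL membership from overlap features.

Variants are described by six binary features (overlap with each active
regulatory marker) and labeled by membership in any molQTL truth set.
Classes are balanced by downsampling the majority class to the minority
size *before* the train/test split, a random forest is fit on the training
split, and the held-out accuracy is reported as the predictive value
(AUROC is reported alongside, since accuracy and AUROC can disagree on
binary overlap features).

Feature importance is measured with exact Shapley values.  Because the
feature space is a small set of binary indicators, the interventional
Shapley value can be computed exactly by enumerating all feature
coalitions (2^m subsets) against the empirical background distribution of
feature patterns — no sampling approximation is involved, and the
attributions satisfy the additivity identity exactly:
``base_value + sum_j phi_j(x) = f(x)`` for every sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import train_test_split

from .benchmark import MembershipMatrix
from .genome_io import VariantSet

__all__ = [
    "ClassifierRun",
    "ImportanceResult",
    "make_labels",
    "balance_downsample",
    "train_evaluate",
    "shapley_attributions",
    "feature_importance",
]


def make_labels(vs: VariantSet, truth_sets: Sequence[VariantSet]) -> np.ndarray:
    """True where the variant id belongs to the union of the truth sets."""
    union: set[str] = set()
    for t in truth_sets:
        union |= t.id_set()
    return vs.ids.isin(union).to_numpy()


def balance_downsample(
    X: MembershipMatrix, y: np.ndarray, seed: int
) -> tuple[MembershipMatrix, np.ndarray]:
    """Downsample both classes to the minority-class size.

    Sampling is without replacement and reproducible given ``seed``; row
    order within each class is preserved, positives first.
    """
    y = np.asarray(y, dtype=bool)
    if len(y) != len(X):
        raise ValueError("labels not aligned to matrix rows")
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be non-empty")
    n = min(len(pos_idx), len(neg_idx))
    rng = np.random.default_rng(seed)
    keep_pos = np.sort(rng.choice(pos_idx, size=n, replace=False))
    keep_neg = np.sort(rng.choice(neg_idx, size=n, replace=False))
    keep = np.concatenate([keep_pos, keep_neg])
    return X.take(keep), y[keep]


@dataclass
class ClassifierRun:
    """A fitted balanced random-forest run with its held-out metrics."""

    model: RandomForestClassifier
    feature_names: list[str]
    predictive_value: float  # held-out accuracy (flagged as such in output)
    auroc: float
    test_fraction: float
    seed: int
    X_train: np.ndarray


def train_evaluate(
    X: MembershipMatrix,
    y: np.ndarray,
    test_fraction: float = 0.25,
    seed: int = 0,
    n_estimators: int = 500,
) -> ClassifierRun:
    """Stratified split, forest fit, and held-out metrics on balanced data."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    y = np.asarray(y, dtype=bool)
    Xa = X.data.to_numpy(dtype=np.int8)
    if min(np.sum(y), np.sum(~y)) < 2:
        raise ValueError("too few rows per class for a stratified split")
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xa, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    model.fit(X_tr, y_tr)
    acc = accuracy_score(y_te, model.predict(X_te))
    proba = model.predict_proba(X_te)[:, 1]
    try:
        auroc = roc_auc_score(y_te, proba)
    except ValueError:
        auroc = math.nan
    return ClassifierRun(
        model=model,
        feature_names=X.feature_names,
        predictive_value=float(acc),
        auroc=float(auroc),
        test_fraction=test_fraction,
        seed=seed,
        X_train=X_tr,
    )


def _subset_weights(m: int) -> np.ndarray:
    """Shapley coalition weight |S|!(m-|S|-1)!/m! indexed by |S|."""
    fact = [math.factorial(i) for i in range(m + 1)]
    return np.array([fact[s] * fact[m - s - 1] / fact[m] for s in range(m)])


def shapley_attributions(
    model, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float]:
    """Exact interventional Shapley values for binary feature matrices.

    For each sample x and feature j::

        phi_j(x) = sum over S ⊆ F\\{j} of w(|S|) * (v(S ∪ {j}) − v(S))
        v(S)     = E_b[ f(x_S, b_{F\\S}) ]   over the background rows b

    where f is the model's positive-class probability.  Exhaustive over all
    2^m coalitions; features must be 0/1 and m ≤ 16.  Returns the (n, m)
    attribution matrix and the base value ``E_b[f(b)]``; attributions
    satisfy ``base + phi.sum(1) == f(X)`` exactly (up to float rounding).
    """
    X = np.asarray(X)
    background = np.asarray(background)
    n, m = X.shape
    if m > 16:
        raise ValueError("exact coalition enumeration limited to <= 16 features")
    if not np.isin(X, (0, 1)).all() or not np.isin(background, (0, 1)).all():
        raise ValueError("exact Shapley attribution requires binary features")

    weights_j = (1 << np.arange(m)).astype(np.int64)
    codes_x = X.astype(np.int64) @ weights_j
    codes_bg = background.astype(np.int64) @ weights_j

    # model output for every possible feature pattern, one batched call
    all_patterns = ((np.arange(1 << m)[:, None] >> np.arange(m)) & 1).astype(np.int8)
    f_table = model.predict_proba(all_patterns)[:, 1]

    bg_codes, bg_counts = np.unique(codes_bg, return_counts=True)
    bg_prob = bg_counts / bg_counts.sum()
    base_value = float(f_table[bg_codes] @ bg_prob)

    uniq_x = np.unique(codes_x)
    full = (1 << m) - 1
    # v[mask][x_code] = E_b f[(x & mask) | (b & ~mask)]
    v: dict[int, dict[int, float]] = {}
    for mask in range(1 << m):
        inv = full ^ mask
        bg_part = bg_codes & inv
        vx = {}
        for xc in uniq_x:
            vx[int(xc)] = float(f_table[(xc & mask) | bg_part] @ bg_prob)
        v[mask] = vx

    w = _subset_weights(m)
    phi_by_code: dict[int, np.ndarray] = {}
    for xc in uniq_x:
        phi = np.zeros(m)
        for j in range(m):
            bit = 1 << j
            for mask in range(1 << m):
                if mask & bit:
                    continue
                s = bin(mask).count("1")
                phi[j] += w[s] * (v[mask | bit][int(xc)] - v[mask][int(xc)])
        phi_by_code[int(xc)] = phi
    attributions = np.vstack([phi_by_code[int(c)] for c in codes_x])
    return attributions, base_value


@dataclass
class ImportanceResult:
    """Per-feature signed importance summary, ordered by magnitude."""

    summary: pd.DataFrame  # feature, mean_when_present, mean_abs, rank
    attributions: np.ndarray
    base_value: float


def feature_importance(
    run: ClassifierRun, X: MembershipMatrix | np.ndarray | None = None
) -> ImportanceResult:
    """Exact Shapley importance of each overlap feature.

    The summary statistic per feature is the mean attribution over samples
    where the feature is present (overlap = 1), so a feature whose presence
    pushes predictions toward the positive class gets a positive value and
    an anti-predictive feature a negative one.  Features ranked by absolute
    summary value, descending; background = the training rows.
    """
    if X is None:
        Xa = run.X_train
    elif isinstance(X, MembershipMatrix):
        Xa = X.data.to_numpy(dtype=np.int8)
    else:
        Xa = np.asarray(X)
    phi, base = shapley_attributions(run.model, Xa, run.X_train)
    rows = []
    for j, name in enumerate(run.feature_names):
        present = Xa[:, j] == 1
        rows.append(
            {
                "feature": name,
                "mean_when_present": float(phi[present, j].mean()) if present.any() else math.nan,
                "mean_abs": float(np.abs(phi[:, j]).mean()),
            }
        )
    summary = pd.DataFrame(rows)
    summary["abs_summary"] = summary["mean_when_present"].abs()
    summary = summary.sort_values(
        ["abs_summary", "feature"], ascending=[False, True], kind="mergesort"
    ).drop(columns="abs_summary")
    summary["rank"] = np.arange(1, len(summary) + 1)
    return ImportanceResult(summary=summary.reset_index(drop=True), attributions=phi, base_value=base)
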