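"""Feature filtering, sample intersection, stratified splitting, scaling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MultiOmicsDataset


@dataclass(frozen=True)
class SplitIndex:
    """A disjoint train/test partition of sample IDs."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test IDs overlap")


@dataclass(frozen=True)
class ScalingParams:
    """Per-feature mean and sd estimated on training data (ddof=1)."""

    mean: pd.Series
    sd: pd.Series


def near_zero_variance_filter(
    X: pd.DataFrame,
    unique_cutoff: float = 0.10,
    freq_ratio_cutoff: float = 19.0,
) -> list[str]:
    """Names of features surviving the near-zero-variance filter.

    A feature is removed iff its variance is zero, or it has very few unique
    values relative to the sample count (distinct/n < ``unique_cutoff``) AND
    the frequency of its most common value dominates the second most common
    (ratio > ``freq_ratio_cutoff``, the 95/5 convention).
    """
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if X.shape[1] == 0:
        raise ValueError("empty matrix")
    kept: list[str] = []
    arr = X.to_numpy()
    for j, name in enumerate(X.columns):
        col = arr[:, j]
        values, counts = np.unique(col, return_counts=True)
        if values.size <= 1:
            continue  # zero variance
        frac_unique = values.size / n
        counts_sorted = np.sort(counts)[::-1]
        freq_ratio = counts_sorted[0] / counts_sorted[1]
        if frac_unique < unique_cutoff and freq_ratio > freq_ratio_cutoff:
            continue
        kept.append(name)
    return kept


def apply_blacklist(X: pd.DataFrame, blacklist: set[str]) -> pd.DataFrame:
    """Drop user-supplied feature names (e.g. flagged methylation probes)."""
    keep = [c for c in X.columns if c not in blacklist]
    return X[keep]


def intersect_samples(
    blocks: dict[str, pd.DataFrame], sample_table: pd.DataFrame
) -> MultiOmicsDataset:
    """Restrict all blocks and the sample table to their common sample IDs.

    Ordering follows the first block's index, filtered to the intersection.
    """
    if not blocks:
        raise ValueError("no blocks given")
    common = set(sample_table.index)
    for X in blocks.values():
        common &= set(X.index)
    if not common:
        raise ValueError("empty sample intersection across blocks")
    first = next(iter(blocks.values()))
    order = [s for s in first.index if s in common]
    if len(order) < 5:
        warnings.warn(f"only {len(order)} samples shared across all blocks")
    table = sample_table.loc[order]
    survival = table[["time", "event"]] if {"time", "event"}.issubset(table.columns) else None
    labels = table["class"].copy()
    labels.name = "class"
    return MultiOmicsDataset(
        blocks={k: v.loc[order] for k, v in blocks.items()},
        labels=labels,
        survival=survival,
    )


def stratified_split(labels: pd.Series, train_frac: float = 0.7, seed: int = 0) -> SplitIndex:
    """Stratified train/test partition preserving class proportions.

    Per-class train counts are round(train_frac * n_k) (half away from
    zero), clamped so both sides keep at least one sample; any shortfall or
    overflow against round(train_frac * n) is corrected on the largest class.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = list(dict.fromkeys(labels))
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("every class needs at least 2 samples to split")
    n = len(labels)
    target_total = int(np.floor(train_frac * n + 0.5))
    n_train = {c: int(np.floor(train_frac * counts[c] + 0.5)) for c in classes}
    for c in classes:
        n_train[c] = min(max(n_train[c], 1), counts[c] - 1)
    largest = max(classes, key=lambda c: (counts[c], -classes.index(c)))
    adj = target_total - sum(n_train.values())
    n_train[largest] = min(max(n_train[largest] + adj, 1), counts[largest] - 1)

    train: list[str] = []
    test: list[str] = []
    for c in classes:
        ids = sorted(labels.index[labels == c])
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        train.extend(shuffled[: n_train[c]])
        test.extend(shuffled[n_train[c] :])
    return SplitIndex(train_ids=tuple(train), test_ids=tuple(test), seed=seed)


def center_scale(X_train: pd.DataFrame) -> tuple[pd.DataFrame, ScalingParams]:
    """Standardize training columns to mean 0, sd 1 (unbiased sd, ddof=1)."""
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=1)
    if (sd <= 0).any():
        bad = list(sd.index[sd <= 0][:5])
        raise ValueError(f"zero-variance features cannot be scaled: {bad}")
    params = ScalingParams(mean=mean, sd=sd)
    return (X_train - mean) / sd, params


def apply_scaling(X: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Transform ``X`` with training means/sds (test-set standardization)."""
    missing = params.mean.index.difference(X.columns)
    if len(missing):
        raise ValueError(f"features missing from input: {list(missing[:5])}")
    X = X[params.mean.index]
    return (X - params.mean) / params.sd
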