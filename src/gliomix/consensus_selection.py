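"""Stability-based consensus feature selection over repeated data partitions.

The tuned model is refit on (by default) 30 stratified 70/30 partitions;
features are scored by how often their loading is nonzero and by the median
absolute loading over the partitions where they were selected, then kept by
the two-clause frequency/median rule. Each kept feature is finally assigned
the outcome class it discriminates, with a modality-specific rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification
from .model_selection import design_from_blocks
from .preprocess import apply_scaling, center_scale, stratified_split
from .sgcca_core import fit_sgcca, transform


@dataclass
class StabilityRecord:
    """Selection history of one feature on one block/component."""

    block: str
    component: int               # 1-based
    feature: str
    loadings: list[float] = field(default_factory=list)  # |loading| when selected

    @property
    def frequency(self) -> int:
        return len(self.loadings)

    @property
    def median_abs_loading(self) -> float:
        return float(np.median(self.loadings)) if self.loadings else 0.0


@dataclass
class SelectedFeature:
    record: StabilityRecord
    rule_clause: str             # which threshold clause admitted it
    outcome: str | None = None
    low_confidence: bool = False

    @property
    def feature(self) -> str:
        return self.record.feature

    @property
    def block(self) -> str:
        return self.record.block


def repeated_fit(
    blocks: dict[str, pd.DataFrame],
    labels: pd.Series,
    keepX: list[dict[str, int]],
    H: int | None = None,
    design: pd.DataFrame | None = None,
    n_partitions: int = 30,
    train_frac: float = 0.7,
    base_seed: int = 0,
) -> tuple[list[StabilityRecord], list[classification.PerformanceReport]]:
    """Refit on ``n_partitions`` stratified splits and accumulate loadings.

    Partition p uses seed ``base_seed + p``. keepX is taken as tuned once
    beforehand and held fixed. Returns the per-feature stability records and
    the per-partition test-set performance reports.
    """
    if H is None:
        H = len(keepX)
    records: dict[tuple[str, int, str], StabilityRecord] = {}
    reports: list[classification.PerformanceReport] = []
    for part in range(n_partitions):
        split = stratified_split(labels, train_frac=train_frac, seed=base_seed + part)
        train_std, scalings = {}, {}
        for b, X in blocks.items():
            train_std[b], scalings[b] = center_scale(X.loc[list(split.train_ids)])
        C = design if design is not None else design_from_blocks(train_std)
        model = fit_sgcca(train_std, labels.loc[list(split.train_ids)], C, keepX, H,
                          scaling=scalings)
        test_std = {
            b: apply_scaling(blocks[b].loc[list(split.test_ids)], scalings[b])
            for b in blocks
        }
        scores = transform(model, test_std)
        preds = {
            b: classification.predict_block(model.centroids[b], scores[b], model.classes)
            for b in blocks
        }
        final = classification.weighted_vote(preds, model.block_weights)
        reports.append(
            classification.performance_metrics(
                labels.loc[list(split.test_ids)], final, classes=model.classes
            )
        )
        for b in model.block_names:
            for h in range(H):
                a = model.loadings[b][:, h]
                for j in np.nonzero(a)[0]:
                    key = (b, h + 1, model.feature_names[b][j])
                    rec = records.get(key)
                    if rec is None:
                        rec = records[key] = StabilityRecord(b, h + 1, key[2])
                    rec.loadings.append(abs(float(a[j])))
    return list(records.values()), reports


def select_consensus(
    records: list[StabilityRecord],
    f1: int = 15,
    m1: float = 0.05,
    f2: int = 10,
    m2: float = 0.2,
) -> list[SelectedFeature]:
    """Two-clause consensus rule with strict inequalities.

    Keep a record iff (frequency > f1 and median > m1) or
    (frequency > f2 and median > m2).
    """
    out = []
    for rec in records:
        fq, med = rec.frequency, rec.median_abs_loading
        if fq > f1 and med > m1:
            out.append(SelectedFeature(rec, rule_clause="frequency"))
        elif fq > f2 and med > m2:
            out.append(SelectedFeature(rec, rule_clause="magnitude"))
    return out


def consensus_feature_sets(selected: list[SelectedFeature]) -> dict[str, set[str]]:
    """Union over components of the selected feature names, per block."""
    out: dict[str, set[str]] = {}
    for sf in selected:
        out.setdefault(sf.block, set()).add(sf.feature)
    return out


def assign_outcome_expression(
    feature: str, de_results: dict[tuple[str, str], pd.DataFrame], classes: list[str]
) -> tuple[str, bool]:
    """Outcome class of an expression feature from pairwise DE results.

    ``de_results[(a, b)]`` must hold gene-indexed logFC (oriented a over b)
    and FDR for every unordered class pair. A class qualifies when both of
    its contrasts are significant (FDR < 0.05) with a consistent logFC sign;
    its score is the smaller |logFC|. The qualifying class with the largest
    score wins. If none qualifies, the contrast with the smallest FDR
    decides: the class with the higher expression in that pair, flagged as
    low confidence.
    """
    def row(a: str, b: str) -> tuple[float, float]:
        """(logFC of a over b, FDR) for this feature."""
        if (a, b) in de_results:
            df = de_results[(a, b)]
            if feature not in df.index:
                raise KeyError(f"feature {feature!r} missing from contrast ({a}, {b})")
            return float(df.loc[feature, "logFC"]), float(df.loc[feature, "FDR"])
        if (b, a) in de_results:
            df = de_results[(b, a)]
            if feature not in df.index:
                raise KeyError(f"feature {feature!r} missing from contrast ({b}, {a})")
            return -float(df.loc[feature, "logFC"]), float(df.loc[feature, "FDR"])
        raise KeyError(f"missing contrast for pair ({a}, {b})")

    scores: dict[str, float] = {}
    for k in classes:
        rows = [row(k, j) for j in classes if j != k]
        fdrs = [r[1] for r in rows]
        lfcs = [r[0] for r in rows]
        if all(f < 0.05 for f in fdrs) and (all(l > 0 for l in lfcs) or all(l < 0 for l in lfcs)):
            scores[k] = min(abs(l) for l in lfcs)
    if scores:
        best = max(scores.values())
        winners = [k for k in classes if scores.get(k) == best]
        return winners[0], len(winners) > 1
    # fallback: smallest-FDR contrast decides
    best_pair, best_fdr, best_lfc = None, np.inf, 0.0
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            lfc, fdr = row(a, b)
            if fdr < best_fdr:
                best_pair, best_fdr, best_lfc = (a, b), fdr, lfc
    a, b = best_pair
    if best_lfc == 0.0:
        return classes[0], True
    return (a if best_lfc > 0 else b), True


def assign_outcome_methylation(class_means: dict[str, float]) -> tuple[str, bool]:
    """Class with the highest mean |beta difference| to the other classes."""
    classes = list(class_means)
    d = {
        k: np.mean([abs(class_means[k] - class_means[j]) for j in classes if j != k])
        for k in classes
    }
    best = max(d.values())
    winners = [k for k in classes if d[k] == best]
    return winners[0], len(winners) > 1


def assign_outcome_mirna(class_means: dict[str, float]) -> tuple[str, bool]:
    """Class with the higher mean expression (two-class rule)."""
    if len(class_means) != 2:
        raise ValueError("miRNA outcome rule is defined for exactly 2 classes")
    classes = list(class_means)
    best = max(class_means.values())
    winners = [k for k in classes if class_means[k] == best]
    return winners[0], len(winners) > 1


def consensus_table(selected: list[SelectedFeature]) -> pd.DataFrame:
    """Flat TSV-ready table of the consensus selection."""
    rows = [
        {
            "block": sf.block,
            "component": sf.record.component,
            "feature": sf.feature,
            "frequency": sf.record.frequency,
            "median_abs_loading": sf.record.median_abs_loading,
            "outcome": sf.outcome,
            "rule_clause": sf.rule_clause,
            "low_confidence": sf.low_confidence,
        }
        for sf in selected
    ]
    return pd.DataFrame(rows)
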