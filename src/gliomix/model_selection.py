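"""Data-driven design matrix and cross-validated sparsity tuning.

The design matrix linking omics blocks is set from a preliminary pairwise
PLS: the first-component score correlation r of each block pair is rounded
down to one decimal, floor(10|r|)/10, and every block is fully connected
(weight 1) to the class-dummy outcome block. The per-block, per-component
feature counts (keepX) are tuned one component at a time on a coarse grid
refined by step halving, scoring each candidate by repeated stratified
cross-validation of the full centroid + weighted-vote classification path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classification
from .preprocess import center_scale, apply_scaling
from .sgcca_core import OUTCOME, fit_sgcca, transform


def pls_pairwise_correlation(X1, X2) -> float:
    """First-component PLS score correlation between two standardized blocks.

    One component maximizing cov(X1 a, X2 b) with unit-norm a, b is the
    rank-1 SVD of X1'X2; returns the Pearson correlation of the two score
    vectors.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    M = X1.T @ X2
    if not np.any(M):
        raise ValueError("zero cross-covariance between blocks")
    u, _, vt = np.linalg.svd(M, full_matrices=False)
    t1 = X1 @ u[:, 0]
    t2 = X2 @ vt[0]
    if np.std(t1) == 0 or np.std(t2) == 0:
        raise ValueError("degenerate PLS scores")
    return float(np.corrcoef(t1, t2)[0, 1])


def design_from_correlations(r_map: dict, block_names: list[str]) -> pd.DataFrame:
    """Design matrix with c_qj = floor(10|r_qj|)/10 and weight 1 to the outcome.

    ``r_map`` maps unordered block-name pairs (tuples, either order) to r.
    """
    names = list(block_names) + [OUTCOME]
    C = pd.DataFrame(0.0, index=names, columns=names)
    for q, j in itertools.combinations(block_names, 2):
        r = r_map.get((q, j), r_map.get((j, q)))
        if r is None:
            raise KeyError(f"no correlation given for pair ({q}, {j})")
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
        # tiny epsilon guards against 10*0.7 = 6.999... landing one bin low
        c = np.floor(10.0 * abs(r) + 1e-9) / 10.0
        C.loc[q, j] = C.loc[j, q] = min(c, 1.0)
    for q in block_names:
        C.loc[q, OUTCOME] = C.loc[OUTCOME, q] = 1.0
    return C


def design_from_blocks(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Convenience: pairwise PLS on standardized blocks, then the rounding rule."""
    names = list(blocks)
    r_map = {}
    for q, j in itertools.combinations(names, 2):
        r_map[(q, j)] = pls_pairwise_correlation(blocks[q], blocks[j])
    if len(names) == 1:
        return design_from_correlations({}, names)
    return design_from_correlations(r_map, names)


def _stratified_folds(labels: pd.Series, folds: int, rng: np.random.Generator):
    """Fold assignment per sample ID, stratified by class; returns dict id->fold."""
    assign: dict[str, int] = {}
    for c in sorted(set(labels)):
        ids = sorted(labels.index[labels == c])
        if len(ids) < folds:
            raise ValueError(f"class {c!r} smaller than the fold count")
        perm = rng.permutation(len(ids))
        for pos, i in enumerate(perm):
            assign[ids[i]] = pos % folds
    return assign


def cv_error(
    blocks: dict[str, pd.DataFrame],
    labels: pd.Series,
    keepX: list[dict[str, int]],
    H: int | None = None,
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    design: pd.DataFrame | None = None,
) -> float:
    """Mean overall misclassification error of the full classification path.

    Stratified ``folds``-fold CV repeated ``repeats`` times: each held-out
    fold is standardized with training statistics, projected through a model
    fit on the training folds, and classified by per-block centroid distance
    fused by weighted vote. Blocks must be raw (unstandardized) and
    sample-aligned with ``labels``.
    """
    if H is None:
        H = len(keepX)
    # canonical sample order: the fold assignment and every downstream
    # computation then depend only on sample IDs, not input row order
    labels = labels.loc[sorted(labels.index)]
    rng = np.random.default_rng(seed)
    errors = []
    for _ in range(repeats):
        assign = _stratified_folds(labels, folds, rng)
        fold_err = []
        for f in range(folds):
            test_ids = [s for s in labels.index if assign[s] == f]
            train_ids = [s for s in labels.index if assign[s] != f]
            err = _fit_predict_error(blocks, labels, train_ids, test_ids, keepX, H, design)
            fold_err.append(err)
        errors.append(np.mean(fold_err))
    return float(np.mean(errors))


def _fit_predict_error(blocks, labels, train_ids, test_ids, keepX, H, design):
    train_std, scalings = {}, {}
    for b, X in blocks.items():
        train_std[b], scalings[b] = center_scale(X.loc[train_ids])
    C = design if design is not None else design_from_blocks(train_std)
    model = fit_sgcca(train_std, labels.loc[train_ids], C, keepX, H, scaling=scalings)
    test_std = {b: apply_scaling(blocks[b].loc[test_ids], scalings[b]) for b in blocks}
    scores = transform(model, test_std)
    preds = {
        b: classification.predict_block(model.centroids[b], scores[b], model.classes)
        for b in blocks
    }
    final = classification.weighted_vote(preds, model.block_weights)
    return float(np.mean(final != np.asarray(labels.loc[test_ids])))


@dataclass
class TuningResult:
    keepX: list[dict[str, int]]                      # chosen, one dict per component
    error_surface: list[dict[tuple, float]] = field(default_factory=list)
    grids_visited: list[list[tuple]] = field(default_factory=list)
    seed: int = 0


def tune_keepX(
    blocks: dict[str, pd.DataFrame],
    labels: pd.Series,
    H: int,
    initial_grid: list[int],
    folds: int = 5,
    repeats: int = 5,
    seed: int = 0,
    design: pd.DataFrame | None = None,
) -> TuningResult:
    """Coarse-to-fine CV tuning of keepX, one component at a time.

    Component h is tuned with components > h absent and components < h fixed
    at their chosen values. Each grid is the Cartesian product of the
    candidate counts over blocks; the minimizer (ties to the smallest total
    feature count, then lexicographic order) is refined with step halving
    until the step reaches 1 or the winner stops moving.
    """
    grid0 = sorted(set(int(g) for g in initial_grid))
    if not grid0:
        raise ValueError("empty grid")
    names = list(blocks)
    p = {b: blocks[b].shape[1] for b in names}
    if any(g > min(p.values()) for g in grid0):
        raise ValueError("grid values exceed a block's feature count")

    chosen: list[dict[str, int]] = []
    surfaces: list[dict[tuple, float]] = []
    visited: list[list[tuple]] = []

    for h in range(H):
        surface: dict[tuple, float] = {}
        seen: list[tuple] = []

        def evaluate(candidates: list[list[int]]) -> tuple:
            best, best_key = None, None
            for combo in itertools.product(*candidates):
                if combo not in surface:
                    kx = chosen + [dict(zip(names, combo))]
                    surface[combo] = cv_error(
                        blocks, labels, kx, h + 1, folds, repeats, seed, design
                    )
                    seen.append(combo)
                key = (surface[combo], sum(combo), combo)
                if best_key is None or key < best_key:
                    best, best_key = combo, key
            return best

        winner = evaluate([grid0 for _ in names])
        gaps = np.diff(grid0)
        step = int(max(gaps)) // 2 if len(grid0) > 1 else 0
        lo, hi = grid0[0], grid0[-1]  # refinement stays inside the coarse span
        while step >= 1:
            cands = [
                sorted({max(lo, w - step), w, min(p[b], hi, w + step)})
                for b, w in zip(names, winner)
            ]
            new_winner = evaluate(cands)
            if new_winner == winner:
                step //= 2
            winner = new_winner
        chosen.append(dict(zip(names, winner)))
        surfaces.append(surface)
        visited.append(seen)
    return TuningResult(keepX=chosen, error_surface=surfaces, grids_visited=visited, seed=seed)


def choose_ncomp(K: int, override: int | None = None) -> int:
    """Number of components: K-1 (sufficient for K-class discrimination)."""
    if K < 2:
        raise ValueError("need at least 2 classes")
    if override is not None:
        if override < 1:
            raise ValueError("component count must be positive")
        return int(override)
    return K - 1
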