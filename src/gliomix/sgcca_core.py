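"""Supervised sparse generalized CCA over omics blocks plus a class-dummy block.

The model maximizes the design-weighted sum of pairwise covariances between
block component scores,

    max_{a^(1)..a^(Q)}  sum_{q != j} c_qj * cov(X^(q) a^(q), X^(j) a^(j)),
    s.t. ||a^(q)||_2 = 1,  ||a^(q)||_0 <= keepX_q   (data blocks),

where one block is the centered class-indicator (dummy) matrix Y, which is
unpenalized. Sparsity is parameterized by the number of features to keep per
block and per component (keepX) and enforced by soft-thresholding inside a
block-coordinate ascent; components beyond the first are obtained by
regression deflation of each block on its own scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ScalingParams, apply_scaling

OUTCOME = "outcome"


@dataclass(frozen=True)
class DummyOutcome:
    """Class-indicator outcome block: raw 0/1 matrix and its centered copy."""

    classes: tuple[str, ...]
    Y: np.ndarray           # n x K, one 1 per row
    Y_centered: np.ndarray  # column-centered copy used in fitting


def dummy_matrix(labels) -> DummyOutcome:
    """Build the 0/1 class-membership matrix, classes in first-appearance order."""
    labels = list(labels)
    classes = tuple(dict.fromkeys(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    col = {c: k for k, c in enumerate(classes)}
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, col[lab]] = 1.0
    return DummyOutcome(classes=classes, Y=Y, Y_centered=Y - Y.mean(axis=0))


def soft_threshold_to_cardinality(z: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """Soft-threshold ``z`` so at most ``k`` entries survive, then l2-normalize.

    The threshold tau is the (k+1)-th largest |z| (0 when k = len(z)), so the
    result sign(z)*max(|z|-tau, 0) has exactly k nonzeros in the absence of
    ties at tau. Returns (vector, degenerate) where degenerate flags an
    all-zero input (the vector is then all-zero too).
    """
    z = np.asarray(z, dtype=float)
    p = z.size
    if not 1 <= k <= p:
        raise ValueError("need 1 <= k <= len(z)")
    absz = np.abs(z)
    if not absz.any():
        return np.zeros(p), True
    if k == p:
        tau = 0.0
    else:
        tau = np.partition(absz, p - k - 1)[p - k - 1]
    v = np.sign(z) * np.maximum(absz - tau, 0.0)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        # all surviving magnitudes tied with tau; fall back to the single
        # largest entry (lowest index on ties) so the update stays usable
        j = int(np.argmax(absz))
        v[j] = np.sign(z[j])
        norm = 1.0
    return v / norm, False


@dataclass
class ComponentFit:
    loadings: dict[str, np.ndarray]   # block -> loading vector (incl. OUTCOME)
    scores: dict[str, np.ndarray]     # block -> score vector t = X a
    converged: bool
    n_iter: int
    objective_path: list[float]
    degenerate: bool = False


def objective(
    mats: dict[str, np.ndarray], loadings: dict[str, np.ndarray], C: pd.DataFrame
) -> float:
    """Design-weighted sum over unordered block pairs of cov(t_q, t_j), ddof=1."""
    names = [b for b in C.index if b in mats]
    n = next(iter(mats.values())).shape[0]
    t = {}
    for b in names:
        if mats[b].shape[1] != loadings[b].size:
            raise ValueError(f"loading length mismatch for block {b!r}")
        t[b] = mats[b] @ loadings[b]
    total = 0.0
    for i, q in enumerate(names):
        for j_ in names[i + 1 :]:
            c = float(C.loc[q, j_])
            if c == 0.0:
                continue
            tq = t[q] - t[q].mean()
            tj = t[j_] - t[j_].mean()
            total += c * float(tq @ tj) / (n - 1)
    return total


def fit_component(
    blocks: dict[str, np.ndarray],
    Y_centered: np.ndarray,
    C: pd.DataFrame,
    keepX: dict[str, int],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ComponentFit:
    """One sparse GCCA component by block-coordinate ascent.

    Each data block's loading is initialized to its first right singular
    vector; updates soft-threshold z = X^(q)' sum_j c_qj t^(j) to the keepX
    cardinality (the outcome block is only normalized). A block update is
    kept only when it does not decrease the block's partial objective z'a,
    which makes the overall objective non-decreasing across iterations. The
    final sign of each loading is fixed so its largest-|entry| is positive.
    """
    names = list(blocks)
    mats = dict(blocks)
    mats[OUTCOME] = Y_centered
    a: dict[str, np.ndarray] = {}
    for b, X in mats.items():
        # first right singular vector, deterministic start
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        a[b] = vt[0]
    t = {b: mats[b] @ a[b] for b in mats}

    degenerate = False
    # recorded from the end of the first sweep on, i.e. once every block's
    # loading satisfies its cardinality bound; non-decreasing from there
    obj_path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        delta = 0.0
        # outcome first: its loading is then driven by the signal-rich
        # initial data-block scores rather than by class sizes alone
        for b in [OUTCOME] + names:
            z = np.zeros(mats[b].shape[0])
            for j_ in mats:
                if j_ == b:
                    continue
                c = float(C.loc[b, j_])
                if c:
                    z = z + c * t[j_]
            z = mats[b].T @ z
            if b == OUTCOME:
                norm = np.linalg.norm(z)
                if norm == 0.0:
                    degenerate = True
                    continue
                a_new = z / norm
            else:
                a_new, deg = soft_threshold_to_cardinality(z, keepX[b])
                if deg:
                    degenerate = True
                    continue
                # ascent guard: once the previous loading is itself feasible
                # (cardinality <= keepX; the dense SVD start is not), keep it
                # if the thresholded update would lower this block's term
                feasible_old = np.count_nonzero(a[b]) <= keepX[b]
                if feasible_old and float(z @ a_new) < float(z @ a[b]) - 1e-12:
                    a_new = a[b]
            diff = min(
                np.max(np.abs(a_new - a[b])), np.max(np.abs(a_new + a[b]))
            )
            delta = max(delta, diff)
            a[b] = a_new
            t[b] = mats[b] @ a[b]
        obj_path.append(objective(mats, a, C))
        if delta < tol:
            converged = True
            break
    if not converged and max_iter > 0:
        warnings.warn(f"sparse GCCA component did not converge in {max_iter} iterations")

    for b in a:
        j = int(np.argmax(np.abs(a[b])))
        if a[b][j] < 0:
            a[b] = -a[b]
            t[b] = -t[b]
    return ComponentFit(
        loadings=a, scores=t, converged=converged, n_iter=it,
        objective_path=obj_path, degenerate=degenerate,
    )


def deflate(X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regress X on the score vector t and remove the fit.

    Returns (X - t b, b) with b = (t't)^-1 t'X, so t is orthogonal to every
    column of the deflated matrix; b is stored for out-of-sample projection.
    """
    tt = float(t @ t)
    if tt == 0.0:
        raise ValueError("cannot deflate by a zero score vector")
    b = (t @ X) / tt
    return X - np.outer(t, b), b


@dataclass
class SGCCAModel:
    """Fitted supervised sparse GCCA model with everything needed to predict."""

    block_names: list[str]
    classes: list[str]
    H: int
    feature_names: dict[str, list[str]]
    loadings: dict[str, np.ndarray]          # block -> (p, H)
    deflation: dict[str, np.ndarray]         # block -> (H, p)
    outcome_loadings: np.ndarray             # (K, H)
    outcome_deflation: np.ndarray            # (H, K)
    design: pd.DataFrame
    train_scores: dict[str, np.ndarray]      # block -> (n, H)
    centroids: dict[str, np.ndarray]         # block -> (K, H)
    block_weights: dict[str, float]
    scaling: dict[str, ScalingParams] | None = None
    keepX: list[dict[str, int]] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_names": self.block_names,
            "classes": self.classes,
            "H": self.H,
            "feature_names": self.feature_names,
            "loadings": {b: v.tolist() for b, v in self.loadings.items()},
            "deflation": {b: v.tolist() for b, v in self.deflation.items()},
            "outcome_loadings": self.outcome_loadings.tolist(),
            "outcome_deflation": self.outcome_deflation.tolist(),
            "design": {
                "names": list(self.design.index),
                "values": self.design.to_numpy().tolist(),
            },
            "centroids": {b: v.tolist() for b, v in self.centroids.items()},
            "block_weights": self.block_weights,
            "keepX": self.keepX,
            "converged": self.converged,
            "scaling": None
            if self.scaling is None
            else {
                b: {"mean": p.mean.tolist(), "sd": p.sd.tolist()}
                for b, p in self.scaling.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SGCCAModel":
        d = json.loads(Path(path).read_text())
        design = pd.DataFrame(
            np.asarray(d["design"]["values"]),
            index=d["design"]["names"],
            columns=d["design"]["names"],
        )
        scaling = None
        if d["scaling"] is not None:
            scaling = {
                b: ScalingParams(
                    mean=pd.Series(s["mean"], index=d["feature_names"][b]),
                    sd=pd.Series(s["sd"], index=d["feature_names"][b]),
                )
                for b, s in d["scaling"].items()
            }
        return cls(
            block_names=d["block_names"],
            classes=d["classes"],
            H=d["H"],
            feature_names=d["feature_names"],
            loadings={b: np.asarray(v) for b, v in d["loadings"].items()},
            deflation={b: np.asarray(v) for b, v in d["deflation"].items()},
            outcome_loadings=np.asarray(d["outcome_loadings"]),
            outcome_deflation=np.asarray(d["outcome_deflation"]),
            design=design,
            train_scores={},
            centroids={b: np.asarray(v) for b, v in d["centroids"].items()},
            block_weights=d["block_weights"],
            scaling=scaling,
            keepX=d["keepX"],
            converged=d["converged"],
        )

    def selected_features(self) -> dict[str, dict[int, list[str]]]:
        """block -> component (1-based) -> nonzero-loading feature names."""
        out: dict[str, dict[int, list[str]]] = {}
        for b in self.block_names:
            out[b] = {}
            for h in range(self.H):
                nz = np.nonzero(self.loadings[b][:, h])[0]
                out[b][h + 1] = [self.feature_names[b][j] for j in nz]
        return out


def fit_sgcca(
    blocks: dict[str, pd.DataFrame],
    labels,
    C: pd.DataFrame,
    keepX: list[dict[str, int]],
    H: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    scaling: dict[str, ScalingParams] | None = None,
) -> SGCCAModel:
    """Fit H sparse GCCA components with per-block regression deflation.

    ``blocks`` must already be standardized and sample-aligned; ``keepX`` is
    one dict (block -> count) per component. Centroids and block weights for
    the downstream weighted-vote classifier are computed on training scores.
    """
    from . import classification  # local import to avoid a cycle

    if H is None:
        H = len(keepX)
    if H < 1 or len(keepX) != H:
        raise ValueError("keepX must list one dict per component")
    names = list(blocks)
    feature_names = {b: list(blocks[b].columns) for b in names}
    dummy = dummy_matrix(labels)
    mats = {b: blocks[b].to_numpy(dtype=float) for b in names}
    Yc = dummy.Y_centered.copy()

    loadings = {b: [] for b in names}
    deflation = {b: [] for b in names}
    out_loadings, out_deflation = [], []
    train_scores = {b: [] for b in names}
    converged = []
    for h in range(H):
        fit = fit_component(mats, Yc, C, keepX[h], tol=tol, max_iter=max_iter)
        converged.append(fit.converged)
        for b in names:
            loadings[b].append(fit.loadings[b])
            train_scores[b].append(fit.scores[b])
            mats[b], bcoef = deflate(mats[b], fit.scores[b])
            deflation[b].append(bcoef)
        out_loadings.append(fit.loadings[OUTCOME])
        Yc, bY = deflate(Yc, fit.scores[OUTCOME])
        out_deflation.append(bY)

    scores = {b: np.column_stack(train_scores[b]) for b in names}
    centroids = {
        b: classification.class_centroids(scores[b], list(labels), list(dummy.classes))
        for b in names
    }
    weights = classification.block_weights_from_scores(scores, dummy.Y_centered)
    return SGCCAModel(
        block_names=names,
        classes=list(dummy.classes),
        H=H,
        feature_names=feature_names,
        loadings={b: np.column_stack(loadings[b]) for b in names},
        deflation={b: np.vstack(deflation[b]) for b in names},
        outcome_loadings=np.column_stack(out_loadings),
        outcome_deflation=np.vstack(out_deflation),
        design=C,
        train_scores=scores,
        centroids=centroids,
        block_weights=weights,
        scaling=scaling,
        keepX=[{b: int(k[b]) for b in names} for k in keepX],
        converged=converged,
    )


def transform(
    model: SGCCAModel, new_blocks: dict[str, pd.DataFrame], scaled: bool = True
) -> dict[str, np.ndarray]:
    """Project new samples onto the model's components, block by block.

    Replays the training deflation: t_h = X a_h, then X <- X - t_h b_h with
    the stored regression coefficients. If ``scaled`` is False the model's
    training ScalingParams are applied first.
    """
    out: dict[str, np.ndarray] = {}
    for b in model.block_names:
        X = new_blocks[b]
        if not scaled:
            if model.scaling is None:
                raise ValueError("model carries no scaling parameters")
            X = apply_scaling(X, model.scaling[b])
        X = X[model.feature_names[b]] if isinstance(X, pd.DataFrame) else X
        X = np.asarray(X, dtype=float).copy()
        if X.shape[1] != len(model.feature_names[b]):
            raise ValueError(f"block {b!r} feature mismatch")
        ts = []
        for h in range(model.H):
            t = X @ model.loadings[b][:, h]
            X -= np.outer(t, model.deflation[b][h])
            ts.append(t)
        out[b] = np.column_stack(ts)
    return out
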