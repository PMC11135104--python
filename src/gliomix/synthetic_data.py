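"""Class-structured multi-omics simulator with known discriminative features.

The generator emulates the statistical structure of a multi-class tumour
multi-omics study: K classes separated along K-1 latent factors, Q blocks
(log-expression-like Gaussian, methylation-like beta values, RNA-seq-like
negative-binomial counts) whose informative features load sparsely on the
shared latent factors, and exponential survival times driven by the first
latent factor with independent uniform censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .containers import MultiOmicsDataset

# baseline log mean count for "counts" blocks; ~150 counts per gene per sample
_COUNT_LOG_BASE = 5.0


@dataclass(frozen=True)
class BlockSpec:
    """Configuration for one simulated omics block.

    Parameters
    ----------
    name : block name (used as key / file name).
    p : number of features.
    n_informative : number of features loading on the latent factors.
    kind : 'gaussian' (log-expression-like), 'beta' (methylation beta values)
        or 'counts' (negative-binomial RNA-seq counts).
    loading_scale : magnitude of the informative loadings.
    noise_sd : standard deviation of the additive feature-level noise
        (on the latent/logit/log scale depending on ``kind``).
    dispersion : NB dispersion for ``kind='counts'`` (var = mu + disp*mu^2).
    """

    name: str
    p: int
    n_informative: int
    kind: str = "gaussian"
    loading_scale: float = 1.0
    noise_sd: float = 1.0
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "beta", "counts"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if not 0 <= self.n_informative <= self.p:
            raise ValueError("need 0 <= n_informative <= p")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_scale: float = 365.0
    effect_size: float = 1.0
    censor_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.baseline_scale <= 0:
            raise ValueError("baseline_scale must be positive")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimConfig:
    """Full study configuration; ``generate_study`` is deterministic in it."""

    n_per_class: tuple[int, ...] = (50, 50, 50)
    block_specs: tuple[BlockSpec, ...] = (
        BlockSpec("mrna", p=300, n_informative=20, kind="gaussian", loading_scale=1.5),
        BlockSpec("methylation", p=300, n_informative=20, kind="beta", loading_scale=1.5),
        BlockSpec("mirna", p=150, n_informative=15, kind="gaussian", loading_scale=1.5),
    )
    class_separation: float = 5.0
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0
    class_names: tuple[str, ...] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.n_per_class)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if any(n <= 0 for n in self.n_per_class):
            raise ValueError("class sizes must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if self.class_names is not None and len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal the number of classes")


def _default_class_names(K: int) -> list[str]:
    glioma = ["astrocytoma", "oligodendroglioma", "GBM"]
    if K <= len(glioma):
        return glioma[:K]
    return [f"class{k}" for k in range(K)]


def simplex_vertices(K: int) -> np.ndarray:
    """K equidistant unit-norm points in R^(K-1), centered at the origin.

    Rows are the vertices of a regular simplex with circumradius 1; scaling
    by ``separation`` puts the class means at distance ``separation`` from
    the overall centroid.
    """
    centered = np.eye(K) - 1.0 / K
    # orthonormal basis of the (K-1)-dim span
    _, _, vt = np.linalg.svd(centered)
    V = centered @ vt[: K - 1].T
    V /= np.linalg.norm(V, axis=1, keepdims=True)
    return V


def generate_latent(
    n_per_class, separation: float, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw latent factor scores with class means on a scaled simplex.

    Returns an (n, K-1) latent matrix and the integer class labels. Within
    each class the latent factors are N(mean_k, I); the class means sit at
    the vertices of a regular simplex at distance ``separation`` from the
    origin, so ``separation`` is the per-class mean norm in latent space.
    """
    n_per_class = tuple(int(n) for n in n_per_class)
    K = len(n_per_class)
    if K < 2:
        raise ValueError("need at least 2 classes")
    if any(n <= 0 for n in n_per_class):
        raise ValueError("class sizes must be positive")
    if separation < 0:
        raise ValueError("separation must be nonnegative")
    rng = np.random.default_rng(seed)
    vertices = simplex_vertices(K) * separation
    labels = np.repeat(np.arange(K), n_per_class)
    latent = vertices[labels] + rng.standard_normal((labels.size, K - 1))
    return latent, labels


def generate_block(
    latent: np.ndarray, spec: BlockSpec, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one omics block from shared latent factors.

    Each informative feature loads with magnitude ``loading_scale`` on a
    single latent axis, with a random sign; for beta (methylation) blocks
    half of the informative loadings are forced negative, emulating the
    negative expression-methylation correlations seen in tumour data.
    Returns the (n, p) matrix and the sorted informative column indices.
    """
    rng = np.random.default_rng(seed)
    n, d = latent.shape
    informative = np.sort(rng.choice(spec.p, size=spec.n_informative, replace=False))
    # balanced round-robin assignment of informative features to latent axes:
    # each class contrast is carried by a comparable number of features
    axes = rng.permutation(np.resize(np.arange(d), spec.n_informative))
    signs = rng.choice([-1.0, 1.0], size=spec.n_informative)
    if spec.kind == "beta" and spec.n_informative > 0:
        signs = np.abs(signs)
        signs[: spec.n_informative // 2] = -1.0

    signal = np.zeros((n, spec.p))
    signal[:, informative] = latent[:, axes] * (spec.loading_scale * signs)
    noise = rng.standard_normal((n, spec.p)) * spec.noise_sd

    if spec.kind == "gaussian":
        X = signal + noise
    elif spec.kind == "beta":
        X = expit(signal + noise)
        eps = np.finfo(float).tiny
        X = np.clip(X, eps, 1.0 - eps)
    else:  # counts
        log_mu = _COUNT_LOG_BASE + signal + noise
        mu = np.exp(np.clip(log_mu, -30, 30))
        if spec.dispersion <= 0:
            X = rng.poisson(mu).astype(float)
        else:
            r = 1.0 / spec.dispersion
            X = rng.negative_binomial(r, r / (r + mu)).astype(float)
    return X, informative


def generate_survival(
    linear_predictor: np.ndarray,
    baseline_scale: float,
    censor_fraction: float,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential survival with hazard exp(lp)/baseline_scale, uniform censoring.

    The censoring horizon c of the independent U(0, c) censoring times is
    solved numerically so that the expected censored fraction equals
    ``censor_fraction``.
    """
    if baseline_scale <= 0:
        raise ValueError("baseline_scale must be positive")
    if not 0 <= censor_fraction < 1:
        raise ValueError("censor_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lp = np.asarray(linear_predictor, dtype=float)
    rate = np.exp(lp) / baseline_scale
    times = rng.exponential(1.0 / rate)
    if censor_fraction == 0:
        return times, np.ones(times.size, dtype=int)

    def expected_censored(c: float) -> float:
        # P(C < T | rate) with C ~ U(0, c): (1 - exp(-rate*c)) / (rate*c)
        x = rate * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-8 / rate.max(), 1.0 / rate.min()
    while expected_censored(hi) > censor_fraction:
        hi *= 10.0
        if hi > 1e12 / rate.min():
            break
    c = brentq(lambda x: expected_censored(x) - censor_fraction, lo, hi)
    censor_times = rng.uniform(0.0, c, size=times.size)
    event = (times <= censor_times).astype(int)
    observed = np.minimum(times, censor_times)
    return observed, event


def generate_study(config: SimConfig) -> MultiOmicsDataset:
    """Assemble latent factors, blocks and survival into one dataset."""
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(len(config.block_specs) + 2)
    latent, y = generate_latent(config.n_per_class, config.class_separation, child[0])
    n = y.size
    sample_ids = [f"S{i:04d}" for i in range(n)]
    names = list(config.class_names or _default_class_names(config.n_classes))

    blocks: dict[str, pd.DataFrame] = {}
    truth: dict[str, list[str]] = {}
    for spec, sseq in zip(config.block_specs, child[1:]):
        X, informative = generate_block(latent, spec, sseq)
        feats = [f"{spec.name}_{j:04d}" for j in range(spec.p)]
        blocks[spec.name] = pd.DataFrame(X, index=sample_ids, columns=feats)
        truth[spec.name] = [feats[j] for j in informative]

    surv = config.survival
    lp_axis = latent[:, 0]
    lp = surv.effect_size * (lp_axis - lp_axis.mean()) / max(lp_axis.std(), 1e-12)
    time, event = generate_survival(lp, surv.baseline_scale, surv.censor_fraction, child[-1])
    survival = pd.DataFrame({"time": time, "event": event}, index=sample_ids)
    labels = pd.Series([names[k] for k in y], index=sample_ids, name="class")
    return MultiOmicsDataset(blocks=blocks, labels=labels, survival=survival, truth=truth)
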