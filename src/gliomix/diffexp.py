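"""Count-based differential expression between class pairs.

Low-count filtering on CPM, TMM library-size normalization, a vectorized
negative-binomial likelihood-ratio test with moment dispersions shrunk
toward a common trimmed-mean value, BH adjustment, the sloped volcano
"relevance" cut-line separating biologically relevant from merely
significant genes, and the -log10(p) x sign(logFC) rank metric used for
preranked gene-set enrichment.

Count matrices are (genes x samples) DataFrames throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, trim_mean
from statsmodels.stats.multitest import multipletests

_MIN_DISP = 1e-8


def cpm(counts: pd.DataFrame, lib_sizes=None, prior: float = 0.0) -> pd.DataFrame:
    """Counts per million; ``lib_sizes`` defaults to the column sums."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    return (counts + prior) / (np.asarray(lib_sizes) + 2.0 * prior) * 1e6


def filter_low_counts(
    counts: pd.DataFrame,
    groups=None,
    min_cpm: float = 1.0,
    min_samples: int | None = None,
) -> list[str]:
    """Genes with CPM > ``min_cpm`` (strict) in at least ``min_samples`` samples.

    ``min_samples`` defaults to the smallest group size when ``groups`` is
    given, otherwise to 1.
    """
    if min_samples is None:
        if groups is not None:
            groups = np.asarray(list(groups))
            min_samples = min(int((groups == g).sum()) for g in np.unique(groups))
        else:
            min_samples = 1
    x = cpm(counts)
    keep = (x > min_cpm).sum(axis=1) >= min_samples
    kept = list(counts.index[keep])
    if not kept:
        raise ValueError("no genes survive the low-count filter")
    return kept


def tmm_factors(
    counts: pd.DataFrame, trim_M: float = 0.30, trim_A: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference is the sample whose upper-quartile CPM is closest to the
    mean upper quartile. For each sample, M (log2 ratio) and A (log2
    abundance) are computed on genes positive in both sample and reference,
    doubly trimmed (``trim_M`` on each M tail, ``trim_A`` on each A tail),
    and the factor is 2 to the precision-weighted mean M, with weights from
    the asymptotic binomial variance.
    """
    Y = counts.to_numpy(dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    lib = Y.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    uq = np.array([np.quantile(Y[:, i][Y[:, i] > 0] / lib[i], 0.75) for i in range(Y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(Y.shape[1])
    yr, Nr = Y[:, ref], lib[ref]
    for i in range(Y.shape[1]):
        if i == ref:
            continue
        yk, Nk = Y[:, i], lib[i]
        ok = (yk > 0) & (yr > 0)
        if ok.sum() < 10:
            continue
        pk, pr = yk[ok] / Nk, yr[ok] / Nr
        M = np.log2(pk / pr)
        A = 0.5 * np.log2(pk * pr)
        w = (Nk - yk[ok]) / (Nk * yk[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        if np.allclose(M, M[0]):
            factors[i] = 2 ** M[0]
            continue
        loM, hiM = np.quantile(M, [trim_M, 1 - trim_M])
        loA, hiA = np.quantile(A, [trim_A, 1 - trim_A])
        keep = (M >= loM) & (M <= hiM) & (A >= loA) & (A <= hiA)
        if not keep.any():
            continue
        factors[i] = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; alpha is per-gene dispersion."""
    r = 1.0 / alpha[:, None]
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu)),
        axis=1,
    )


def _nb_fit_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene MLE of log mean-per-unit-size, mu_i = exp(beta) * s_i.

    Newton iterations on the score sum((y - mu)/(1 + alpha*mu)) = 0,
    vectorized over genes.
    """
    beta = np.log((y.sum(axis=1) + 0.5) / s.sum())
    for _ in range(50):
        mu = np.exp(beta)[:, None] * s
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def _moment_dispersion(y: np.ndarray, s: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Within-group method-of-moments dispersion per gene (can be negative)."""
    z = y / s
    num = np.zeros(y.shape[0])
    den = 0.0
    inv_s = 1.0 / s
    for g in np.unique(groups):
        m = groups == g
        ng = int(m.sum())
        if ng < 2:
            continue
        mg = z[:, m].mean(axis=1)
        vg = z[:, m].var(axis=1, ddof=1)
        ag = (vg - mg * inv_s[m].mean()) / np.maximum(mg, 1e-12) ** 2
        num += (ng - 1) * ag
        den += ng - 1
    return num / max(den, 1.0)


def nb_de_test(
    counts: pd.DataFrame,
    groups,
    factors: pd.Series | None = None,
    data_weight: float = 0.25,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test per gene.

    Effective library sizes are column sums times the TMM factors; the NB
    dispersion per gene is a shrinkage estimate, ``data_weight`` (default
    0.25) on the per-gene method-of-moments value and the rest on the
    trimmed-mean common dispersion, unless ``dispersion`` fixes it. The
    statistic is the likelihood ratio of group-specific vs shared means,
    referred to chi-square with 1 df. logFC is log2 of the second group's
    mean CPM over the first's, with prior count 0.5.

    Returns a DataFrame with columns logFC, p indexed by gene.
    """
    groups = np.asarray(list(groups))
    uniq = list(dict.fromkeys(groups))
    if len(uniq) != 2:
        raise ValueError("need exactly 2 groups")
    if any((groups == g).sum() < 2 for g in uniq):
        raise ValueError("each group needs at least 2 samples")
    Y = counts.to_numpy(dtype=float)
    if not np.allclose(Y, np.round(Y)):
        raise ValueError("counts must be integers")
    if factors is None:
        factors = tmm_factors(counts)
    s = Y.sum(axis=0) * np.asarray(factors, dtype=float)

    if dispersion is not None:
        alpha = np.full(Y.shape[0], max(dispersion, _MIN_DISP))
    else:
        raw = np.clip(_moment_dispersion(Y, s, groups), 0.0, 10.0)
        common = float(trim_mean(raw, 0.25)) if raw.size > 4 else float(np.mean(raw))
        alpha = np.clip(data_weight * raw + (1.0 - data_weight) * common, _MIN_DISP, 10.0)

    m0, m1 = groups == uniq[0], groups == uniq[1]
    beta0 = _nb_fit_mean(Y[:, m0], s[m0], alpha)
    beta1 = _nb_fit_mean(Y[:, m1], s[m1], alpha)
    beta_null = _nb_fit_mean(Y, s, alpha)
    ll_full = _nb_loglik(Y[:, m0], np.exp(beta0)[:, None] * s[m0], alpha) + _nb_loglik(
        Y[:, m1], np.exp(beta1)[:, None] * s[m1], alpha
    )
    ll_null = _nb_loglik(Y, np.exp(beta_null)[:, None] * s, alpha)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    p = chi2.sf(lrt, df=1)

    mean_cpm = {}
    for g, m in ((uniq[0], m0), (uniq[1], m1)):
        per_sample = (Y[:, m] + 0.5) / (s[m] + 1.0) * 1e6
        mean_cpm[g] = per_sample.mean(axis=1)
    logfc = np.log2(mean_cpm[uniq[1]] / mean_cpm[uniq[0]])
    return pd.DataFrame({"logFC": logfc, "p": p}, index=counts.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CutlineThresholds:
    """Parameters of the sloped volcano cut-line."""

    M: float                       # max over genes of -log10(FDR)
    c: float = -np.log10(0.05)     # -log10 of the significance level


def relevance_cutline(
    logFC, FDR, thresholds: CutlineThresholds | None = None, alpha: float = 0.05
) -> pd.Series:
    """Classify genes as pos_relevant / neg_relevant / significant_not_relevant / ns.

    Only genes with FDR < alpha can be relevant. With M = max(-log10 FDR)
    over the contrast and c = -log10(alpha), a gene is positively relevant
    when -log10(FDR) > M + logFC*(c - M) and negatively relevant when
    -log10(FDR) > M + logFC*(M - c); at logFC = +-1 both lines pass through
    c and at logFC = 0 through M. If M <= c the cut-line is degenerate and
    the rule falls back to FDR < alpha and |logFC| > 1 (with a warning).
    """
    logFC = np.asarray(logFC, dtype=float)
    # FDR = 0 (underflow) is clamped so M stays finite
    fdr = np.maximum(np.asarray(FDR, dtype=float), np.finfo(float).tiny)
    neglog = -np.log10(fdr)
    c = -np.log10(alpha)
    M = thresholds.M if thresholds is not None else float(np.nanmax(neglog))
    sig = fdr < alpha
    if M <= c:
        warnings.warn("degenerate cut-line (max -log10 FDR <= significance line); "
                      "falling back to FDR and |logFC| > 1")
        pos = sig & (logFC > 1.0)
        neg = sig & (logFC < -1.0)
    else:
        pos = sig & (neglog > M + logFC * (c - M))
        neg = sig & (neglog > M + logFC * (M - c))
    status = np.where(pos, "pos_relevant",
             np.where(neg, "neg_relevant",
             np.where(sig, "significant_not_relevant", "ns")))
    return pd.Series(status, index=getattr(logFC, "index", None))


def rank_metric(p, logFC) -> np.ndarray:
    """Preranked GSEA score: -log10(p) * sign(logFC); p = 0 is clamped."""
    p = np.asarray(p, dtype=float)
    logFC = np.asarray(logFC, dtype=float)
    if (p == 0).any():
        warnings.warn("p = 0 clamped to the smallest positive float")
        p = np.where(p == 0, np.finfo(float).tiny, p)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return -np.log10(p) * np.sign(logFC)


def de_contrast(
    counts: pd.DataFrame,
    labels,
    pair: tuple[str, str],
    min_cpm: float = 1.0,
    alpha: float = 0.05,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full DE pipeline for one class pair: filter, TMM, NB test, BH, cut-line.

    logFC is oriented as ``pair[1]`` over ``pair[0]``. Returns gene-indexed
    columns logFC, p, FDR, status, rank_metric.
    """
    labels = np.asarray(list(labels))
    mask = np.isin(labels, pair)
    sub = counts.loc[:, mask]
    groups = labels[mask]
    kept = filter_low_counts(sub, groups, min_cpm=min_cpm)
    sub = sub.loc[kept]
    factors = tmm_factors(sub)
    # enforce the requested orientation regardless of column order
    order = np.argsort([pair.index(g) for g in groups], kind="stable")
    res = nb_de_test(sub.iloc[:, order], groups[order], factors.iloc[order],
                     dispersion=dispersion)
    res["FDR"] = bh_adjust(res["p"].to_numpy())
    res["status"] = relevance_cutline(res["logFC"].to_numpy(), res["FDR"].to_numpy(),
                                      alpha=alpha).to_numpy()
    res["rank_metric"] = rank_metric(res["p"].to_numpy(), res["logFC"].to_numpy())
    return res


def write_rnk(res: pd.DataFrame, path) -> None:
    """Two-column preranked file (gene, rank metric), descending."""
    res["rank_metric"].sort_values(ascending=False).to_csv(
        path, sep="\t", header=False
    )
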