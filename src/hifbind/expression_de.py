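"""Two-group negative-binomial differential expression (likelihood-ratio
test with per-gene dispersion) and the signed significance ranking
statistic pi = log2FC * (-log10 p)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "RankedGeneList",
    "size_factors_median_ratio",
    "nb_two_group_lrt",
    "rank_statistic",
    "build_ranking",
]

_PVALUE_FLOOR = 1e-300


@dataclass(frozen=True)
class DEResult:
    gene: str
    log2fc: float
    pvalue: float
    mean_counts: tuple[float, float]
    lrt_stat: float = float("nan")
    dispersion: float = float("nan")
    na: bool = False


@dataclass
class RankedGeneList:
    """Genes ordered by the ranking statistic pi, descending; ties stable."""

    genes: list[str]
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if len(self.genes) != self.pi.size:
            raise ValueError("genes and pi differ in length")
        if np.any(np.diff(self.pi) > 0):
            raise ValueError("pi must be nonincreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "pi": self.pi})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def size_factors_median_ratio(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors against the geometric-mean reference,
    rescaled to geometric mean 1.

    Falls back to library-size factors (with a warning) when no gene has
    all-positive counts.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x samples")
    if counts.shape[1] == 1:
        return np.ones(1)
    positive = np.all(counts > 0, axis=1)
    if not np.any(positive):
        warnings.warn(
            "no gene with all-positive counts; falling back to library-size factors",
            stacklevel=2,
        )
        libsize = counts.sum(axis=0)
        factors = libsize / np.exp(np.mean(np.log(libsize)))
        return factors
    sub = counts[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo_mean
    factors = np.exp(np.median(ratios, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood; alpha is the dispersion (variance mu + alpha mu^2)."""
    if alpha < 1e-12:
        # Poisson limit, numerically stable
        return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
    r = 1.0 / alpha
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    )


def _fit_group_means(
    y: np.ndarray, s: np.ndarray, groups: np.ndarray, alpha: float
) -> tuple[float, float]:
    """ML group means for fixed dispersion, by 1-d optimisation per group."""
    means = []
    for g in (0, 1):
        yg, sg = y[groups == g], s[groups == g]
        means.append(_fit_single_mean(yg, sg, alpha))
    return means[0], means[1]


def _fit_single_mean(y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """ML of m in mu_j = s_j m for fixed dispersion (Newton on log m)."""
    m = max(np.sum(y) / np.sum(s), 1e-8)
    if alpha < 1e-12:
        return m  # Poisson ML with offsets is the weighted mean, exact
    log_m = np.log(m)
    for _ in range(50):
        mu = s * np.exp(log_m)
        w = 1.0 + alpha * mu
        grad = np.sum((y - mu) / w)
        hess = -np.sum(mu * (1.0 + alpha * y) / w**2)
        if hess >= 0:
            break
        step = grad / hess
        log_m -= np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-10:
            break
    return float(np.exp(log_m))


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Residual-df-corrected moment estimator: solve Pearson chi2(alpha) =
    n - n_params under the fitted means.

    Plain per-gene ML dispersion is biased low at small n, which inflates the
    LRT badly (measured type-I ~0.19 at alpha=0.05, n=6); equating the
    Pearson statistic to its residual degrees of freedom removes most of the
    bias.  Underdispersed genes fall back to the Poisson edge.
    """
    resid2 = (y - mu) ** 2
    df = y.size - n_params

    def pearson_excess(alpha: float) -> float:
        return float(np.sum(resid2 / (mu * (1.0 + alpha * mu))) - df)

    if pearson_excess(0.0) <= 0:
        return 1e-8
    hi = 1.0
    while pearson_excess(hi) > 0 and hi < 1e6:
        hi *= 10.0
    return max(float(optimize.brentq(pearson_excess, 0.0, hi)), 1e-8)


def _fit_alternative(y, s, groups):
    """Two-group fit: means by ML given dispersion, dispersion by the
    df-corrected Pearson equation, one alternation."""
    m1, m2 = _fit_group_means(y, s, groups, 0.0)
    mu = np.maximum(s * np.where(groups == 0, m1, m2), 1e-8)
    alpha = _estimate_dispersion(y, mu, n_params=2)
    m1, m2 = _fit_group_means(y, s, groups, alpha)
    mu = np.maximum(s * np.where(groups == 0, m1, m2), 1e-12)
    ll = _nb_loglik(y, mu, alpha)
    return m1, m2, alpha, ll


def nb_two_group_lrt(
    counts: np.ndarray,
    groups: Sequence,
    size_factors: np.ndarray | None = None,
    genes: Sequence[str] | None = None,
    dispersion: float | None = None,
) -> list[DEResult]:
    """Per-gene NB likelihood-ratio test between a shared-mean null and a
    two-group alternative.

    Dispersion is estimated per gene under the alternative (df-corrected
    Pearson equation; no shrinkage across genes) and reused for the null
    fit.  The LRT statistic is referred to F(1, n-2), which equals the
    1-df chi-square reference asymptotically but stays calibrated at small
    n (chi-square rejects ~13-19% at nominal 5% with n=6).  ``dispersion``
    fixes the dispersion instead of estimating it (used for the
    Poisson-limit check).  All-zero genes are flagged NA.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x samples")
    group_labels = pd.unique(pd.Series(groups))
    if len(group_labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(group_labels)}")
    g = np.asarray([0 if v == group_labels[0] else 1 for v in groups])
    if np.sum(g == 0) < 2 or np.sum(g == 1) < 2:
        raise ValueError("need >= 2 samples per group")
    if size_factors is None:
        size_factors = size_factors_median_ratio(counts)
    s = np.asarray(size_factors, dtype=float)
    if np.any(s <= 0):
        raise ValueError("size factors must be positive")
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]

    results: list[DEResult] = []
    for gi, name in enumerate(genes):
        y = counts[gi]
        norm = y / s
        mean1 = float(np.mean(norm[g == 0]))
        mean2 = float(np.mean(norm[g == 1]))
        if np.all(y == 0):
            results.append(
                DEResult(name, float("nan"), float("nan"), (mean1, mean2), na=True)
            )
            continue
        if dispersion is None:
            m1, m2, alpha, ll1 = _fit_alternative(y, s, g)
        else:
            alpha = float(dispersion)
            m1, m2 = _fit_group_means(y, s, g, alpha)
            mu = s * np.where(g == 0, m1, m2)
            ll1 = _nb_loglik(y, np.maximum(mu, 1e-12), alpha)
        m0 = _fit_single_mean(y, s, alpha)
        ll0 = _nb_loglik(y, np.maximum(s * m0, 1e-12), alpha)
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        pvalue = float(stats.f.sf(lrt, 1, y.size - 2))
        pvalue = min(max(pvalue, _PVALUE_FLOOR), 1.0)
        if m1 > 0 and m2 > 0:
            log2fc = float(np.log2(m2 / m1))
        else:
            log2fc = float("nan")
        results.append(
            DEResult(name, log2fc, pvalue, (mean1, mean2), lrt_stat=lrt,
                     dispersion=alpha)
        )
    n_na = sum(r.na for r in results)
    if n_na:
        logger.info("%d all-zero gene(s) flagged NA", n_na)
    return results


def rank_statistic(log2fc: float, pvalue: float) -> float:
    """Signed ranking statistic: log2 fold-change times -log10 p-value."""
    if not np.isfinite(log2fc):
        raise ValueError("log2fc must be finite")
    if pvalue <= 0:
        warnings.warn(
            f"p-value {pvalue} clamped to {_PVALUE_FLOOR}", stacklevel=2
        )
        pvalue = _PVALUE_FLOOR
    if pvalue > 1:
        raise ValueError(f"p-value must be <= 1, got {pvalue}")
    return float(log2fc * (-np.log10(pvalue)))


def build_ranking(de_results: Sequence[DEResult]) -> RankedGeneList:
    """Order genes by the ranking statistic descending; NA genes omitted."""
    usable = [r for r in de_results if not r.na and np.isfinite(r.log2fc)]
    dropped = len(de_results) - len(usable)
    if dropped:
        logger.info("build_ranking omitted %d NA gene(s)", dropped)
    if not usable:
        raise ValueError("no usable DE results to rank")
    pis = [rank_statistic(r.log2fc, r.pvalue) for r in usable]
    order = sorted(range(len(usable)), key=lambda i: -pis[i])
    return RankedGeneList(
        genes=[usable[i].gene for i in order],
        pi=np.asarray([pis[i] for i in order]),
    )
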