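"""Consensus peak definition, RPKM normalisation, background-percentile
filtering, cross-condition scatter summaries, and the PCA biplot."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, read_table

logger = logging.getLogger(__name__)

__all__ = [
    "SignalMatrix",
    "PcaBiplot",
    "compute_rpkm",
    "consensus_peaks",
    "background_threshold",
    "filter_peaks",
    "signal_scatter",
    "pca_biplot",
]


@dataclass
class SignalMatrix:
    """Peak regions x conditions matrix of non-negative normalised signal."""

    regions: list[GenomicInterval]
    conditions: list[str]
    values: np.ndarray  # shape (n_regions, n_conditions)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.conditions)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.conditions)} conditions"
            )
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")
        keys = [r.key() for r in self.regions]
        if len(set(keys)) != len(keys):
            raise ValueError("regions must be unique")

    def column(self, condition: str) -> np.ndarray:
        try:
            idx = self.conditions.index(condition)
        except ValueError as exc:
            raise KeyError(f"condition {condition!r} not in {self.conditions}") from exc
        return self.values[:, idx]

    def subset(self, mask: np.ndarray) -> "SignalMatrix":
        mask = np.asarray(mask)
        regions = [r for r, keep in zip(self.regions, mask) if keep]
        return SignalMatrix(regions, list(self.conditions), self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
            }
        )
        for j, cond in enumerate(self.conditions):
            df[cond] = self.values[:, j]
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalMatrix":
        df = read_table(path, {"chrom": str, "start": int, "end": int})
        conditions = [c for c in df.columns if c not in {"chrom", "start", "end"}]
        regions = [
            GenomicInterval(row.chrom, int(row.start), int(row.end))
            for row in df.itertuples()
        ]
        return cls(regions, conditions, df[conditions].to_numpy(dtype=float))


@dataclass
class PcaBiplot:
    site_scores: np.ndarray          # regions x 2
    condition_loadings: np.ndarray   # conditions x 2
    explained_variance: np.ndarray   # per-component fraction, nonincreasing
    conditions: list[str]
    degenerate: bool = False


def compute_rpkm(count: float, region_length: int, library_size: float) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise ValueError(f"region_length must be > 0, got {region_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return count / ((region_length / 1000.0) * (library_size / 1e6))


def consensus_peaks(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Reciprocally supported peaks: for each A-peak overlapping >=1 bp of B,
    emit the span of its base-pair intersection with B; drop the rest.
    Output is sorted and merged where overlapping."""
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for iv in set_b:
        by_chrom_b.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for spans in by_chrom_b.values():
        spans.sort()

    supported: list[GenomicInterval] = []
    for iv in set_a:
        spans = by_chrom_b.get(iv.chrom, [])
        lo, hi = None, None
        for b_start, b_end in spans:
            if b_start >= iv.end:
                break
            s, e = max(iv.start, b_start), min(iv.end, b_end)
            if e > s:
                lo = s if lo is None else min(lo, s)
                hi = e if hi is None else max(hi, e)
        if lo is not None:
            supported.append(GenomicInterval(iv.chrom, lo, hi))

    supported.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in supported:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged.pop()
            merged.append(GenomicInterval(iv.chrom, prev.start, max(prev.end, iv.end)))
        else:
            merged.append(iv)
    return merged


def background_threshold(background_values: Sequence[float], p: float) -> float:
    """Empirical (1-p) quantile of background totals, nearest-rank type.

    The filter downstream keeps peaks with total >= the returned threshold, so
    on n distinct background values about ``p * n`` land at/above it.
    """
    values = np.asarray(background_values, dtype=float)
    if values.size == 0:
        raise ValueError("background_values is empty")
    if not 0 < p < 1:
        raise ValueError(f"tail probability p must be in (0,1), got {p}")
    if values.size < 1.0 / p:
        warnings.warn(
            f"only {values.size} background values for tail p={p}; "
            f">= {int(np.ceil(1/p))} recommended",
            stacklevel=2,
        )
    ordered = np.sort(values)
    rank = min(ordered.size - 1, int(np.floor((1.0 - p) * ordered.size)))
    return float(ordered[rank])


def filter_peaks(
    peaks: Sequence[GenomicInterval],
    totals: Sequence[float],
    threshold: float,
) -> tuple[list[GenomicInterval], np.ndarray]:
    """Keep peaks whose total signal is >= threshold; returns (kept, mask)."""
    if len(peaks) != len(totals):
        raise ValueError(f"{len(peaks)} peaks but {len(totals)} totals")
    totals = np.asarray(totals, dtype=float)
    mask = totals >= threshold
    kept = [p for p, keep in zip(peaks, mask) if keep]
    logger.info("retained %d/%d peaks at threshold %.4g", len(kept), len(peaks), threshold)
    return kept, mask


def signal_scatter(
    matrix: SignalMatrix,
    cond_x: str,
    cond_y: str,
    site_mask: np.ndarray | None = None,
    epsilon: float = 1.0,
) -> dict:
    """Paired log signals plus correlation and equity-line summary.

    Correlations are computed on log2(value + epsilon); the equity summary is
    the fraction of sites strictly above the y=x line (ties count below).
    """
    x = matrix.column(cond_x)
    y = matrix.column(cond_y)
    if site_mask is not None:
        mask = np.asarray(site_mask)
        x, y = x[mask], y[mask]
    log_x = np.log2(x + epsilon)
    log_y = np.log2(y + epsilon)
    out = {
        "log_x": log_x,
        "log_y": log_y,
        "n": int(x.size),
        "fraction_above_equity": float(np.mean(y > x)) if x.size else float("nan"),
    }
    if x.size < 3 or np.all(log_x == log_x[0]) or np.all(log_y == log_y[0]):
        out["pearson_r"] = float("nan")
        out["spearman_rho"] = float("nan")
        out["correlation_defined"] = False
        return out
    out["pearson_r"] = float(stats.pearsonr(log_x, log_y).statistic)
    out["spearman_rho"] = float(stats.spearmanr(log_x, log_y).statistic)
    out["correlation_defined"] = True
    return out


def pca_biplot(
    matrix: SignalMatrix, n_components: int = 2, epsilon: float = 1.0
) -> PcaBiplot:
    """SVD-based PCA biplot of log-transformed, column-centred signal.

    Site scores are U * S, condition loadings the right singular vectors;
    each component's sign is fixed by making its largest-magnitude loading
    positive.
    """
    if len(matrix.conditions) < 2:
        raise ValueError("need >= 2 conditions for a biplot")
    if len(matrix.regions) < 3:
        raise ValueError("need >= 3 regions for a biplot")
    logged = np.log2(matrix.values + epsilon)
    centered = logged - logged.mean(axis=0, keepdims=True)
    degenerate = bool(np.allclose(centered, 0.0))
    if degenerate:
        logger.warning("constant signal matrix: PCA is degenerate")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    explained = s**2 / total if total > 0 else np.zeros_like(s)
    # sign convention: largest-|loading| per component is positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    return PcaBiplot(
        site_scores=scores,
        condition_loadings=loadings,
        explained_variance=explained[:k],
        conditions=list(matrix.conditions),
        degenerate=degenerate,
    )
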