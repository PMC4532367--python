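"""Pre-ranked gene set enrichment: weighted running-sum enrichment score
with a gene-set permutation null.

The ranking is pre-computed (signed significance statistic), so the null is
built by drawing random same-size gene sets from the ranked universe; sample
label permutation is unavailable in pre-ranked mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np

from .expression_de import RankedGeneList

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "enrichment_score",
    "gsea_permutation",
    "two_tail_report",
    "read_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    pvalue: float
    running_sum: np.ndarray
    leading_edge: list[str]
    n_perm: int
    n_hits: int


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets in GMT format (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets.append(GeneSet(fields[0], frozenset(fields[2:])))
    return sets


def _hit_mask(ranking: RankedGeneList, gene_set: GeneSet) -> np.ndarray:
    universe = set(ranking.genes)
    in_universe = gene_set.members & universe
    dropped = len(gene_set.members) - len(in_universe)
    if dropped:
        logger.info(
            "gene set %s: %d member(s) outside the ranked universe dropped",
            gene_set.name, dropped,
        )
    if not in_universe:
        raise ValueError(f"gene set {gene_set.name!r} disjoint from the ranked universe")
    if len(in_universe) == len(universe):
        raise ValueError(f"gene set {gene_set.name!r} covers the whole universe")
    return np.asarray([g in in_universe for g in ranking.genes])


def _running_sum(
    pi: np.ndarray, hits: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """Running enrichment sum over the ranking for a boolean hit mask."""
    n = pi.size
    k = int(hits.sum())
    weights = np.abs(pi) ** weight_exponent
    hit_weights = np.where(hits, weights, 0.0)
    total = hit_weights.sum()
    if total == 0:
        # degenerate: all hit weights zero -> equal increments
        hit_weights = hits.astype(float)
        total = float(k)
    steps = hit_weights / total - np.where(hits, 0.0, 1.0 / (n - k))
    return np.cumsum(steps)


def enrichment_score(
    ranking: RankedGeneList,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted Kolmogorov-Smirnov-like enrichment score.

    Walking down the ranking, hits increment the running sum by their weight
    share |pi|^p / sum over hits, misses decrement by 1/(N-k); the score is
    the signed extremum of the running sum.
    """
    hits = _hit_mask(ranking, gene_set)
    rs = _running_sum(ranking.pi, hits, weight_exponent)
    es = float(rs[np.argmax(np.abs(rs))])
    return es, rs


def _null_scores(
    pi: np.ndarray,
    n_hits: int,
    n_perm: int,
    weight_exponent: float,
    rng: np.random.Generator,
    chunk: int = 500,
) -> np.ndarray:
    """ES of random same-size gene sets, vectorised in chunks."""
    n = pi.size
    weights = np.abs(pi) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m random subsets of size n_hits as a boolean matrix
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :n_hits]
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        hit_w = np.where(mask, weights, 0.0)
        totals = hit_w.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        steps = hit_w / totals - np.where(mask, 0.0, 1.0 / (n - n_hits))
        rs = np.cumsum(steps, axis=1)
        ext = np.take_along_axis(
            rs, np.argmax(np.abs(rs), axis=1)[:, None], axis=1
        )[:, 0]
        out[done : done + m] = ext
        done += m
    return out


def gsea_permutation(
    ranking: RankedGeneList,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Permutation p-value and normalised ES for one gene set.

    The p-value is one-sided in the direction of the observed score,
    computed against the same-sign portion of the null with an add-one
    correction (so it can never be zero); NES divides by the mean |null ES|
    of the same sign.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p-value resolution is coarse",
                      stacklevel=2)
    hits = _hit_mask(ranking, gene_set)
    k = int(hits.sum())
    rs = _running_sum(ranking.pi, hits, weight_exponent)
    es = float(rs[np.argmax(np.abs(rs))])

    rng = np.random.default_rng(seed)
    null = _null_scores(ranking.pi, k, n_perm, weight_exponent, rng)
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    extreme = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
    pvalue = (1 + extreme) / (n_same + 1)
    denom = float(np.mean(np.abs(null[same_sign]))) if n_same else float("nan")
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else float("nan")

    extremum_idx = int(np.argmax(np.abs(rs)))
    if es >= 0:
        leading = [g for g, h, i in zip(ranking.genes, hits, range(len(hits)))
                   if h and i <= extremum_idx]
    else:
        leading = [g for g, h, i in zip(ranking.genes, hits, range(len(hits)))
                   if h and i >= extremum_idx]
    return EnrichmentResult(
        es=es, nes=float(nes), pvalue=float(pvalue), running_sum=rs,
        leading_edge=leading, n_perm=n_perm, n_hits=k,
    )


def two_tail_report(
    ranking: RankedGeneList,
    gene_set: GeneSet,
    n_perm: int = 10_000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> dict:
    """Positive-end and negative-end enrichment reported separately.

    The positive tail scores the running-sum maximum (enrichment among
    upregulated genes), the negative tail its minimum, each against the
    matching side of a shared permutation null.
    """
    hits = _hit_mask(ranking, gene_set)
    k = int(hits.sum())
    rs = _running_sum(ranking.pi, hits, weight_exponent)
    es_pos = float(np.max(rs))
    es_neg = float(np.min(rs))

    rng = np.random.default_rng(seed)
    n = ranking.pi.size
    weights = np.abs(ranking.pi) ** weight_exponent
    null_pos = np.empty(n_perm)
    null_neg = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(500, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)[:, :k]
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        hit_w = np.where(mask, weights, 0.0)
        totals = hit_w.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        steps = hit_w / totals - np.where(mask, 0.0, 1.0 / (n - k))
        null_rs = np.cumsum(steps, axis=1)
        null_pos[done : done + m] = null_rs.max(axis=1)
        null_neg[done : done + m] = null_rs.min(axis=1)
        done += m
    p_pos = (1 + int(np.sum(null_pos >= es_pos))) / (n_perm + 1)
    p_neg = (1 + int(np.sum(null_neg <= es_neg))) / (n_perm + 1)
    return {
        "positive": {"es": es_pos, "pvalue": float(p_pos)},
        "negative": {"es": es_neg, "pvalue": float(p_neg)},
    }
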