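"""Relating binding sites to genes: nearest-TSS links, gene-class
breakdowns, isoform-specific classification, and windowed gene capture."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import GeneRecord, GenomicInterval
from .peak_quant import SignalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SiteGeneLink",
    "IsoformCall",
    "nearest_tss",
    "class_breakdown",
    "classify_isoform_specific",
    "genes_within",
    "tss_histogram",
]

CALL_ISOFORM1 = "isoform1_specific"
CALL_ISOFORM2 = "isoform2_specific"
CALL_SHARED = "shared"


@dataclass(frozen=True)
class SiteGeneLink:
    """A binding site linked to a gene, with a signed summit-to-TSS distance.

    The distance is summit minus TSS, sign-flipped for minus-strand genes so
    that positive always means downstream of the TSS.
    """

    site: GenomicInterval
    gene: GeneRecord | None
    distance: int | None


@dataclass(frozen=True)
class IsoformCall:
    site: GenomicInterval
    call: str
    fold: float


def nearest_tss(
    site: GenomicInterval, annotation: Sequence[GeneRecord]
) -> SiteGeneLink:
    """Link a site to the gene whose TSS is nearest its summit.

    Equidistant candidates tie-break to the lexicographically smaller gene id
    (logged).  A site on a chromosome with no genes yields a null link.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    summit = site.summit_position
    candidates = [g for g in annotation if g.chrom == site.chrom]
    if not candidates:
        logger.warning("no gene on chromosome %s; null link emitted", site.chrom)
        return SiteGeneLink(site, None, None)
    best = min(candidates, key=lambda g: (abs(summit - g.tss), g.id))
    ties = [g for g in candidates if abs(summit - g.tss) == abs(summit - best.tss)]
    if len(ties) > 1:
        logger.info(
            "site %s:%d equidistant to %d genes; kept %s by id",
            site.chrom, summit, len(ties), best.id,
        )
    return SiteGeneLink(site, best, _signed_distance(summit, best))


def _signed_distance(summit: int, gene: GeneRecord) -> int:
    d = summit - gene.tss
    return d if gene.strand == "+" else -d


def class_breakdown(links: Sequence[SiteGeneLink]) -> dict:
    """Per-gene-class fractions (and counts) of nearest-gene links."""
    counts: dict[str, int] = {}
    for link in links:
        if link.gene is None:
            continue
        counts[link.gene.gene_class] = counts.get(link.gene.gene_class, 0) + 1
    total = sum(counts.values())
    if total == 0:
        logger.warning("class_breakdown called with no linked genes")
        return {"fractions": {}, "counts": {}, "n": 0}
    fractions = {cls: n / total for cls, n in counts.items()}
    return {"fractions": fractions, "counts": counts, "n": total}


def classify_isoform_specific(
    matrix: SignalMatrix,
    cond1: str,
    cond2: str,
    fold: float = 3.0,
    epsilon: float = 1.0,
) -> list[IsoformCall]:
    """Call each site isoform-specific or shared by pseudocounted fold ratio.

    fold_ratio = (v1 + eps) / (v2 + eps); the call is isoform1-specific when
    the ratio is >= ``fold`` (inclusive), isoform2-specific when <= 1/fold,
    shared otherwise.
    """
    if fold <= 1:
        raise ValueError(f"fold cutoff must exceed 1, got {fold}")
    v1 = matrix.column(cond1)
    v2 = matrix.column(cond2)
    ratios = (v1 + epsilon) / (v2 + epsilon)
    calls = []
    for site, r in zip(matrix.regions, ratios):
        if r >= fold:
            call = CALL_ISOFORM1
        elif r <= 1.0 / fold:
            call = CALL_ISOFORM2
        else:
            call = CALL_SHARED
        calls.append(IsoformCall(site, call, float(r)))
    return calls


def genes_within(
    site: GenomicInterval,
    annotation: Sequence[GeneRecord],
    window: int = 10_000,
) -> list[GeneRecord]:
    """All genes whose TSS lies within ``window`` bp of the site summit
    (inclusive), sorted by absolute distance then gene id."""
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    summit = site.summit_position
    hits = [
        g
        for g in annotation
        if g.chrom == site.chrom and abs(summit - g.tss) <= window
    ]
    hits.sort(key=lambda g: (abs(summit - g.tss), g.id))
    return hits


def tss_histogram(
    links: Sequence[SiteGeneLink], bin_edges: Sequence[float]
) -> np.ndarray:
    """Counts of signed summit-to-TSS distances per bin.

    Distances beyond the outer edges are folded into the first/last bin so
    no site silently disappears.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    distances = np.asarray(
        [link.distance for link in links if link.distance is not None], dtype=float
    )
    if distances.size == 0:
        return np.zeros(edges.size - 1, dtype=int)
    clipped = np.clip(distances, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts.astype(int)
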