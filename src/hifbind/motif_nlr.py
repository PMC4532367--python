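"""Normalised likelihood-ratio motif scanning and the enrichment-trend and
differential-distribution analyses built on top of it.

The per-window score is the arithmetic mean, over motif positions, of the
ratio between the motif probability of the observed base and its background
weight; the per-region statistic is the maximum of that score over all
windows (and optionally both strands).  ``log2`` of the maximum is reported
for plotting.  A conventional product-form (log-sum) likelihood ratio is
available behind ``form="product"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import BSpline

from .io_formats import GenomicInterval

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "PWM",
    "BackgroundModel",
    "MotifScanResult",
    "pwm_from_counts",
    "background_from_regions",
    "nlr_profile",
    "pnlr",
    "motif_trend",
    "differential_motif_test",
]


@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities; columns sum to one."""

    probs: np.ndarray  # 4 x L, rows in A,C,G,T order
    motif_id: str = ""

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError(f"PWM must be 4 x L with L >= 1, got {probs.shape}")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if np.any(probs < 0):
            raise ValueError("PWM entries must be non-negative")

    @property
    def length(self) -> int:
        return self.probs.shape[1]


@dataclass(frozen=True)
class BackgroundModel:
    """Background base weights; strictly positive and summing to one."""

    weights: np.ndarray  # length 4, A,C,G,T order

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (4,):
            raise ValueError(f"background must have 4 weights, got shape {w.shape}")
        if np.any(w <= 0):
            raise ValueError("background weights must be strictly positive")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("background weights must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))


@dataclass
class MotifScanResult:
    region: GenomicInterval | None
    pnlr: float
    log_pnlr: float
    best_offset: int
    best_strand: str
    motif_id: str = ""


def pwm_from_counts(
    counts: Sequence[Sequence[float]] | np.ndarray,
    pseudocount: float = 0.25,
    motif_id: str = "",
) -> PWM:
    """Convert a raw 4 x L count matrix to probabilities with a per-cell
    pseudocount: (count + pc) / (column sum + 4 pc)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError(f"counts must be 4 x L, got {counts.shape}")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and np.any(colsums == 0):
        raise ValueError("all-zero column with pseudocount=0")
    probs = (counts + pseudocount) / (colsums + 4.0 * pseudocount)
    return PWM(probs, motif_id=motif_id)


def background_from_regions(
    sequences: Mapping[str, str] | Sequence[str], pseudocount: float = 1.0
) -> BackgroundModel:
    """Base frequencies pooled over sequences; N/ambiguous bases are ignored.

    One pseudocount per base keeps every weight positive even when a base is
    absent from the pool.
    """
    if isinstance(sequences, Mapping):
        sequences = list(sequences.values())
    counts = np.zeros(4)
    for seq in sequences:
        seq = seq.upper()
        for i, b in enumerate(_BASES):
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        raise ValueError("no informative (ACGT) bases in background sequences")
    counts += pseudocount
    return BackgroundModel(counts / counts.sum())


def _encode(sequence: str) -> np.ndarray:
    """Map a sequence to base indices; anything not ACGT becomes 4 (N)."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def nlr_profile(
    sequence: str,
    pwm: PWM,
    background: BackgroundModel,
    form: str = "mean",
) -> np.ndarray:
    """Score every window j = 0..W-L of the sequence.

    ``form="mean"``: arithmetic mean over motif positions of
    PWM(b, i) / B(b).  ``form="product"``: product over positions (the
    conventional likelihood ratio).  Windows containing N score 0.
    """
    if form not in {"mean", "product"}:
        raise ValueError(f"form must be 'mean' or 'product', got {form!r}")
    L = pwm.length
    W = len(sequence)
    if W < L:
        raise ValueError(f"sequence length {W} shorter than motif length {L}")
    idx = _encode(sequence)
    n_windows = W - L + 1

    # ratio[i, j] = PWM(base at j+i, i) / B(base at j+i), 0 contribution for N
    ratios = np.empty((L, n_windows))
    valid = np.ones(n_windows, dtype=bool)
    for i in range(L):
        bases = idx[i : i + n_windows]
        ok = bases < 4
        valid &= ok
        safe = np.where(ok, bases, 0)
        ratios[i] = pwm.probs[safe, i] / background.weights[safe]
    if form == "mean":
        scores = ratios.mean(axis=0)
    else:
        scores = ratios.prod(axis=0)
    scores[~valid] = 0.0
    return scores


def _reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


def pnlr(
    sequence: str,
    pwm: PWM,
    background: BackgroundModel,
    both_strands: bool = True,
    region: GenomicInterval | None = None,
    form: str = "mean",
) -> MotifScanResult:
    """Maximum window score over the region (optionally both strands).

    Offsets are reported in forward-strand coordinates.  Ties resolve to the
    smallest offset, then to the forward strand.
    """
    L = pwm.length
    forward = nlr_profile(sequence, pwm, background, form=form)
    candidates: list[tuple[float, int, int]] = [  # (score, offset, strand_order)
        (float(forward[j]), j, 0) for j in range(forward.size)
    ]
    if both_strands:
        reverse = nlr_profile(_reverse_complement(sequence), pwm, background, form=form)
        W = len(sequence)
        for j in range(reverse.size):
            candidates.append((float(reverse[j]), W - L - j, 1))
    best = max(candidates, key=lambda t: (t[0], -t[1], -t[2]))
    score, offset, strand_order = best
    log_pnlr = float(np.log2(score)) if score > 0 else float("-inf")
    return MotifScanResult(
        region=region,
        pnlr=score,
        log_pnlr=log_pnlr,
        best_offset=offset,
        best_strand="+" if strand_order == 0 else "-",
        motif_id=pwm.motif_id,
    )


def _pspline_design(x: np.ndarray, n_knots: int = 20, degree: int = 3):
    """Cubic B-spline basis with a second-difference roughness penalty."""
    lo, hi = float(x.min()), float(x.max())
    inner = np.linspace(lo, hi, n_knots)
    knots = np.concatenate(
        [np.full(degree, lo), inner, np.full(degree, hi)]
    )
    design = BSpline.design_matrix(x, knots, degree).toarray()
    n_coef = design.shape[1]
    d2 = np.diff(np.eye(n_coef), n=2, axis=0)
    return design, d2.T @ d2


def motif_trend(
    scan_results: Sequence[MotifScanResult] | Sequence[float],
    ranking_values: Sequence[float],
    n_lambda: int = 20,
) -> dict:
    """Smoothed trend of log scores against descending signal rank.

    Regions are ranked by ``ranking_values`` descending (rank 0 = highest);
    a cubic penalised regression spline of log score on rank is fitted, with
    the smoothing parameter chosen by leave-one-out cross-validation via the
    hat-matrix leverage shortcut.
    """
    y_raw = np.asarray(
        [r.log_pnlr if isinstance(r, MotifScanResult) else float(r) for r in scan_results],
        dtype=float,
    )
    ranking = np.asarray(ranking_values, dtype=float)
    if y_raw.size != ranking.size:
        raise ValueError("scan_results and ranking_values differ in length")
    if y_raw.size < 10:
        raise ValueError(f"need >= 10 regions for a trend, got {y_raw.size}")
    if np.all(ranking == ranking[0]):
        raise ValueError("constant ranking values: rank order undefined")

    order = np.argsort(-ranking, kind="stable")
    y = y_raw[order]
    y = np.where(np.isfinite(y), y, np.nanmin(y[np.isfinite(y)]))
    rank = np.arange(y.size, dtype=float)

    design, penalty = _pspline_design(rank, n_knots=min(20, max(4, y.size // 3)))
    gram = design.T @ design
    lambdas = np.logspace(-2, 6, n_lambda)
    best = None
    for lam in lambdas:
        try:
            inv = np.linalg.inv(gram + lam * penalty)
        except np.linalg.LinAlgError:
            continue
        hat = design @ inv @ design.T
        fitted = hat @ y
        lev = np.clip(np.diag(hat), 0.0, 1.0 - 1e-10)
        loo = np.mean(((y - fitted) / (1.0 - lev)) ** 2)
        if best is None or loo < best[0]:
            best = (loo, lam, fitted)
    if best is None:
        raise np.linalg.LinAlgError("spline system singular for all smoothing values")
    loo_score, lam, fitted = best
    residual_sd = float(np.std(y - fitted, ddof=1))
    return {
        "order": order,
        "rank": rank,
        "y": y,
        "fitted": fitted,
        "lambda": float(lam),
        "loo_mse": float(loo_score),
        "residual_sd": residual_sd,
    }


def differential_motif_test(
    pnlr_set_a: Sequence[float], pnlr_set_b: Sequence[float]
) -> dict:
    """Two-sided Mann-Whitney U test on log scores of two site sets.

    Returns the p-value and which set is shifted higher.  (A rank test is a
    documented substitution: the max-score distribution is heavy-tailed.)
    """
    a = np.asarray(pnlr_set_a, dtype=float)
    b = np.asarray(pnlr_set_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both sets need >= 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    # U > n_a n_b / 2 means A tends to exceed B
    u_mid = a.size * b.size / 2.0
    if res.statistic > u_mid:
        direction = "A_higher"
    elif res.statistic < u_mid:
        direction = "B_higher"
    else:
        direction = "none"
    return {"pvalue": float(res.pvalue), "direction": direction, "U": float(res.statistic)}
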