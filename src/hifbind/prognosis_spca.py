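"""Clinical stratification, Kaplan-Meier / Cox machinery, and the
supervised-PCA gene predictor with leave-one-out cross-validation.

Cox models are univariate throughout (a screening step and a final score
evaluation), so the partial-likelihood Newton solver is written to run on a
whole patients x genes matrix at once; the leave-one-out loop refits the
screen and the SVD in every fold and would be prohibitively slow with a
general-purpose fitter.  Efron's approximation is used for tied event times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "PredictorModel",
    "SurvivalFit",
    "CoxResult",
    "prognostic_score",
    "stratify_cohort",
    "km_estimator",
    "cox_fit",
    "cox_fit_batch",
    "univariate_screen",
    "spca_fit",
    "loo_cv",
    "median_split_eval",
]

GOOD_PROGNOSIS = "good"
POOR_PROGNOSIS = "poor"

_MAX_COEF = 50.0


@dataclass(frozen=True)
class PatientRecord:
    id: str
    age: float
    stage: int
    metastasis: bool
    deceased: bool
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"patient {self.id}: follow-up time must be > 0")
        if self.stage not in {1, 2, 3, 4}:
            raise ValueError(f"patient {self.id}: stage must be 1-4, got {self.stage}")
        if self.event and not self.deceased:
            raise ValueError(f"patient {self.id}: observed death implies deceased flag")


@dataclass
class PredictorModel:
    """Screened genes with unit-norm SVD weights and fold standardisation."""

    genes: list[str]
    weights: np.ndarray
    centering: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(np.linalg.norm(self.weights), 1.0, atol=1e-8):
            raise ValueError("weights must have unit L2 norm")

    def score(self, expression: np.ndarray) -> np.ndarray:
        """Project (standardised) expression rows onto the weight vector."""
        x = np.atleast_2d(np.asarray(expression, dtype=float))
        z = (x - self.centering) / self.scale
        return z @ self.weights

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "weights": self.weights.tolist(),
            "centering": self.centering.tolist(),
            "scale": self.scale.tolist(),
        }


@dataclass
class CoxResult:
    coef: float
    hazard_ratio: float
    se: float
    pvalue: float
    ci95: tuple[float, float]
    converged: bool
    n_events: int


@dataclass
class SurvivalFit:
    hazard_ratio: float
    ci95: tuple[float, float]
    pvalue: float
    km_curves: dict


def prognostic_score(patient: PatientRecord) -> tuple[int, str]:
    """0-4 clinical risk score: one point each for age > 60, stage 3 or 4,
    metastasis, and deceased status.  Scores 0-1 are the good-prognosis
    group, 2-4 the poor-prognosis group.

    Note the deceased criterion overlaps the survival outcome; downstream
    survival analyses of these groups are partially circular by design.
    """
    score = int(patient.age > 60) + int(patient.stage >= 3)
    score += int(patient.metastasis) + int(patient.deceased)
    return score, (GOOD_PROGNOSIS if score <= 1 else POOR_PROGNOSIS)


def stratify_cohort(clinical: pd.DataFrame) -> pd.DataFrame:
    """Score every patient; rows with missing fields are excluded and counted."""
    required = ["id", "age", "stage", "metastasis", "deceased", "time", "event"]
    missing_cols = [c for c in required if c not in clinical.columns]
    if missing_cols:
        raise ValueError(f"clinical table missing column(s) {missing_cols}")
    complete = clinical.dropna(subset=required)
    n_dropped = len(clinical) - len(complete)
    if n_dropped:
        logger.info("excluded %d patient(s) with missing clinical data", n_dropped)
    rows = []
    for row in complete.itertuples():
        patient = PatientRecord(
            str(row.id), float(row.age), int(row.stage), bool(row.metastasis),
            bool(row.deceased), float(row.time), bool(row.event),
        )
        score, group = prognostic_score(patient)
        rows.append((patient.id, score, group))
    return pd.DataFrame(rows, columns=["id", "score", "group"])


def km_estimator(
    times: Sequence[float], events: Sequence[bool]
) -> dict:
    """Product-limit survival estimate.

    Returns ``times`` (distinct event times), ``survival`` (value of S just
    after each event time) and an ``evaluate`` callable; S(0) = 1 and the
    curve is right-continuous.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("need at least one subject")
    event_times = np.unique(t[e])
    surv = []
    s = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / at_risk
        surv.append(s)
    surv_arr = np.asarray(surv)

    def evaluate(query: float | np.ndarray) -> np.ndarray:
        q = np.atleast_1d(np.asarray(query, dtype=float))
        idx = np.searchsorted(event_times, q, side="right")
        out = np.where(idx == 0, 1.0, surv_arr[np.maximum(idx - 1, 0)] if surv_arr.size else 1.0)
        return out

    return {"times": event_times, "survival": surv_arr, "evaluate": evaluate}


def _prepare_cox(times: np.ndarray, events: np.ndarray):
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    n = t.size
    # first sorted index of each subject's time group = start of its risk set
    group_first = np.searchsorted(t, t, side="left")
    ev_idx = np.flatnonzero(e)
    ev_t = t[ev_idx]
    # event tie groups
    grp_starts = np.flatnonzero(np.concatenate(([True], np.diff(ev_t) > 0)))
    grp_ids = np.cumsum(np.concatenate(([0], (np.diff(ev_t) > 0).astype(int))))
    grp_sizes = np.add.reduceat(np.ones_like(ev_idx), grp_starts)
    # per-event Efron fraction l/d within its tie group
    within = np.arange(ev_idx.size) - grp_starts[grp_ids]
    l_frac = within / grp_sizes[grp_ids]
    risk_start = group_first[ev_idx]  # risk-set start index per event row
    return order, t, e, ev_idx, grp_starts, grp_ids, l_frac, risk_start


def _rev_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def cox_fit_batch(
    X: np.ndarray,
    times: Sequence[float],
    events: Sequence[bool],
    max_iter: int = 30,
    tol: float = 1e-9,
) -> dict:
    """Univariate Cox fits for every column of ``X`` simultaneously.

    Newton-Raphson on the Efron partial likelihood, vectorised across
    columns.  Returns arrays ``coef``, ``se``, ``pvalue``, ``converged``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.ndim != 2:
        raise ValueError("X must be patients x covariates")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n, g = X.shape
    if times.size != n or events.size != n:
        raise ValueError("times/events length mismatch with X rows")
    n_events = int(events.sum())
    if n_events < 2:
        nan = np.full(g, np.nan)
        return {"coef": nan, "se": nan, "pvalue": nan,
                "converged": np.zeros(g, dtype=bool), "n_events": n_events}

    order, t, e, ev_idx, grp_starts, grp_ids, l_frac, risk_start = _prepare_cox(
        times, events
    )
    Xs = X[order]
    x_ev = Xs[ev_idx]  # event rows
    sum_x_events = x_ev.sum(axis=0)

    beta = np.zeros(g)
    converged = np.zeros(g, dtype=bool)
    info = np.full(g, np.nan)
    for _ in range(max_iter):
        eta = np.clip(Xs * beta, -500, 500)
        w = np.exp(eta)
        xw = Xs * w
        xxw = Xs * xw
        cw, cxw, cxxw = _rev_cumsum(w), _rev_cumsum(xw), _rev_cumsum(xxw)
        R = cw[risk_start]
        Rx = cxw[risk_start]
        Rxx = cxxw[risk_start]
        T = np.add.reduceat(w[ev_idx], grp_starts, axis=0)[grp_ids]
        Tx = np.add.reduceat(xw[ev_idx], grp_starts, axis=0)[grp_ids]
        Txx = np.add.reduceat(xxw[ev_idx], grp_starts, axis=0)[grp_ids]
        lf = l_frac[:, None]
        denom = np.maximum(R - lf * T, 1e-300)
        num_x = Rx - lf * Tx
        num_xx = Rxx - lf * Txx
        grad = sum_x_events - (num_x / denom).sum(axis=0)
        info = (num_xx / denom - (num_x / denom) ** 2).sum(axis=0)
        safe_info = np.where(info > 1e-12, info, np.nan)
        step = grad / safe_info
        step = np.where(np.isnan(step), 0.0, np.clip(step, -2.0, 2.0))
        beta = np.clip(beta + step, -_MAX_COEF, _MAX_COEF)
        converged = np.abs(step) < tol
        if np.all(converged | (np.abs(beta) >= _MAX_COEF)):
            break
    diverged = np.abs(beta) >= _MAX_COEF
    converged = converged & ~diverged
    with np.errstate(invalid="ignore", divide="ignore"):
        se = 1.0 / np.sqrt(np.where(info > 1e-12, info, np.nan))
        z = beta / se
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
    return {
        "coef": beta, "se": se, "pvalue": pvalue,
        "converged": converged, "n_events": n_events,
    }


def cox_fit(
    covariate: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald inference)."""
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    res = cox_fit_batch(x[:, None], times, events)
    coef = float(res["coef"][0])
    se = float(res["se"][0])
    conv = bool(res["converged"][0])
    if res["n_events"] < 2 or not np.isfinite(coef) or not np.isfinite(se):
        logger.warning("degenerate Cox fit (%d events); result flagged", res["n_events"])
        return CoxResult(float("nan"), float("nan"), float("nan"), float("nan"),
                         (float("nan"), float("nan")), False, res["n_events"])
    half = 1.959963984540054 * se
    lo, hi = max(coef - half, -700.0), min(coef + half, 700.0)
    return CoxResult(
        coef=coef,
        hazard_ratio=float(np.exp(coef)),
        se=se,
        pvalue=float(res["pvalue"][0]),
        ci95=(float(np.exp(lo)), float(np.exp(hi))),
        converged=conv,
        n_events=res["n_events"],
    )


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd, mean, sd


def univariate_screen(
    expression: np.ndarray,
    genes: Sequence[str],
    times: Sequence[float],
    events: Sequence[bool],
    alpha: float = 0.05,
) -> list[str]:
    """Genes whose standardised expression predicts survival at p < alpha."""
    x = np.asarray(expression, dtype=float)
    if x.shape[1] != len(genes):
        raise ValueError("expression columns must match gene list")
    if len(genes) < 2:
        raise ValueError("need >= 2 candidate genes")
    z, _, _ = _standardize(x)
    res = cox_fit_batch(z, times, events)
    pvals = res["pvalue"]
    keep = [g for g, p in zip(genes, pvals) if np.isfinite(p) and p < alpha]
    if not keep:
        logger.info("univariate screen retained no genes at alpha=%.3g", alpha)
    return keep


def spca_fit(
    expression: np.ndarray,
    genes: Sequence[str],
    times: Sequence[float],
    events: Sequence[bool],
) -> tuple[PredictorModel, np.ndarray]:
    """Supervised-PCA predictor: SVD weights on the screened gene block.

    Genes are centred and scaled; the weight vector is the first right
    singular vector of the patients x genes matrix, sign-oriented so that a
    higher score means higher hazard (checked with a Cox fit on the score).
    Returns the model and per-patient risk scores.
    """
    x = np.asarray(expression, dtype=float)
    if x.shape[1] < 2:
        raise ValueError(
            "screen produced < 2 genes; relax alpha or provide more candidates"
        )
    if x.shape[0] < 3:
        raise ValueError("need >= 3 patients")
    z, mean, sd = _standardize(x)
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    weights = vt[0]
    scores = z @ weights
    if np.all(scores == scores[0]):
        orient = 1.0
    else:
        fit = cox_fit_batch(scores[:, None], times, events)
        coef = fit["coef"][0]
        orient = -1.0 if np.isfinite(coef) and coef < 0 else 1.0
    weights = weights * orient
    model = PredictorModel(list(genes), weights, mean, sd)
    return model, z @ weights


def loo_cv(
    expression: np.ndarray,
    genes: Sequence[str],
    times: Sequence[float],
    events: Sequence[bool],
    alpha: float = 0.05,
    screen_and_fit: Callable | None = None,
) -> np.ndarray:
    """Out-of-fold risk score per patient.

    Each fold refits the univariate screen and the SVD on the other n-1
    patients and projects the held-out patient with the fold's centring and
    scale.  Folds whose screen retains < 2 genes yield NaN (logged).

    ``screen_and_fit(expression, genes, times, events, alpha)`` may replace
    the default screen+SPCA pipeline; it must return ``(kept_genes, model)``
    or ``(kept_genes, None)`` when the fold fails.
    """
    x = np.asarray(expression, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"need >= 10 patients for leave-one-out, got {n}")
    genes = list(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    if screen_and_fit is None:
        screen_and_fit = _default_screen_and_fit
    scores = np.full(n, np.nan)
    n_failed = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        kept, model = screen_and_fit(x[mask], genes, times[mask], events[mask], alpha)
        if model is None:
            n_failed += 1
            continue
        cols = [gene_index[g] for g in kept]
        scores[i] = model.score(x[i, cols])[0]
    if n_failed:
        logger.warning("%d/%d leave-one-out fold(s) failed the screen", n_failed, n)
    return scores


def _default_screen_and_fit(x, genes, times, events, alpha):
    """One fold of the predictor pipeline: univariate screen then SPCA."""
    kept = univariate_screen(x, genes, times, events, alpha)
    if len(kept) < 2:
        return kept, None
    cols = [genes.index(g) for g in kept]
    model, _ = spca_fit(x[:, cols], kept, times, events)
    return kept, model


def median_split_eval(
    risk_scores: Sequence[float],
    times: Sequence[float],
    events: Sequence[bool],
) -> SurvivalFit:
    """Split at the median risk score (ties below) and compare survival.

    The hazard ratio is for the above-median group versus the rest, from a
    Cox fit on the binary indicator; Kaplan-Meier curves are returned for
    both groups.
    """
    scores = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    ok = np.isfinite(scores)
    if not np.all(ok):
        logger.info("median_split_eval drops %d patient(s) with NaN scores",
                    int(np.sum(~ok)))
        scores, times, events = scores[ok], times[ok], events[ok]
    median = float(np.median(scores))
    high = scores > median
    if high.sum() == 0 or high.sum() == scores.size:
        raise ValueError("degenerate split: all scores tied at the median")
    if high.sum() < 2 or (scores.size - high.sum()) < 2:
        raise ValueError("need >= 2 patients per group")
    fit = cox_fit(high.astype(float), times, events)
    km_curves = {
        "above_median": km_estimator(times[high], events[high]),
        "below_median": km_estimator(times[~high], events[~high]),
    }
    return SurvivalFit(
        hazard_ratio=fit.hazard_ratio,
        ci95=fit.ci95,
        pvalue=fit.pvalue,
        km_curves=km_curves,
    )
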