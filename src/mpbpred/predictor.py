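"""Prediction-model construction and evaluation for baldness status.

Two model flavours mirror the study design: a compact model of the
strongest independent predictors (stepwise multivariate selection, see
:func:`mpbpred.association.multivariate_select`) and an extended model
built by forward selection over univariate-ranked candidates, admitting
each SNP only if it raises the in-sample AUC by at least a small delta
(0.001 by default).

Calls are thresholded with an inconclusive zone: at threshold t >= 0.5 a
sample is called bald when P(bald) >= t, non-bald when P(bald) <= 1 - t,
and inconclusive otherwise (at t = 0.5 the zone is empty).  Sensitivity,
specificity, PPV and NPV are computed over conclusive calls only; AUC is
threshold-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .genodata import MISSING, GenotypeMatrix, SampleRecord
from .association import (
    FittedLogit,
    SeparationError,
    ConvergenceError,
    coded_matrix,
    fit_logistic,
    univariate_scan,
)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both outcome classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def nagelkerke(fit: FittedLogit) -> float:
    """Nagelkerke pseudo-R^2: Cox-Snell R^2 rescaled to a [0, 1] maximum."""
    if fit.llf < fit.llnull - 1e-8:
        raise ValueError("model log-likelihood below null: not an ML fit")
    n = fit.n
    r2_cs = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
    denom = 1.0 - np.exp(2.0 * fit.llnull / n)
    return float(r2_cs / denom) if denom > 0 else 0.0


@dataclass(frozen=True)
class PredictionModel:
    """Fitted logistic prediction model over an ordered SNP set."""

    snps: tuple[str, ...]
    codings: tuple[str, ...]
    intercept: float
    betas: tuple[float, ...]
    train_auc: float | None = None
    nagelkerke_r2: float | None = None
    overall_p: float | None = None
    details: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.betas) != len(self.snps) or len(self.codings) != len(self.snps):
            raise ValueError("snps, codings and betas must have equal length")

    def design(self, gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        """Coded design matrix for this model's SNPs + complete-case mask."""
        cols, masks = [], []
        from .association import code  # local to keep namespace tight

        for rsid, mode in zip(self.snps, self.codings):
            j = gm.snp_index(rsid)
            c = code(gm.dosage[:, j], gm.snps[j], mode)
            cols.append(c)
            masks.append(c != MISSING)
        if not cols:
            return (np.empty((gm.n_samples, 0)), np.ones(gm.n_samples, bool))
        X = np.column_stack(cols)
        return X, np.logical_and.reduce(masks)

    def probabilities(self, gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
        """P(bald) per sample and the mask of samples with complete data."""
        X, complete = self.design(gm)
        eta = self.intercept + X.astype(float) @ np.asarray(self.betas)
        p = 1.0 / (1.0 + np.exp(-eta))
        p[~complete] = np.nan
        return p, complete


def model_from_fit(
    rsids: Sequence[str],
    codings: Sequence[str],
    fit: FittedLogit,
    y: np.ndarray | None = None,
    X: np.ndarray | None = None,
) -> PredictionModel:
    """Package a fitted logistic regression as a PredictionModel."""
    train_auc = None
    if y is not None and X is not None and len(rsids) > 0:
        train_auc = auc(fit.predict(X), y)
    details = {}
    for k, rsid in enumerate(rsids):
        i = k + 1 if fit.include_intercept else k
        details[rsid] = {
            "beta": float(fit.params[i]),
            "or": float(np.exp(fit.params[i])),
            "ci95": fit.ci95(k),
            "p": float(fit.pvalues[i]),
        }
    return PredictionModel(
        snps=tuple(rsids),
        codings=tuple(codings),
        intercept=fit.intercept,
        betas=tuple(float(b) for b in fit.betas),
        train_auc=train_auc,
        nagelkerke_r2=nagelkerke(fit),
        overall_p=fit.lr_pvalue if len(rsids) > 0 else None,
        details=details,
    )


def rank_candidates(
    gm: GenotypeMatrix, labels: np.ndarray | None = None
) -> list[str]:
    """Candidates ordered by univariate additive p ascending, rsid tie-break."""
    results = univariate_scan(gm, labels, modes=("additive",))
    keyed = [
        (r.p if np.isfinite(r.p) else np.inf, r.rsid) for r in results
    ]
    return [rsid for _, rsid in sorted(keyed)]


def forward_auc_select(
    gm: GenotypeMatrix,
    labels: np.ndarray | None = None,
    candidates: list[str] | None = None,
    delta: float = 0.001,
) -> PredictionModel:
    """Forward selection keeping each candidate that lifts training AUC.

    Candidates are visited in order of univariate significance (including
    non-significant SNPs, which can still contribute jointly); a candidate
    is kept iff refitting the joint model raises the in-sample AUC by at
    least ``delta``. Collinear or separation-causing candidates are skipped.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    y_all = gm.labels() if labels is None else np.asarray(labels)
    order = candidates if candidates is not None else rank_candidates(gm, y_all)

    kept: list[str] = []
    best_auc = 0.5

    def fit_set(rsids: list[str]):
        X, complete = coded_matrix(gm, rsids)
        fit = fit_logistic(y_all[complete], X[complete].astype(float))
        a = auc(fit.predict(X[complete].astype(float)), y_all[complete])
        return fit, a, X, complete

    for rsid in order:
        try:
            fit, a, X, complete = fit_set(kept + [rsid])
        except (SeparationError, ConvergenceError, ValueError):
            continue
        if a - best_auc >= delta:
            kept.append(rsid)
            best_auc = a
    fit, a, X, complete = fit_set(kept)
    return model_from_fit(
        kept, ["additive"] * len(kept), fit,
        y=y_all[complete], X=X[complete].astype(float),
    )


# ---------------------------------------------------------------------------
# Thresholded prediction and evaluation

BALD, NON_BALD, INCONCLUSIVE = "bald", "non_bald", "inconclusive"


@dataclass(frozen=True)
class PredictionOutcome:
    sample_id: str
    p_bald: float
    call: str
    threshold: float


def predict(
    model: PredictionModel, gm: GenotypeMatrix, threshold: float = 0.5
) -> tuple[list[PredictionOutcome], list[str]]:
    """Thresholded calls for every sample with complete model genotypes.

    Returns ``(outcomes, excluded_ids)``; samples missing any model SNP are
    excluded and reported separately. At the probability boundary the call
    is made (only probabilities strictly inside (1-t, t) are inconclusive).
    """
    if not 0.5 <= threshold < 1.0:
        raise ValueError("threshold must be in [0.5, 1)")
    p, complete = model.probabilities(gm)
    outcomes, excluded = [], []
    for i, sample in enumerate(gm.samples):
        if not complete[i]:
            excluded.append(sample.sample_id)
            continue
        if p[i] >= threshold:
            call = BALD
        elif p[i] <= 1.0 - threshold:
            call = NON_BALD
        else:
            call = INCONCLUSIVE
        outcomes.append(
            PredictionOutcome(sample.sample_id, float(p[i]), call, threshold)
        )
    return outcomes, excluded


@dataclass
class EvaluationReport:
    """Accuracy summary of thresholded predictions against true status.

    Rates carry their integer numerator/denominator pairs so published-style
    "87.10% (27/31)" figures can be reproduced exactly.
    """

    auc: float
    sensitivity: tuple[int, int]
    specificity: tuple[int, int]
    ppv: tuple[int, int]
    npv: tuple[int, int]
    correct_by_category: dict[int, tuple[int, int]]
    overall_correct: tuple[int, int]
    inconclusive: tuple[int, int]
    n_excluded_missing: int = 0

    @staticmethod
    def _rate(pair: tuple[int, int]) -> float:
        num, den = pair
        return num / den if den else float("nan")

    def rate(self, name: str, category: int | None = None) -> float:
        if name == "correct_by_category":
            return self._rate(self.correct_by_category[category])
        return self._rate(getattr(self, name))


def evaluate(
    outcomes: list[PredictionOutcome],
    samples: list[SampleRecord],
    n_excluded_missing: int = 0,
) -> EvaluationReport:
    """Score thresholded calls; confusion rates over conclusive calls only."""
    by_id = {s.sample_id: s for s in samples}
    y_true, p_all = [], []
    tp = fp = tn = fn = 0
    cat_ok: dict[int, int] = {}
    cat_n: dict[int, int] = {}
    n_inconclusive = 0
    for out in outcomes:
        sample = by_id[out.sample_id]
        y_true.append(sample.label)
        p_all.append(out.p_bald)
        if out.call == INCONCLUSIVE:
            n_inconclusive += 1
            continue
        called_bald = out.call == BALD
        correct = called_bald == bool(sample.label)
        cat_n[sample.category] = cat_n.get(sample.category, 0) + 1
        cat_ok[sample.category] = cat_ok.get(sample.category, 0) + int(correct)
        if called_bald and sample.label:
            tp += 1
        elif called_bald:
            fp += 1
        elif sample.label:
            fn += 1
        else:
            tn += 1
    the_auc = auc(np.array(p_all), np.array(y_true))
    n_conclusive = tp + fp + tn + fn
    return EvaluationReport(
        auc=the_auc,
        sensitivity=(tp, tp + fn),
        specificity=(tn, tn + fp),
        ppv=(tp, tp + fp),
        npv=(tn, tn + fn),
        correct_by_category={
            c: (cat_ok.get(c, 0), cat_n[c]) for c in sorted(cat_n)
        },
        overall_correct=(tp + tn, n_conclusive),
        inconclusive=(n_inconclusive, len(outcomes)),
        n_excluded_missing=n_excluded_missing,
    )


def age_stratified_report(
    outcomes: list[PredictionOutcome],
    samples: list[SampleRecord],
) -> dict[str, EvaluationReport]:
    """Evaluate separately for men <50 (categories 1+3) and >=50 (2+4)."""
    by_id = {s.sample_id: s for s in samples}
    young = [o for o in outcomes if by_id[o.sample_id].age < 50]
    old = [o for o in outcomes if by_id[o.sample_id].age >= 50]
    reports = {}
    if young:
        reports["under50"] = evaluate(young, samples)
    if old:
        reports["50plus"] = evaluate(old, samples)
    return reports


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if np.any(expected == 0):
        return float("nan"), float("nan")
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, 1))
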