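"""Genotype coding schemes and logistic association testing.

SNPs enter the models under an inheritance coding: additive (minor-allele
count 0/1/2), dominant (any minor allele), or recessive (two minor alleles).
Hemizygous male X genotypes are coded 0/2 under the additive scheme — a
minor-allele hemizygote carries the full two-unit effect of an autosomal
minor-allele homozygote — and 0/1 under dominant and recessive alike.
Association is tested case (early-bald, category 1) versus control
(old non-bald, category 2) by binary logistic regression, with Wald
odds ratios, 95% confidence intervals and p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .genodata import MISSING, GenotypeMatrix, SNPInfo

MODES = ("additive", "dominant", "recessive")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist (infinite coefficient)."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


def code(dosage: np.ndarray, snp: SNPInfo, mode: str) -> np.ndarray:
    """Code minor-allele dosages under an inheritance mode.

    Missing calls (-1) propagate as -1; callers exclude them pairwise.
    """
    if mode not in MODES:
        raise ValueError(f"unknown coding mode {mode!r}; expected one of {MODES}")
    dosage = np.asarray(dosage)
    out = np.full(dosage.shape, MISSING, dtype=np.int8)
    ok = dosage != MISSING
    d = dosage[ok]
    if snp.x_linked:
        # single allele: minor carrier is the "homozygote"
        coded = d * 2 if mode == "additive" else d
    else:
        if mode == "additive":
            coded = d
        elif mode == "dominant":
            coded = (d >= 1).astype(np.int8)
        else:
            coded = (d == 2).astype(np.int8)
    out[ok] = coded
    return out


@dataclass
class FittedLogit:
    """Maximum-likelihood logistic fit with Wald inference."""

    params: np.ndarray        # intercept first if include_intercept
    bse: np.ndarray
    pvalues: np.ndarray
    llf: float
    llnull: float
    n: int
    include_intercept: bool

    @property
    def intercept(self) -> float:
        return float(self.params[0]) if self.include_intercept else 0.0

    @property
    def betas(self) -> np.ndarray:
        return self.params[1:] if self.include_intercept else self.params

    def ci95(self, k: int) -> tuple[float, float]:
        """Wald 95% CI for the odds ratio of coefficient k (0 = first slope)."""
        i = k + 1 if self.include_intercept else k
        lo = np.exp(self.params[i] - 1.96 * self.bse[i])
        hi = np.exp(self.params[i] + 1.96 * self.bse[i])
        return float(lo), float(hi)

    @property
    def lr_pvalue(self) -> float:
        """Likelihood-ratio p-value of the whole model against intercept-only."""
        df = len(self.betas)
        lr = 2.0 * (self.llf - self.llnull)
        return float(stats.chi2.sf(max(lr, 0.0), df))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.include_intercept:
            X = sm.add_constant(X, has_constant="add")
        return 1.0 / (1.0 + np.exp(-(X @ self.params)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    include_intercept: bool = True,
    maxiter: int = 100,
) -> FittedLogit:
    """Fit a binary logistic regression by Newton-scored IRLS.

    Raises :class:`SeparationError` on (quasi-)perfect separation and
    :class:`ConvergenceError` if the score does not vanish within
    ``maxiter`` iterations.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"X has {X.shape[0]} rows but y has {y.shape[0]} samples"
        )
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 samples in each outcome class")
    if X.shape[1] > 0 and np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor column")
    design = sm.add_constant(X, has_constant="add") if include_intercept else X
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = model.fit(method="newton", maxiter=maxiter, disp=False, tol=1e-10)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(f"no convergence in {maxiter} iterations")
    if np.any(np.abs(res.params) > 15) or np.any(~np.isfinite(res.bse)):
        raise SeparationError("quasi-separation: unbounded coefficient estimate")
    return FittedLogit(
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        pvalues=np.asarray(res.pvalues, dtype=float),
        llf=float(res.llf),
        llnull=float(res.llnull),
        n=len(y),
        include_intercept=include_intercept,
    )


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP logistic association result under one coding mode."""

    rsid: str
    mode: str
    beta: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_used: int
    note: str = ""


def _assoc_one(
    y: np.ndarray, coded: np.ndarray, rsid: str, mode: str
) -> AssociationResult | None:
    ok = coded != MISSING
    yy, xx = y[ok], coded[ok].astype(float)
    if np.ptp(xx) == 0:
        return AssociationResult(
            rsid, mode, np.nan, np.nan, (np.nan, np.nan), np.nan, int(ok.sum()),
            note="monomorphic: skipped",
        )
    try:
        fit = fit_logistic(yy, xx[:, None])
    except (SeparationError, ConvergenceError, ValueError) as exc:
        return AssociationResult(
            rsid, mode, np.nan, np.nan, (np.nan, np.nan), np.nan, int(ok.sum()),
            note=f"fit failed: {exc}",
        )
    beta = float(fit.betas[0])
    return AssociationResult(
        rsid=rsid,
        mode=mode,
        beta=beta,
        or_=float(np.exp(beta)),
        ci95=fit.ci95(0),
        p=float(fit.pvalues[1]),
        n_used=len(yy),
    )


def univariate_scan(
    gm: GenotypeMatrix,
    labels: np.ndarray | None = None,
    modes: tuple[str, ...] = MODES,
) -> list[AssociationResult]:
    """Test each SNP against the binary phenotype under each coding mode.

    Samples with a missing call at a SNP are excluded pairwise for that SNP.
    Significance is judged at p < 0.05 with no multiple-testing correction.
    """
    y = gm.labels() if labels is None else np.asarray(labels)
    results = []
    for j, snp in enumerate(gm.snps):
        for mode in modes:
            coded = code(gm.dosage[:, j], snp, mode)
            res = _assoc_one(y.astype(float), coded, snp.rsid, mode)
            if res is not None:
                results.append(res)
    return results


def significant_snps(
    results: list[AssociationResult], alpha: float = 0.05
) -> list[str]:
    """rsIDs significant under at least one coding mode (uncorrected)."""
    hits = {r.rsid for r in results if np.isfinite(r.p) and r.p < alpha}
    seen: list[str] = []
    for r in results:
        if r.rsid in hits and r.rsid not in seen:
            seen.append(r.rsid)
    return seen


def coded_matrix(
    gm: GenotypeMatrix, rsids: list[str], mode: str = "additive"
) -> tuple[np.ndarray, np.ndarray]:
    """Additively coded design matrix for ``rsids`` plus complete-case mask."""
    cols = []
    for rsid in rsids:
        j = gm.snp_index(rsid)
        cols.append(code(gm.dosage[:, j], gm.snps[j], mode))
    X = np.column_stack(cols) if cols else np.empty((gm.n_samples, 0), dtype=np.int8)
    complete = ~(X == MISSING).any(axis=1) if cols else np.ones(gm.n_samples, bool)
    return X, complete


def _drop_collinear(gm: GenotypeMatrix, rsids: list[str]) -> tuple[list[str], list[str]]:
    """Among perfectly collinear SNP pairs, keep the first; return kept, dropped."""
    kept: list[str] = []
    dropped: list[str] = []
    for rsid in rsids:
        x = gm.column(rsid).astype(float)
        duplicate = False
        for other in kept:
            z = gm.column(other).astype(float)
            ok = (x != MISSING) & (z != MISSING)
            if ok.sum() > 1 and np.ptp(x[ok]) > 0 and np.ptp(z[ok]) > 0:
                r = np.corrcoef(x[ok], z[ok])[0, 1]
                if r * r > 1 - 1e-12:
                    duplicate = True
                    break
        (dropped if duplicate else kept).append(rsid)
    return kept, dropped


def multivariate_select(
    gm: GenotypeMatrix,
    labels: np.ndarray | None = None,
    candidates: list[str] | None = None,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_snps: int | None = None,
):
    """Forward-LR stepwise multivariate logistic selection over candidate SNPs.

    At each step the candidate with the smallest likelihood-ratio p-value
    enters if p < ``p_enter``; included SNPs whose removal LR p >= ``p_remove``
    are then dropped. SNPs are coded additively (male X as 0/2); samples are
    complete-case within the current model. Perfectly collinear candidates are
    reduced to a single representative with a warning.  ``max_snps`` caps the
    model at the first (most significant) k entrants — use 5 for the compact
    model of strongest independent predictors.

    Returns a :class:`~mpbpred.predictor.PredictionModel` refitted on the
    final SNP set, with per-SNP joint statistics in ``model.details``.
    """
    from .predictor import model_from_fit  # deferred: avoid import cycle

    y_all = gm.labels() if labels is None else np.asarray(labels)
    cand = list(candidates) if candidates is not None else gm.rsids
    cand, dropped = _drop_collinear(gm, cand)
    if dropped:
        warnings.warn(f"dropped perfectly collinear SNP(s): {', '.join(dropped)}")

    selected: list[str] = []

    def fit_set(rsids: list[str]) -> FittedLogit:
        X, complete = coded_matrix(gm, rsids)
        return fit_logistic(y_all[complete], X[complete].astype(float))

    while True:
        changed = False
        # forward entry
        at_cap = max_snps is not None and len(selected) >= max_snps
        current_fit = fit_set(selected) if selected else None
        best_p, best_rsid = np.inf, None
        for rsid in cand if not at_cap else []:
            if rsid in selected:
                continue
            try:
                trial = fit_set(selected + [rsid])
            except (SeparationError, ConvergenceError, ValueError):
                continue
            if current_fit is None:
                lr_p = trial.lr_pvalue
            else:
                # complete-case sets can differ; refit reduced on trial's samples
                X, complete = coded_matrix(gm, selected + [rsid])
                reduced = fit_logistic(
                    y_all[complete], X[complete, :-1].astype(float)
                ) if selected else None
                ll0 = reduced.llf if reduced is not None else trial.llnull
                lr = 2.0 * (trial.llf - ll0)
                lr_p = float(stats.chi2.sf(max(lr, 0.0), 1))
            if lr_p < best_p:
                best_p, best_rsid = lr_p, rsid
        if best_rsid is not None and best_p < p_enter:
            selected.append(best_rsid)
            changed = True
        # backward removal
        if len(selected) > 1:
            full = fit_set(selected)
            worst_p, worst_rsid = -np.inf, None
            for rsid in selected:
                rest = [r for r in selected if r != rsid]
                X, complete = coded_matrix(gm, selected)
                reduced = fit_logistic(
                    y_all[complete],
                    X[complete][:, [selected.index(r) for r in rest]].astype(float),
                )
                lr = 2.0 * (full.llf - reduced.llf)
                lr_p = float(stats.chi2.sf(max(lr, 0.0), 1))
                if lr_p > worst_p:
                    worst_p, worst_rsid = lr_p, rsid
            if worst_rsid is not None and worst_p >= p_remove:
                selected.remove(worst_rsid)
                changed = True
        if not changed:
            break

    X, complete = coded_matrix(gm, selected)
    fit = fit_set(selected)
    model = model_from_fit(
        selected, ["additive"] * len(selected), fit,
        y=y_all[complete], X=X[complete].astype(float),
    )
    return model
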