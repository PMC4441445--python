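"""Weighted genotype risk score (GRS) and quartile risk analysis.

The GRS of a sample is the sum over model SNPs of |beta| times the count
of that SNP's risk allele.  The risk allele is the allele whose carriage
increases the odds of baldness: the minor allele when its fitted beta is
positive, otherwise the major allele (so counting is flipped, and every
weight acts in the risk-increasing direction).  Male X-linked counts are
0 or 2.  With five SNPs the count totals range 0-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeMatrix
from .association import fit_logistic
from .predictor import PredictionModel, chi2_2x2


@dataclass
class RiskScoreResult:
    sample_ids: list[str]
    grs: np.ndarray                 # weighted risk-allele sum per sample
    risk_allele_count: np.ndarray   # unweighted risk-allele total per sample
    excluded: list[str]             # samples missing a model SNP
    quartile: np.ndarray | None = None
    quartile_or: dict[int, dict] | None = None


def risk_allele_matrix(
    gm: GenotypeMatrix, model: PredictionModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample risk-allele counts for each model SNP.

    Returns ``(counts, weights, complete_mask)``; counts use the 0/2
    hemizygous convention for male X SNPs.
    """
    counts = np.zeros((gm.n_samples, len(model.snps)))
    weights = np.abs(np.asarray(model.betas, dtype=float))
    masks = []
    for j, (rsid, beta) in enumerate(zip(model.snps, model.betas)):
        snp = gm.snp(rsid)
        d = gm.column(rsid).astype(float)
        ok = d != MISSING
        masks.append(ok)
        unit = 2.0 if snp.x_linked else 1.0
        minor_count = d * unit          # 0/1/2 autosomal, 0/2 male X
        max_count = 2.0
        # minor allele is the risk allele iff its effect is risk-increasing
        risk = minor_count if beta > 0 else max_count - minor_count
        counts[:, j] = np.where(ok, risk, np.nan)
    complete = np.logical_and.reduce(masks)
    return counts, weights, complete


def compute_grs(gm: GenotypeMatrix, model: PredictionModel) -> RiskScoreResult:
    """Weighted risk-allele counting GRS for every complete sample."""
    if len(model.snps) == 0:
        raise ValueError("model has no SNPs")
    counts, weights, complete = risk_allele_matrix(gm, model)
    ids = [s.sample_id for s in gm.samples]
    kept = [i for i in range(gm.n_samples) if complete[i]]
    excluded = [ids[i] for i in range(gm.n_samples) if not complete[i]]
    grs = counts[kept] @ weights
    totals = counts[kept].sum(axis=1)
    return RiskScoreResult(
        sample_ids=[ids[i] for i in kept],
        grs=grs,
        risk_allele_count=totals,
        excluded=excluded,
    )


def generic_grs(
    gm: GenotypeMatrix, snp_weights: dict[str, float]
) -> RiskScoreResult:
    """GRS for an arbitrary SNP/weight table (signed weights: negative
    means the major allele is the risk allele)."""
    model = PredictionModel(
        snps=tuple(snp_weights),
        codings=tuple("additive" for _ in snp_weights),
        intercept=0.0,
        betas=tuple(snp_weights.values()),
    )
    return compute_grs(gm, model)


def assign_quartiles(scores: np.ndarray) -> np.ndarray:
    """Rank-based quartiles 1-4; tied scores all go to the lower quartile."""
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if len(np.unique(scores)) < 4:
        raise ValueError("need at least 4 distinct score values")
    order = np.argsort(scores, kind="stable")
    rank_quartile = np.minimum(np.arange(n) * 4 // n, 3) + 1
    q = np.empty(n, dtype=int)
    q[order] = rank_quartile
    # ties span quartile boundaries -> pull the whole tie block down
    for value in np.unique(scores):
        tie = scores == value
        if tie.sum() > 1:
            q[tie] = q[tie].min()
    return q


def quartile_or(scores: np.ndarray, labels: np.ndarray) -> dict[int, dict]:
    """Odds of baldness per GRS quartile versus the lowest quartile.

    Fits a logistic regression on quartile indicator variables; returns
    {quartile: {"or", "ci95", "p", "n"}} with quartile 1 as reference.
    """
    labels = np.asarray(labels)
    q = assign_quartiles(scores)
    if not np.any(q == 1):
        raise ValueError("reference quartile (1) is empty")
    present = sorted(set(q) - {1})
    X = np.column_stack([(q == k).astype(float) for k in present])
    fit = fit_logistic(labels, X)
    out: dict[int, dict] = {1: {"or": 1.0, "ci95": (np.nan, np.nan),
                                "p": np.nan, "n": int((q == 1).sum())}}
    for i, k in enumerate(present):
        out[k] = {
            "or": float(np.exp(fit.betas[i])),
            "ci95": fit.ci95(i),
            "p": float(fit.pvalues[i + 1]),
            "n": int((q == k).sum()),
        }
    return out


def grs_with_quartiles(
    gm: GenotypeMatrix, model: PredictionModel, labels: np.ndarray | None = None
) -> RiskScoreResult:
    """GRS plus quartile assignment and per-quartile odds ratios."""
    res = compute_grs(gm, model)
    by_id = {s.sample_id: s for s in gm.samples}
    if labels is None:
        y = np.array([by_id[sid].label for sid in res.sample_ids])
    else:
        full = dict(zip((s.sample_id for s in gm.samples), np.asarray(labels)))
        y = np.array([full[sid] for sid in res.sample_ids])
    res.quartile = assign_quartiles(res.grs)
    res.quartile_or = quartile_or(res.grs, y)
    return res


def risk_allele_histogram(
    gm: GenotypeMatrix,
    model: PredictionModel,
    categories: tuple[int, int] = (1, 2),
    carrier_threshold: int = 7,
) -> dict:
    """Risk-allele count distributions by phenotype category.

    Returns histograms of total risk-allele counts (0 .. 2*n_snps) for the
    two categories plus a chi-square comparison of the proportion of
    samples carrying more than ``carrier_threshold`` risk alleles.
    """
    res = compute_grs(gm, model)
    by_id = {s.sample_id: s for s in gm.samples}
    max_total = 2 * len(model.snps)
    hist = {c: np.zeros(max_total + 1, dtype=int) for c in categories}
    over = {c: 0 for c in categories}
    totals = {c: 0 for c in categories}
    for sid, count in zip(res.sample_ids, res.risk_allele_count):
        cat = by_id[sid].category
        if cat not in hist:
            continue
        k = int(round(count))
        hist[cat][k] += 1
        totals[cat] += 1
        if k > carrier_threshold:
            over[cat] += 1
    c1, c2 = categories
    stat, p = chi2_2x2(
        over[c1], totals[c1] - over[c1], over[c2], totals[c2] - over[c2]
    )
    return {
        "histogram": hist,
        "over_threshold": over,
        "n": totals,
        "chi2": stat,
        "chi2_p": p,
        "threshold": carrier_threshold,
    }


def top_quartile_mean_risk_alleles(res: RiskScoreResult) -> float:
    """Mean unweighted risk-allele count within the highest GRS quartile."""
    if res.quartile is None:
        res.quartile = assign_quartiles(res.grs)
    top = res.quartile == 4
    return float(res.risk_allele_count[top].mean())
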