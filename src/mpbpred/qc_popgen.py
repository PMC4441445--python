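"""Population-genetic QC: exact HWE testing, LD estimation, power.

The Hardy-Weinberg test is the exact conditional test: given the minor
allele count, every possible heterozygote count (same parity) is
enumerated and the two-sided p-value sums the probabilities of all
configurations no more likely than the observed one.  LD between
autosomal SNPs uses EM-estimated haplotype frequencies from unphased
genotypes; between X-linked SNPs in an all-male cohort the haplotypes
are directly observed, so r^2 is the squared allelic correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genodata import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class HWEResult:
    rsid: str
    n_hom_major: int
    n_het: int
    n_hom_minor: int
    exact_p: float


def hwe_exact(n_hom_major: int, n_het: int, n_hom_minor: int, rsid: str = "") -> HWEResult:
    """Exact two-sided Hardy-Weinberg test by heterozygote enumeration."""
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    # orient so "rare" is the minor allele
    n_rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    # log-probability of each possible het count conditional on allele counts
    hets = range(n_rare % 2, n_rare + 1, 2)
    logps = []
    for h in hets:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if common_hom < 0:
            logps.append(-np.inf)
            continue
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(common_hom + 1)
            - math.lgamma(h + 1)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs = list(hets).index(n_het)
    p = float(probs[probs <= probs[obs] * (1 + 1e-12)].sum())
    return HWEResult(rsid, n_hom_major, n_het, n_hom_minor, min(p, 1.0))


def hwe_scan(gm: GenotypeMatrix) -> list[HWEResult]:
    """Exact HWE test for every autosomal SNP in the matrix.

    X-linked SNPs are refused: hemizygous male genotypes carry no
    within-individual allele pairing, so HWE is untestable here.
    """
    results = []
    for j, snp in enumerate(gm.snps):
        if snp.x_linked:
            continue
        col = gm.dosage[:, j]
        col = col[col != MISSING]
        results.append(
            hwe_exact(
                int((col == 0).sum()), int((col == 1).sum()),
                int((col == 2).sum()), rsid=snp.rsid,
            )
        )
    return results


def hwe_exact_snp(gm: GenotypeMatrix, rsid: str) -> HWEResult:
    j = gm.snp_index(rsid)
    snp = gm.snps[j]
    if snp.x_linked:
        raise ValueError(
            f"{rsid} is X-linked: male hemizygous genotypes carry a single "
            "allele, so Hardy-Weinberg proportions are not testable"
        )
    col = gm.dosage[:, j]
    col = col[col != MISSING]
    return hwe_exact(
        int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()),
        rsid=rsid,
    )


@dataclass(frozen=True)
class LDResult:
    rsid_a: str
    rsid_b: str
    r2: float
    d_prime: float
    n_used: int
    note: str = ""


def _em_haplotype_freqs(g1: np.ndarray, g2: np.ndarray,
                        tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """EM estimate of two-locus haplotype frequencies from unphased dosages.

    Returns [f_MM, f_Mm, f_mM, f_mm] where the first index is locus 1 and
    capital M denotes the minor allele.  Deterministic initialisation at
    linkage equilibrium.
    """
    # genotype cell counts n[i, j], i = dosage at locus 1, j = at locus 2
    n = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            n[i, j] = np.sum((g1 == i) & (g2 == j))
    total = n.sum()
    p1 = (2 * n[2, :].sum() + n[1, :].sum()) / (2 * total)
    p2 = (2 * n[:, 2].sum() + n[:, 1].sum()) / (2 * total)
    f = np.array([p1 * p2, p1 * (1 - p2), (1 - p1) * p2, (1 - p1) * (1 - p2)])

    def loglik(f: np.ndarray) -> float:
        fMM, fMm, fmM, fmm = f
        # per-cell haplotype-pair probabilities
        probs = np.array([
            [fmm ** 2, 2 * fmm * fmM, fmM ** 2],
            [2 * fmm * fMm, 2 * fMm * fmM + 2 * fMM * fmm, 2 * fMM * fmM],
            [fMm ** 2, 2 * fMM * fMm, fMM ** 2],
        ])
        with np.errstate(divide="ignore"):
            lp = np.where(n > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
        return float((n * lp).sum())

    ll = loglik(f)
    for _ in range(max_iter):
        fMM, fMm, fmM, fmm = f
        cis = fMM * fmm
        trans = fMm * fmM
        frac_cis = cis / (cis + trans) if (cis + trans) > 0 else 0.5
        dh = n[1, 1]  # double heterozygotes: phase-ambiguous
        cMM = 2 * n[2, 2] + n[2, 1] + n[1, 2] + dh * frac_cis
        cMm = 2 * n[2, 0] + n[2, 1] + n[1, 0] + dh * (1 - frac_cis)
        cmM = 2 * n[0, 2] + n[0, 1] + n[1, 2] + dh * (1 - frac_cis)
        cmm = 2 * n[0, 0] + n[0, 1] + n[1, 0] + dh * frac_cis
        f = np.array([cMM, cMm, cmM, cmm]) / (2 * total)
        new_ll = loglik(f)
        if abs(new_ll - ll) < tol * max(1.0, abs(ll)):
            break
        ll = new_ll
    return f


def _r2_dprime_from_freqs(f: np.ndarray) -> tuple[float, float]:
    fMM = f[0]
    p1 = f[0] + f[1]
    p2 = f[0] + f[2]
    d = fMM - p1 * p2
    denom = p1 * (1 - p1) * p2 * (1 - p2)
    if denom <= 0:
        return float("nan"), float("nan")
    r2 = d * d / denom
    d_max = min(p1 * (1 - p2), (1 - p1) * p2) if d > 0 else min(p1 * p2, (1 - p1) * (1 - p2))
    d_prime = abs(d) / d_max if d_max > 0 else float("nan")
    return float(r2), float(d_prime)


def ld_r2(
    g1: np.ndarray, g2: np.ndarray, x_linked: bool,
    rsid_a: str = "A", rsid_b: str = "B",
) -> LDResult:
    """Pairwise LD between two SNPs over the same samples.

    For male X-linked pairs the single-allele genotypes ARE haplotypes,
    so r^2 is the squared Pearson correlation of the allele indicators.
    For autosomal pairs haplotype frequencies are estimated by EM.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok].astype(float), g2[ok].astype(float)
    n_used = int(ok.sum())
    if n_used == 0 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return LDResult(rsid_a, rsid_b, float("nan"), float("nan"), n_used,
                        note="monomorphic: r2 undefined")
    if x_linked:
        r = float(np.corrcoef(a, b)[0, 1])
        p1, p2 = a.mean(), b.mean()
        d = float(np.mean(a * b) - p1 * p2)
        d_max = min(p1 * (1 - p2), (1 - p1) * p2) if d > 0 else min(p1 * p2, (1 - p1) * (1 - p2))
        d_prime = abs(d) / d_max if d_max > 0 else float("nan")
        return LDResult(rsid_a, rsid_b, r * r, d_prime, n_used)
    f = _em_haplotype_freqs(a.astype(int), b.astype(int))
    r2, d_prime = _r2_dprime_from_freqs(f)
    return LDResult(rsid_a, rsid_b, r2, d_prime, n_used)


def ld_scan(gm: GenotypeMatrix, same_chrom_only: bool = True) -> list[LDResult]:
    """All pairwise LD results (by default within chromosomes only)."""
    results = []
    for j in range(gm.n_snps):
        for k in range(j + 1, gm.n_snps):
            a, b = gm.snps[j], gm.snps[k]
            if same_chrom_only and a.chrom != b.chrom:
                continue
            if a.x_linked != b.x_linked:
                continue
            results.append(
                ld_r2(gm.dosage[:, j], gm.dosage[:, k], a.x_linked,
                      a.rsid, b.rsid)
            )
    return results


def block_group(ld: list[LDResult], threshold: float = 0.8) -> list[set[str]]:
    """Group SNPs into blocks: connected components of the r2 > threshold graph.

    Singletons (SNPs appearing in ``ld`` but exceeding the threshold with
    no partner) come back as single-member sets.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for res in ld:
        for node in (res.rsid_a, res.rsid_b):
            parent.setdefault(node, node)
        if np.isfinite(res.r2) and res.r2 > threshold:
            ra, rb = find(res.rsid_a), find(res.rsid_b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return sorted(groups.values(), key=lambda g: (-len(g), sorted(g)[0]))


def _power_two_proportion(
    p0: float, p1: float, n1: int, n2: int, alpha: float
) -> float:
    """Power of the two-sided two-proportion z-test (allele counts)."""
    pbar = (n1 * p1 + n2 * p0) / (n1 + n2)
    z_a = stats.norm.ppf(1 - alpha / 2)
    se0 = math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n2)
    z = (abs(p1 - p0) - z_a * se0) / se1
    return float(stats.norm.cdf(z))


def min_detectable_or(
    n_case: int, n_control: int, maf: float,
    alpha: float = 0.05, power: float = 0.8,
) -> float:
    """Smallest OR >= 1 detectable for an allele-frequency comparison.

    Control minor-allele frequency is ``maf``; the case frequency implied
    by a candidate OR is p1 = OR*p0 / (1 + p0*(OR-1)); power is from the
    normal approximation with 2n alleles per group.  Monotone decreasing
    in both sample size and MAF.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if n_case < 1 or n_control < 1:
        raise ValueError("need at least one case and one control")
    n1, n2 = 2 * n_case, 2 * n_control

    def power_at(or_: float) -> float:
        p1 = or_ * maf / (1 + maf * (or_ - 1))
        return _power_two_proportion(maf, p1, n1, n2, alpha)

    from scipy.optimize import brentq

    lo, hi = 1.0 + 1e-9, 2.0
    while power_at(hi) < power:
        hi *= 2
        if hi > 1e6:
            raise RuntimeError("power target unreachable")
    return float(brentq(lambda o: power_at(o) - power, lo, hi, xtol=1e-9))
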