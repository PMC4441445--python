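"""Synthetic male cohorts with the genetic architecture of pattern baldness.

The default panel emulates a 50-SNP androgenetic-alopecia candidate set:
17 X-linked SNPs in the Xq12 (*AR*/*EDA2R*) region arranged in three
high-LD blocks, eight SNPs at 20p11 (five in one block), a tight 17q21
triplet, and singleton markers near *TARDBP* (chr1), *EBF1* (chr5),
*HDAC9* (chr7), *WNT10A* (chr2), *SSPN* (chr12) and *SETBP1* (chr18).
The five strongest predictors carry the published joint odds ratios
(0.480, 0.482, 0.557, 0.493 for the minor alleles of rs5919324,
rs1998076, rs929626 and rs12565727; 1.595 for rs756853), with smaller
effects at secondary loci.  Panel members without a literature anchor are
synthetic fillers: plausible rsIDs, MAFs and positions frozen here so
that runs are reproducible, not measured values.

Phenotypes follow a logistic liability model: baldness probability is
logit-linear in age — calibrated so that roughly 16% of men aged 18-29
and 43-50% of men approaching 50 show significant hair loss — plus the
per-SNP allelic effects.  Norwood-Hamilton grades are assigned from bald
status by a monotone quantile map of the linear predictor (a stand-in:
the true grade-by-age joint distribution is not modelled).

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genodata import GenotypeMatrix, SampleRecord, SNPInfo

LOG = math.log


def _snp(rsid, chrom, pos, major, minor, maf):
    return SNPInfo(rsid, chrom, pos, major, minor, maf)


#: 50-SNP candidate panel (GRCh37-style coordinates).  The literature-anchored
#: members keep their real rsIDs; the rest are synthetic fillers.
DEFAULT_PANEL: list[SNPInfo] = [
    # --- Xq12 block 1 (7 SNPs, target r2 0.85), includes the top predictor
    _snp("rs5919324", "X", 66563018, "T", "C", 0.17),
    _snp("rs1041668", "X", 66608824, "T", "C", 0.17),
    _snp("rs2497938", "X", 66641767, "C", "T", 0.17),
    _snp("rs12558842", "X", 66696344, "A", "G", 0.17),
    _snp("rs6152", "X", 66765627, "G", "A", 0.17),
    _snp("rs2207081", "X", 66831086, "G", "A", 0.17),
    _snp("rs1204038", "X", 66862007, "G", "A", 0.17),
    # --- Xq12 block 2 (5 SNPs, target r2 0.85)
    _snp("rs6625163", "X", 65988670, "A", "G", 0.30),
    _snp("rs6625150", "X", 66021877, "C", "G", 0.30),
    _snp("rs1385699", "X", 66056240, "C", "T", 0.30),
    _snp("rs2497911", "X", 66089912, "T", "C", 0.30),
    _snp("rs5964607", "X", 66123489, "C", "T", 0.30),
    # --- Xq12 block 3 (5 SNPs, target r2 0.85)
    _snp("rs962458", "X", 67290086, "G", "A", 0.25),
    _snp("rs12007229", "X", 67343176, "C", "A", 0.25),
    _snp("rs2223841", "X", 67391520, "C", "T", 0.25),
    _snp("rs5919393", "X", 67437212, "A", "G", 0.25),
    _snp("rs4827528", "X", 67481904, "C", "T", 0.25),
    # --- 20p11 block (5 SNPs, target r2 0.85) + three unlinked chr20
    _snp("rs1998076", "20", 21842674, "C", "T", 0.39),
    _snp("rs2180439", "20", 21870623, "T", "C", 0.39),
    _snp("rs913063", "20", 21901685, "A", "C", 0.39),
    _snp("rs1160312", "20", 21938706, "G", "A", 0.39),
    _snp("rs6113491", "20", 21986219, "A", "C", 0.39),
    _snp("rs6137444", "20", 22405631, "C", "T", 0.20),
    _snp("rs2327101", "20", 22674518, "T", "C", 0.35),
    _snp("rs6047844", "20", 22891370, "T", "C", 0.39),
    # --- 17q21 triplet (target r2 0.92)
    _snp("rs1800547", "17", 43924150, "A", "G", 0.20),
    _snp("rs12373124", "17", 43986423, "C", "T", 0.20),
    _snp("rs199533", "17", 44828931, "G", "A", 0.20),
    # --- chr7: HDAC9 intron, a linked pair, and the duplicated-region SNP
    _snp("rs756853", "7", 18671664, "T", "C", 0.39),
    _snp("rs2249817", "7", 34938916, "C", "T", 0.45),
    _snp("rs6461387", "7", 34981275, "G", "A", 0.45),
    _snp("rs6945541", "7", 65836294, "A", "C", 0.30),
    # --- chr1 TARDBP cluster (4 SNPs, target r2 0.70)
    _snp("rs12565727", "1", 11071691, "C", "T", 0.18),
    _snp("rs9659814", "1", 11083215, "G", "A", 0.18),
    _snp("rs1193009", "1", 11094412, "C", "G", 0.18),
    _snp("rs6679497", "1", 11105836, "T", "C", 0.18),
    # --- remaining singletons (model members first)
    _snp("rs929626", "5", 158120348, "T", "C", 0.47),
    _snp("rs7349332", "2", 219755011, "C", "T", 0.25),
    _snp("rs4679955", "3", 151532686, "T", "C", 0.35),
    _snp("rs9668810", "12", 26351708, "G", "A", 0.30),
    _snp("rs10502861", "18", 42546273, "C", "T", 0.25),
    # --- synthetic filler markers (no literature anchor)
    _snp("rs6867655", "5", 158289412, "A", "G", 0.30),
    _snp("rs9287638", "2", 219912475, "A", "C", 0.40),
    _snp("rs11803731", "1", 152083262, "A", "T", 0.45),
    _snp("rs17646946", "1", 151976041, "G", "A", 0.15),
    _snp("rs1268789", "6", 78962178, "G", "A", 0.30),
    _snp("rs2073963", "6", 31322581, "G", "T", 0.45),
    _snp("rs10756929", "9", 16842930, "C", "T", 0.25),
    _snp("rs4552364", "11", 68213764, "A", "G", 0.40),
    _snp("rs7127101", "11", 69328415, "C", "T", 0.20),
]

#: LD blocks: (ordered member rsIDs, target pairwise r2 between neighbours).
DEFAULT_LD_BLOCKS: list[tuple[tuple[str, ...], float]] = [
    (("rs5919324", "rs1041668", "rs2497938", "rs12558842",
      "rs6152", "rs2207081", "rs1204038"), 0.85),
    (("rs6625163", "rs6625150", "rs1385699", "rs2497911", "rs5964607"), 0.85),
    (("rs962458", "rs12007229", "rs2223841", "rs5919393", "rs4827528"), 0.85),
    (("rs1998076", "rs2180439", "rs913063", "rs1160312", "rs6113491"), 0.85),
    (("rs1800547", "rs12373124", "rs199533"), 0.92),
    (("rs2249817", "rs6461387"), 0.85),
    (("rs12565727", "rs9659814", "rs1193009", "rs6679497"), 0.70),
]

#: Case-control contrast amplification of the extreme-category design.
#: Association contrasts early-bald cases (low-prevalence age stratum)
#: with old non-bald controls (high-prevalence stratum); the log-odds
#: slope measured in that design is approximately
#: ``(1 - p_bald|<50) + p_bald|>=50`` times the within-age allelic
#: log-odds (about 0.70 + 0.66 under the default age model).  Target
#: effect sizes below are stated on the design scale — the scale on
#: which candidate-SNP odds ratios are reported — and deflated by this
#: factor to the within-age liability scale at generation time, so that
#: refitting the case-control contrast recovers the stated values.
DESIGN_AMPLIFICATION = 1.36

#: Design-scale odds ratio per coded additive unit of the minor allele
#: (male X coded 0/2, so hemizygotes carry twice the per-unit effect).
#: The five principal predictors use the published joint odds ratios.
DEFAULT_EFFECT_ORS: dict[str, float] = {
    "rs5919324": 0.480,
    "rs1998076": 0.482,
    "rs929626": 0.557,
    "rs12565727": 0.493,
    "rs756853": 1.595,
    # secondary loci: univariately detectable at best, rarely independent
    "rs10502861": 0.70,
    "rs6945541": 1.15,
    "rs7349332": 1.12,
    "rs4679955": 0.88,
    "rs9668810": 1.12,
    "rs6461387": 1.15,
    "rs2327101": 0.90,
    # weak independent signal in the secondary Xq12 blocks (per coded unit,
    # so a minor-allele hemizygote carries twice this log-odds)
    "rs6625163": 0.85,
    "rs962458": 0.85,
}

#: Within-age per-coded-unit log-odds actually injected into the liability.
DEFAULT_EFFECTS: dict[str, float] = {
    rsid: LOG(or_) / DESIGN_AMPLIFICATION
    for rsid, or_ in DEFAULT_EFFECT_ORS.items()
}

#: Age model: logit of baldness at the mean genotype is
#: ``age_intercept + age_slope * age``.  Calibrated against reported
#: prevalence of significant hair loss (~16% at 18-29, 43-50% before 50).
DEFAULT_AGE_INTERCEPT = -3.886
DEFAULT_AGE_SLOPE = 0.0828


class LDInfeasibleError(ValueError):
    """Requested r2 exceeds what the two MAFs allow."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic-cohort draw."""

    n_samples: int = 1000
    snp_panel: list[SNPInfo] = field(default_factory=lambda: list(DEFAULT_PANEL))
    ld_blocks: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: list(DEFAULT_LD_BLOCKS)
    )
    effect_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    age_intercept: float = DEFAULT_AGE_INTERCEPT
    age_slope: float = DEFAULT_AGE_SLOPE
    age_range: tuple[int, int] = (18, 79)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rsids = {s.rsid for s in self.snp_panel}
        for block, r2 in self.ld_blocks:
            if not 0.0 <= r2 <= 1.0:
                raise ValueError(f"target r2 {r2} outside [0, 1]")
            unknown = set(block) - rsids
            if unknown:
                raise ValueError(f"LD block names unknown SNPs: {unknown}")
        unknown = set(self.effect_table) - rsids
        if unknown:
            raise ValueError(f"effect table names unknown SNPs: {unknown}")
        for snp in self.snp_panel:
            if not 0.0 < snp.maf <= 0.5:
                raise ValueError(f"{snp.rsid}: simulation needs MAF in (0, 0.5]")


def max_feasible_r2(maf_a: float, maf_b: float) -> float:
    """Largest attainable r2 between two loci with the given MAFs (D > 0)."""
    pa, qa, pb, qb = maf_a, 1 - maf_a, maf_b, 1 - maf_b
    d_max = min(pa * qb, qa * pb)
    return d_max * d_max / (pa * qa * pb * qb)


def _conditional_probs(maf_a: float, maf_b: float, r2: float) -> tuple[float, float]:
    """P(B=minor | A=minor) and P(B=minor | A=major) achieving target r2."""
    feasible = max_feasible_r2(maf_a, maf_b)
    if r2 > feasible + 1e-12:
        raise LDInfeasibleError(
            f"target r2={r2:.3f} unattainable for MAFs "
            f"({maf_a:.3f}, {maf_b:.3f}); feasible maximum is {feasible:.3f}"
        )
    pa, qa, pb, qb = maf_a, 1 - maf_a, maf_b, 1 - maf_b
    d = math.sqrt(r2 * pa * qa * pb * qb)
    return pb + d / pa, pb - d / qa


def _draw_block_haplotypes(
    rng: np.random.Generator,
    mafs: list[float],
    r2: float,
    n: int,
) -> np.ndarray:
    """Draw n haplotypes over a block as a first-order Markov chain.

    Adjacent pairs hit the target r2; more distant pairs decay
    multiplicatively (r2 across a gap of g neighbours is r2**g).
    """
    out = np.empty((n, len(mafs)), dtype=np.int8)
    out[:, 0] = rng.random(n) < mafs[0]
    for k in range(1, len(mafs)):
        p_given_minor, p_given_major = _conditional_probs(mafs[k - 1], mafs[k], r2)
        prev = out[:, k - 1]
        p = np.where(prev == 1, p_given_minor, p_given_major)
        out[:, k] = rng.random(n) < p
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw genotype calls for the panel under HWE with block-wise LD.

    Autosomal dosages are sums of two independent haplotypes; male X
    dosages are a single haplotype (0/1).  Returns a GenotypeMatrix with
    placeholder phenotype records (use :func:`simulate_phenotypes` or
    :func:`simulate_cohort` to attach phenotypes).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    panel = config.snp_panel
    index = {s.rsid: j for j, s in enumerate(panel)}
    dosage = np.empty((n, len(panel)), dtype=np.int8)

    in_block = set()
    for block, r2 in config.ld_blocks:
        cols = [index[r] for r in block]
        mafs = [panel[j].maf for j in cols]
        x_linked = panel[cols[0]].x_linked
        if any(panel[j].x_linked != x_linked for j in cols):
            raise ValueError(f"LD block {block} mixes X-linked and autosomal SNPs")
        n_hap = 1 if x_linked else 2
        total = np.zeros((n, len(cols)), dtype=np.int8)
        for _ in range(n_hap):
            total += _draw_block_haplotypes(rng, mafs, r2, n)
        dosage[:, cols] = total
        in_block.update(cols)

    for j, snp in enumerate(panel):
        if j in in_block:
            continue
        if snp.x_linked:
            dosage[:, j] = rng.random(n) < snp.maf
        else:
            dosage[:, j] = (rng.random(n) < snp.maf).astype(np.int8) + (
                rng.random(n) < snp.maf
            )

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1

    samples = [
        SampleRecord(sample_id=f"S{i + 1:05d}", age=18, grade="I")
        for i in range(n)
    ]
    return GenotypeMatrix(samples, panel, dosage)


# proportions of Norwood-Hamilton grades III..VII among bald men,
# filled monotonically in the genetic-plus-age liability
_BALD_GRADE_PROPS = np.array([0.35, 0.30, 0.20, 0.10, 0.05])
_BALD_GRADES = ("III", "IV", "V", "VI", "VII")


def simulate_phenotypes(
    gm: GenotypeMatrix, config: SimulationConfig
) -> list[SampleRecord]:
    """Draw ages, bald status and Norwood-Hamilton grades for a cohort.

    The bald indicator is Bernoulli with logit = age term + centred genetic
    score.  Grades: non-bald men get I or II (II more likely with age);
    bald men get III-VII by a monotone quantile map of the liability.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = gm.n_samples
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)

    # additive code: autosomal dosage 0/1/2, male X dosage 0/1 coded 0/2;
    # either way the expected code is 2*MAF, used both to impute rare
    # missing calls at their mean and to centre the genetic contribution
    eta = config.age_intercept + config.age_slope * ages.astype(float)
    for rsid, beta in config.effect_table.items():
        snp = gm.snp(rsid)
        d = gm.column(rsid).astype(float)
        unit = 2.0 if snp.x_linked else 1.0
        expected = 2.0 * snp.maf
        codes = np.where(d < 0, expected, d * unit)
        eta += beta * (codes - expected)

    bald = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    grades = np.empty(n, dtype=object)
    p_grade2 = np.clip(0.25 + 0.006 * ages, 0.0, 0.95)
    nonbald_idx = np.flatnonzero(~bald)
    grades[nonbald_idx] = np.where(
        rng.random(len(nonbald_idx)) < p_grade2[nonbald_idx], "II", "I"
    )
    bald_idx = np.flatnonzero(bald)
    if len(bald_idx) > 0:
        liability = eta[bald_idx] + rng.logistic(size=len(bald_idx))
        order = np.argsort(np.argsort(liability))  # ranks 0..m-1
        quantile = (order + 0.5) / len(bald_idx)
        cuts = np.cumsum(_BALD_GRADE_PROPS)[:-1]
        grade_k = np.searchsorted(cuts, quantile)
        grades[bald_idx] = np.array(_BALD_GRADES, dtype=object)[grade_k]

    return [
        SampleRecord(
            sample_id=gm.samples[i].sample_id,
            age=int(ages[i]),
            grade=str(grades[i]),
        )
        for i in range(n)
    ]


def simulate_cohort(config: SimulationConfig) -> GenotypeMatrix:
    """Genotypes plus phenotypes in one call."""
    gm = simulate_genotypes(config)
    samples = simulate_phenotypes(gm, config)
    return GenotypeMatrix(samples, gm.snps, gm.dosage)


def sample_study(
    cohort: GenotypeMatrix,
    seed: int,
    discovery: tuple[int, int] = (176, 129),
    test: tuple[int, int, int, int] = (50, 50, 100, 100),
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Draw the two-stage study design from a simulated population.

    The discovery set contrasts the phenotypic extremes (``discovery`` =
    counts for categories 1 and 2); the disjoint test set spans all four
    categories (``test`` = counts for categories 1-4).  Raises if the
    cohort holds too few samples of any category.
    """
    rng = np.random.default_rng(seed)
    cats = cohort.categories()
    need = {1: discovery[0] + test[0], 2: discovery[1] + test[1],
            3: test[2], 4: test[3]}
    picks: dict[int, np.ndarray] = {}
    for c, k in need.items():
        pool = np.flatnonzero(cats == c)
        if len(pool) < k:
            raise ValueError(
                f"cohort has {len(pool)} category-{c} samples; need {k} "
                f"(simulate a larger cohort)"
            )
        picks[c] = rng.choice(pool, size=k, replace=False)
    disc_idx = np.concatenate([picks[1][: discovery[0]], picks[2][: discovery[1]]])
    test_idx = np.concatenate(
        [picks[1][discovery[0]:], picks[2][discovery[1]:], picks[3], picks[4]]
    )
    return cohort.subset_samples(np.sort(disc_idx)), cohort.subset_samples(
        np.sort(test_idx)
    )
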