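"""Epistasis analysis: MDR and entropy-based interaction information.

Multifactor dimensionality reduction (MDR) exhaustively scores k-SNP
genotype combinations: each multi-locus genotype cell is labelled
high-risk when its case:control ratio reaches the cohort-wide ratio, and
the resulting binary classifier is scored by balanced accuracy with
stratified cross-validation.

The interaction graph uses plug-in (maximum-likelihood) entropies.  A
node carries 100 * I(SNP; class) / H(class) — the percentage of outcome
uncertainty the SNP removes on its own; an edge carries the interaction
information 100 * [I(A,B; class) - I(A; class) - I(B; class)] / H(class),
negative for redundant pairs (shared information) and positive for
synergistic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .genodata import MISSING, GenotypeMatrix
from .association import SeparationError, ConvergenceError, AssociationResult, code, fit_logistic


@dataclass
class MDRModel:
    snp_set: tuple[str, ...]
    high_risk_cells: frozenset[tuple[int, ...]]
    balanced_accuracy_train: float
    balanced_accuracy_test: float | None = None
    cv_consistency: int | None = None


def _dosage_levels(gm: GenotypeMatrix, rsids: list[str]) -> tuple[np.ndarray, list[int]]:
    """Dosage columns and level counts (3 autosomal, 2 male X) per SNP."""
    cols, levels = [], []
    for rsid in rsids:
        j = gm.snp_index(rsid)
        cols.append(gm.dosage[:, j])
        levels.append(2 if gm.snps[j].x_linked else 3)
    return np.column_stack(cols), levels


def _cell_index(codes: np.ndarray, levels: list[int]) -> np.ndarray:
    idx = np.zeros(codes.shape[0], dtype=np.int64)
    for j, lv in enumerate(levels):
        idx = idx * lv + codes[:, j]
    return idx


def _mdr_fit(
    cell_idx: np.ndarray, y: np.ndarray, n_cells: int, threshold: float
) -> np.ndarray:
    """High-risk mask per cell: case:control ratio >= threshold.

    Empty cells default to low-risk; cells with cases but no controls are
    high-risk (infinite ratio).
    """
    cases = np.bincount(cell_idx[y == 1], minlength=n_cells).astype(float)
    controls = np.bincount(cell_idx[y == 0], minlength=n_cells).astype(float)
    high = np.zeros(n_cells, dtype=bool)
    nonempty = (cases + controls) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cases / controls
    high[nonempty] = np.where(
        controls[nonempty] > 0,
        ratio[nonempty] >= threshold - 1e-12,   # ties count as high-risk
        cases[nonempty] > 0,
    )
    return high


def _balanced_accuracy(pred: np.ndarray, y: np.ndarray) -> float:
    sens = pred[y == 1].mean() if (y == 1).any() else np.nan
    spec = (~pred[y == 0]).mean() if (y == 0).any() else np.nan
    return float((sens + spec) / 2)


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, sample in enumerate(idx):
            folds[i % n_folds].append(sample)
    return [np.array(sorted(f)) for f in folds]


def mdr_search(
    gm: GenotypeMatrix,
    labels: np.ndarray | None = None,
    k_range: tuple[int, ...] = (1, 2, 3),
    cv_folds: int = 10,
    seed: int = 0,
    candidates: list[str] | None = None,
) -> dict[int, MDRModel]:
    """Exhaustive MDR over k-SNP combinations for each k in ``k_range``.

    Samples missing any candidate SNP are dropped (complete-case).  The
    best model per k maximises training balanced accuracy; its testing
    balanced accuracy is the average over stratified CV folds of models
    refitted on the fold-training data, and CV consistency counts folds
    whose own best combination matches the overall winner.
    """
    y_all = gm.labels() if labels is None else np.asarray(labels)
    rsids = candidates if candidates is not None else gm.rsids
    if max(k_range) > len(rsids):
        raise ValueError(
            f"k={max(k_range)} exceeds the {len(rsids)} available SNPs"
        )
    codes_all, levels_all = _dosage_levels(gm, rsids)
    complete = ~(codes_all == MISSING).any(axis=1)
    codes_all = codes_all[complete]
    y = y_all[complete]
    n_cases, n_controls = int((y == 1).sum()), int((y == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("MDR needs both cases and controls")
    threshold = n_cases / n_controls
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, cv_folds, rng)

    def best_for_k(k: int, rows: np.ndarray) -> tuple[tuple[int, ...], float]:
        best_ba, best_combo = -np.inf, None
        yy = y[rows]
        thr = (yy == 1).sum() / max((yy == 0).sum(), 1)
        for combo in combinations(range(len(rsids)), k):
            sub = codes_all[np.ix_(rows, combo)]
            lv = [levels_all[j] for j in combo]
            n_cells = int(np.prod(lv))
            idx = _cell_index(sub, lv)
            high = _mdr_fit(idx, yy, n_cells, thr)
            ba = _balanced_accuracy(high[idx], yy)
            if ba > best_ba:
                best_ba, best_combo = ba, combo
        return best_combo, best_ba

    all_rows = np.arange(len(y))
    results: dict[int, MDRModel] = {}
    for k in k_range:
        combo, train_ba = best_for_k(k, all_rows)
        lv = [levels_all[j] for j in combo]
        n_cells = int(np.prod(lv))
        idx_full = _cell_index(codes_all[:, combo], lv)
        high_full = _mdr_fit(idx_full, y, n_cells, threshold)
        cells = frozenset(
            tuple(np.unravel_index(c, lv)) for c in np.flatnonzero(high_full)
        )
        test_bas, consistent = [], 0
        for fold in folds:
            train_rows = np.setdiff1d(all_rows, fold)
            fold_combo, _ = best_for_k(k, train_rows)
            if fold_combo == combo:
                consistent += 1
            # refit the winning combination on the training rows, score on fold
            sub_train = codes_all[np.ix_(train_rows, combo)]
            yy = y[train_rows]
            thr = (yy == 1).sum() / max((yy == 0).sum(), 1)
            high = _mdr_fit(_cell_index(sub_train, lv), yy, n_cells, thr)
            test_idx = _cell_index(codes_all[np.ix_(fold, combo)], lv)
            test_bas.append(_balanced_accuracy(high[test_idx], y[fold]))
        results[k] = MDRModel(
            snp_set=tuple(rsids[j] for j in combo),
            high_risk_cells=cells,
            balanced_accuracy_train=train_ba,
            balanced_accuracy_test=float(np.mean(test_bas)),
            cv_consistency=consistent,
        )
    return results


def mdr_balanced_accuracy(
    gm: GenotypeMatrix, labels: np.ndarray, snp_set: tuple[str, ...]
) -> float:
    """Training balanced accuracy of the MDR model on a given SNP set."""
    y = np.asarray(labels)
    codes, levels = _dosage_levels(gm, list(snp_set))
    complete = ~(codes == MISSING).any(axis=1)
    codes, y = codes[complete], y[complete]
    thr = (y == 1).sum() / (y == 0).sum()
    idx = _cell_index(codes, levels)
    high = _mdr_fit(idx, y, int(np.prod(levels)), thr)
    return _balanced_accuracy(high[idx], y)


# ---------------------------------------------------------------------------
# Interaction information


@dataclass
class InteractionGraph:
    node_entropy: dict[str, float] = field(default_factory=dict)   # percent
    edge_entropy: dict[tuple[str, str], float] = field(default_factory=dict)


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in I(X; Y) in bits from two discrete label arrays."""
    xs, xi = np.unique(x, return_inverse=True)
    ys, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xs), len(ys)))
    np.add.at(joint, (xi, yi), 1)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    return hx + hy - hxy


def interaction_entropy(
    gm: GenotypeMatrix,
    labels: np.ndarray | None = None,
    snps: list[str] | None = None,
) -> InteractionGraph:
    """Entropy-based interaction graph over the given SNPs.

    Node: percentage of class entropy removed by the SNP alone.  Edge:
    interaction information of the pair as a percentage of class entropy
    (negative = redundancy).  Missing calls are excluded per node /
    pairwise per edge.
    """
    y_all = gm.labels() if labels is None else np.asarray(labels)
    rsids = snps if snps is not None else gm.rsids
    if len(rsids) < 2:
        raise ValueError("interaction graph needs at least 2 SNPs")
    graph = InteractionGraph()
    cols = {r: gm.column(r) for r in rsids}
    for rsid in rsids:
        g = cols[rsid]
        ok = g != MISSING
        y = y_all[ok]
        h_class = _entropy(np.bincount(y))
        graph.node_entropy[rsid] = 100.0 * _mutual_information(g[ok], y) / h_class
    for a, b in combinations(rsids, 2):
        ga, gb = cols[a], cols[b]
        ok = (ga != MISSING) & (gb != MISSING)
        y = y_all[ok]
        h_class = _entropy(np.bincount(y))
        joint = ga[ok].astype(int) * 4 + gb[ok].astype(int)
        i_ab = _mutual_information(joint, y)
        i_a = _mutual_information(ga[ok], y)
        i_b = _mutual_information(gb[ok], y)
        graph.edge_entropy[(a, b)] = 100.0 * (i_ab - i_a - i_b) / h_class
    return graph


def interaction_logistic(
    gm: GenotypeMatrix,
    labels: np.ndarray | None = None,
    pair: tuple[str, str] = (),
) -> AssociationResult:
    """Multiplicative-scale pairwise interaction test.

    Logistic regression with both additive main effects and their product;
    the returned result describes the product term.
    """
    a, b = pair
    y_all = gm.labels() if labels is None else np.asarray(labels)
    ja, jb = gm.snp_index(a), gm.snp_index(b)
    ca = code(gm.dosage[:, ja], gm.snps[ja], "additive")
    cb = code(gm.dosage[:, jb], gm.snps[jb], "additive")
    ok = (ca != MISSING) & (cb != MISSING)
    xa, xb, y = ca[ok].astype(float), cb[ok].astype(float), y_all[ok]
    X = np.column_stack([xa, xb, xa * xb])
    try:
        fit = fit_logistic(y, X)
    except (SeparationError, ConvergenceError) as exc:
        return AssociationResult(
            f"{a}x{b}", "interaction", np.nan, np.nan, (np.nan, np.nan),
            np.nan, int(ok.sum()), note=f"fit failed: {exc}",
        )
    beta = float(fit.betas[2])
    return AssociationResult(
        rsid=f"{a}x{b}",
        mode="interaction",
        beta=beta,
        or_=float(np.exp(beta)),
        ci95=fit.ci95(2),
        p=float(fit.pvalues[3]),
        n_used=int(ok.sum()),
    )
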