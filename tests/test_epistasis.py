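import numpy as np
import pytest

from mpbpred.genodata import GenotypeMatrix, SampleRecord, SNPInfo
from mpbpred.epistasis import (
    interaction_entropy,
    interaction_logistic,
    mdr_balanced_accuracy,
    mdr_search,
)
from mpbpred.association import fit_logistic


def _gm(columns, x_linked=None):
    """Build a matrix from dosage columns (dict rsid -> array)."""
    x_linked = x_linked or set()
    snps, cols = [], []
    for i, (rsid, col) in enumerate(columns.items()):
        chrom = "X" if rsid in x_linked else "1"
        snps.append(SNPInfo(rsid, chrom, i + 1, "C", "T", 0.3))
        cols.append(np.asarray(col, dtype=np.int8))
    n = len(cols[0])
    samples = [SampleRecord(f"S{i}", 45, "IV") for i in range(n)]
    return GenotypeMatrix(samples, snps, np.column_stack(cols))


class TestMDR:
    def test_single_causal_snp_selected_k1(self):
        rng = np.random.default_rng(83)
        n = 600
        causal = rng.integers(0, 3, n)
        noise = {f"rs_n{i}": rng.integers(0, 3, n) for i in range(5)}
        gm = _gm({"rs_causal": causal, **noise})
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.8 + 1.0 * causal)))).astype(int)
        models = mdr_search(gm, y, k_range=(1,), cv_folds=5, seed=1)
        assert models[1].snp_set == ("rs_causal",)

    def test_xor_pair_beats_marginals(self):
        """A pure XOR penetrance (risk iff exactly one locus carries a
        minor allele) has no marginal effects; the 2-SNP MDR model finds
        the pair and clearly beats every 1-SNP model."""
        rng = np.random.default_rng(89)
        n = 1200
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        noise = {f"rs_n{i}": rng.integers(0, 3, n) for i in range(3)}
        gm = _gm({"rs_a": a, "rs_b": b, **noise}, x_linked={"rs_a", "rs_b"})
        y = (rng.random(n) < np.where((a + b) % 2 == 1, 0.8, 0.2)).astype(int)
        models = mdr_search(gm, y, k_range=(1, 2), cv_folds=5, seed=2)
        assert set(models[2].snp_set) == {"rs_a", "rs_b"}
        assert models[2].balanced_accuracy_train > models[1].balanced_accuracy_train + 0.15

    def test_balanced_accuracy_matches_recount_oracle(self, discovery,
                                                      discovery_labels):
        """MDR balanced accuracy equals a naive per-cell recount."""
        snp_set = ("rs5919324", "rs1998076")
        ba = mdr_balanced_accuracy(discovery, discovery_labels, snp_set)
        # oracle: dictionary of cells -> counts, then confusion recount
        cols = [discovery.column(r) for r in snp_set]
        ok = (cols[0] >= 0) & (cols[1] >= 0)
        g = list(zip(cols[0][ok].tolist(), cols[1][ok].tolist()))
        y = discovery_labels[ok] if len(discovery_labels) == len(ok) else None
        y = np.asarray(discovery_labels)[ok]
        ratio = y.sum() / (len(y) - y.sum())
        cells = {}
        for gi, yi in zip(g, y):
            cells.setdefault(gi, [0, 0])[yi] += 1
        tp = fp = tn = fn = 0
        for gi, yi in zip(g, y):
            ctrl, case = cells[gi][0], cells[gi][1]
            high = (case / ctrl >= ratio - 1e-12) if ctrl else case > 0
            if high and yi:
                tp += 1
            elif high:
                fp += 1
            elif yi:
                fn += 1
            else:
                tn += 1
        oracle = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
        assert ba == pytest.approx(oracle, abs=1e-12)

    def test_empty_cells_low_risk(self):
        gm = _gm({"rs_a": [0, 0, 1, 1], "rs_b": [0, 0, 1, 1]})
        y = np.array([1, 0, 1, 0])
        models = mdr_search(gm, y, k_range=(2,), cv_folds=2, seed=3)
        # cells (0,1),(1,0),(2,*) never observed -> not in high-risk set
        for cell in models[2].high_risk_cells:
            assert cell in {(0, 0), (1, 1)}

    def test_k_too_large_rejected(self, tiny_gm):
        with pytest.raises(ValueError):
            mdr_search(tiny_gm, tiny_gm.labels(), k_range=(5,))


class TestInteractionEntropy:
    def test_independent_snp_node_near_zero(self):
        rng = np.random.default_rng(97)
        n = 20000
        gm = _gm({"rs_a": rng.integers(0, 3, n), "rs_b": rng.integers(0, 3, n)})
        y = rng.integers(0, 2, n)
        graph = interaction_entropy(gm, y)
        assert graph.node_entropy["rs_a"] < 0.1

    def test_duplicated_snp_fully_redundant(self):
        """For a duplicated SNP, I(A,A;C) = I(A;C), so the edge equals
        minus the node percentage exactly."""
        rng = np.random.default_rng(101)
        n = 2000
        a = rng.integers(0, 3, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(a - 1.0)))).astype(int)
        gm = _gm({"rs_a": a, "rs_dup": a.copy()})
        graph = interaction_entropy(gm, y)
        node = graph.node_entropy["rs_a"]
        edge = graph.edge_entropy[("rs_a", "rs_dup")]
        assert edge == pytest.approx(-node, abs=1e-9)

    def test_decomposition_identity(self, discovery, discovery_labels):
        """Edge + both nodes reconstruct the joint information
        I(A,B;C)/H(C) to machine precision (plug-in entropies)."""
        snps = ["rs929626", "rs1998076", "rs10502861"]
        graph = interaction_entropy(discovery, discovery_labels, snps)
        # independent joint-information computation via explicit tables
        from collections import Counter

        def entropy(counter):
            tot = sum(counter.values())
            return -sum((c / tot) * np.log2(c / tot) for c in counter.values())

        for a, b in [("rs929626", "rs1998076")]:
            ga, gb = discovery.column(a), discovery.column(b)
            ok = (ga >= 0) & (gb >= 0)
            y = np.asarray(discovery_labels)[ok]
            pairs = list(zip(ga[ok].tolist(), gb[ok].tolist()))
            h_c = entropy(Counter(y.tolist()))
            h_ab = entropy(Counter(pairs))
            h_abc = entropy(Counter(zip(pairs, y.tolist())))
            i_ab_c = h_ab + h_c - h_abc
            lhs = graph.edge_entropy[(a, b)] + graph.node_entropy[a] + graph.node_entropy[b]
            assert lhs == pytest.approx(100 * i_ab_c / h_c, abs=1e-9)

    def test_permuted_labels_destroy_signal(self, discovery, discovery_labels):
        rng = np.random.default_rng(103)
        snps = ["rs5919324", "rs1998076"]
        vals = []
        for _ in range(20):
            y = rng.permutation(discovery_labels)
            graph = interaction_entropy(discovery, y, snps)
            vals.extend(graph.node_entropy.values())
        assert np.mean(vals) < 0.5  # percent of class entropy

    def test_informative_snp_positive_node(self, discovery, discovery_labels):
        graph = interaction_entropy(
            discovery, discovery_labels, ["rs5919324", "rs1998076"]
        )
        assert graph.node_entropy["rs5919324"] > 1.0  # percent scale


class TestInteractionLogistic:
    def test_null_interaction_p_not_small(self):
        """Purely additive simulated effects: the product term is null."""
        rng = np.random.default_rng(107)
        n = 3000
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        eta = -0.5 + 0.4 * a + 0.4 * b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = _gm({"rs_a": a, "rs_b": b})
        res = interaction_logistic(gm, y, ("rs_a", "rs_b"))
        assert res.p > 0.01
        assert res.or_ == pytest.approx(1.0, abs=0.25)

    def test_matches_precomputed_product_column(self, discovery,
                                                discovery_labels):
        res = interaction_logistic(
            discovery, discovery_labels, ("rs929626", "rs1998076")
        )
        from mpbpred.association import code

        ja = discovery.snp_index("rs929626")
        jb = discovery.snp_index("rs1998076")
        ca = code(discovery.dosage[:, ja], discovery.snps[ja], "additive")
        cb = code(discovery.dosage[:, jb], discovery.snps[jb], "additive")
        ok = (ca >= 0) & (cb >= 0)
        X = np.column_stack(
            [ca[ok], cb[ok], ca[ok].astype(float) * cb[ok]]
        ).astype(float)
        fit = fit_logistic(np.asarray(discovery_labels)[ok], X)
        assert res.beta == pytest.approx(float(fit.betas[2]), abs=1e-9)
        assert res.p == pytest.approx(float(fit.pvalues[3]), abs=1e-9)

    def test_true_antagonistic_interaction_detected(self):
        """A built-in negative product effect is recovered with OR < 1."""
        rng = np.random.default_rng(109)
        n = 4000
        a = rng.integers(0, 3, n)
        b = rng.integers(0, 3, n)
        eta = -0.3 + 0.6 * a + 0.6 * b - 0.55 * a * b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        gm = _gm({"rs_a": a, "rs_b": b})
        res = interaction_logistic(gm, y, ("rs_a", "rs_b"))
        assert res.or_ < 0.75 and res.p < 1e-4
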