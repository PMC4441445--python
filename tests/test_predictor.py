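import numpy as np
import pytest

from mpbpred.association import fit_logistic
from mpbpred.genodata import GenotypeMatrix, SampleRecord, SNPInfo
from mpbpred.predictor import (
    BALD,
    INCONCLUSIVE,
    NON_BALD,
    PredictionModel,
    PredictionOutcome,
    age_stratified_report,
    auc,
    evaluate,
    forward_auc_select,
    nagelkerke,
    predict,
    rank_candidates,
)


def auc_pair_oracle(scores, labels):
    """O(n^2) Mann-Whitney pair enumeration with ties counted one half."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_half(self):
        assert auc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(61)
        scores = np.round(rng.random(50), 2)  # force some ties
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        assert auc(scores, labels) == pytest.approx(
            auc_pair_oracle(scores, labels), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(67)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        a = auc(scores, labels)
        assert auc(np.exp(3 * scores), labels) == pytest.approx(a, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.2, 0.4], [1, 1])


class TestNagelkerke:
    def test_null_model_zero(self):
        rng = np.random.default_rng(71)
        x = rng.normal(size=500)
        y = rng.integers(0, 2, 500)
        fit = fit_logistic(y, x)
        assert 0.0 <= nagelkerke(fit) < 0.03

    def test_strong_model_approaches_one(self):
        rng = np.random.default_rng(73)
        x = rng.normal(size=2000)
        y = (rng.random(2000) < 1 / (1 + np.exp(-6 * x))).astype(int)
        fit = fit_logistic(y, x)
        assert nagelkerke(fit) > 0.7

    def test_bounded(self, discovery, discovery_labels):
        from mpbpred.association import coded_matrix

        X, comp = coded_matrix(discovery, ["rs5919324", "rs929626"])
        fit = fit_logistic(discovery_labels[comp], X[comp].astype(float))
        assert 0.0 < nagelkerke(fit) < 1.0


class TestForwardAUCSelect:
    def test_null_snps_mostly_rejected(self):
        """One informative SNP among nine nulls: forward AUC selection keeps
        the signal and rejects most noise at delta 0.001."""
        from mpbpred.simulate import SimulationConfig, simulate_genotypes

        panel = [SNPInfo(f"rs_n{i}", "1", i + 1, "A", "G", 0.3) for i in range(9)]
        panel.append(SNPInfo("rs_causal", "2", 99, "A", "G", 0.3))
        kept_null = kept_causal = 0
        for seed in range(5):
            cfg = SimulationConfig(n_samples=500, snp_panel=panel, ld_blocks=[],
                                   effect_table={}, seed=seed + 200)
            gm = simulate_genotypes(cfg)
            rng = np.random.default_rng(seed + 300)
            eta = -0.3 + 0.9 * gm.column("rs_causal").astype(float)
            y = (rng.random(500) < 1 / (1 + np.exp(-eta))).astype(int)
            model = forward_auc_select(gm, y, delta=0.001)
            kept_causal += "rs_causal" in model.snps
            kept_null += len([s for s in model.snps if s != "rs_causal"])
        assert kept_causal >= 4
        assert kept_null / (5 * 9) < 0.5

    def test_candidates_ranked_by_univariate_p(self, discovery, discovery_labels):
        order = rank_candidates(discovery, discovery_labels)
        assert len(order) == 50
        from mpbpred.association import univariate_scan

        results = {r.rsid: r.p for r in
                   univariate_scan(discovery, discovery_labels, ("additive",))}
        ps = [results[r] for r in order if np.isfinite(results[r])]
        assert ps == sorted(ps)

    def test_zero_delta_admits_more(self, discovery, discovery_labels):
        tight = forward_auc_select(discovery, discovery_labels, delta=0.001)
        loose = forward_auc_select(discovery, discovery_labels, delta=0.0)
        assert len(loose.snps) >= len(tight.snps)


class TestPredict:
    MODEL = PredictionModel(
        snps=("rs_a",), codings=("additive",), intercept=0.0, betas=(1.0,)
    )

    def _gm(self, dosages):
        snps = [SNPInfo("rs_a", "1", 1, "C", "T", 0.3)]
        samples = [SampleRecord(f"S{i}", 45, "IV") for i in range(len(dosages))]
        return GenotypeMatrix(
            samples, snps, np.array(dosages, dtype=np.int8)[:, None]
        )

    @pytest.mark.parametrize(
        "p,call",
        [(0.70, BALD), (0.50, INCONCLUSIVE), (0.30, NON_BALD), (0.65, BALD),
         (0.35, NON_BALD)],
    )
    def test_threshold_zone(self, p, call):
        """At t=0.65: bald iff p >= 0.65, non-bald iff p <= 0.35, else
        inconclusive; the boundary itself is a conclusive call."""
        model = PredictionModel(
            snps=("rs_a",), codings=("additive",),
            intercept=float(np.log(p / (1 - p))), betas=(0.0001,),
        )
        gm = self._gm([0])
        outcomes, _ = predict(model, gm, threshold=0.65)
        assert outcomes[0].call == call

    def test_half_threshold_has_no_inconclusive(self, discovery):
        model = PredictionModel(
            snps=("rs5919324",), codings=("additive",),
            intercept=0.1, betas=(-0.5,),
        )
        outcomes, _ = predict(model, discovery, threshold=0.5)
        assert all(o.call != INCONCLUSIVE for o in outcomes)

    def test_missing_snp_excluded(self):
        gm = self._gm([1, -1])
        outcomes, excluded = predict(self.MODEL, gm, 0.5)
        assert [o.sample_id for o in outcomes] == ["S0"] and excluded == ["S1"]

    def test_invalid_threshold(self, tiny_gm):
        with pytest.raises(ValueError):
            predict(self.MODEL, tiny_gm, threshold=0.4)


class TestEvaluate:
    def _outcomes(self, spec):
        """spec: list of (label, call, p)."""
        samples, outcomes = [], []
        for i, (label, call, p) in enumerate(spec):
            samples.append(
                SampleRecord(f"S{i}", 45 if label else 60,
                             "IV" if label else "I")
            )
            outcomes.append(PredictionOutcome(f"S{i}", p, call, 0.65))
        return outcomes, samples

    def test_all_correct_conclusive(self):
        outcomes, samples = self._outcomes(
            [(1, BALD, 0.9), (1, BALD, 0.8), (0, NON_BALD, 0.1),
             (0, NON_BALD, 0.2)]
        )
        rep = evaluate(outcomes, samples)
        assert rep.sensitivity == (2, 2) and rep.specificity == (2, 2)
        assert rep.auc == 1.0 and rep.inconclusive == (0, 4)

    def test_counts_match_loop_oracle(self, discovery, discovery_labels):
        from mpbpred.association import multivariate_select

        model = multivariate_select(discovery, discovery_labels, max_snps=5)
        outcomes, excluded = predict(model, discovery, 0.65)
        rep = evaluate(outcomes, discovery.samples, len(excluded))
        # independent per-sample recount
        by_id = {s.sample_id: s for s in discovery.samples}
        tp = fp = tn = fn = inc = 0
        for o in outcomes:
            s = by_id[o.sample_id]
            if o.call == INCONCLUSIVE:
                inc += 1
            elif o.call == BALD:
                tp += s.label
                fp += 1 - s.label
            else:
                tn += 1 - s.label
                fn += s.label
        assert rep.sensitivity == (tp, tp + fn)
        assert rep.specificity == (tn, tn + fp)
        assert rep.ppv == (tp, tp + fp) and rep.npv == (tn, tn + fn)
        assert rep.inconclusive == (inc, len(outcomes))
        # reconciliation: conclusive + inconclusive + excluded = attempted
        assert tp + fp + tn + fn + inc + len(excluded) == discovery.n_samples

    def test_inconclusive_not_in_confusion_denominators(self):
        outcomes, samples = self._outcomes(
            [(1, BALD, 0.9), (1, INCONCLUSIVE, 0.55), (0, NON_BALD, 0.2),
             (0, INCONCLUSIVE, 0.45)]
        )
        rep = evaluate(outcomes, samples)
        assert rep.sensitivity == (1, 1) and rep.specificity == (1, 1)
        assert rep.inconclusive == (2, 4)

    def test_raising_threshold_improves_conclusive_accuracy(self):
        """On calibrated scores, restricting to confident calls does not
        reduce the correct-call rate."""
        rng = np.random.default_rng(79)
        deltas = []
        for _ in range(10):
            p = rng.beta(2, 2, 2000)
            y = (rng.random(2000) < p).astype(int)
            rates = []
            for t in (0.5, 0.65):
                calls = np.where(p >= t, 1, np.where(p <= 1 - t, 0, -1))
                ok = calls >= 0
                rates.append((calls[ok] == y[ok]).mean())
            deltas.append(rates[1] - rates[0])
        assert np.mean(deltas) > 0


class TestAgeStratified:
    def test_groups_partition_test_set(self, study):
        _, test = study
        model = PredictionModel(
            snps=("rs5919324",), codings=("additive",),
            intercept=0.2, betas=(-0.4,),
        )
        outcomes, _ = predict(model, test, 0.65)
        reports = age_stratified_report(outcomes, test.samples)
        n_young = sum(1 for s in test.samples if s.age < 50)
        n_old = sum(1 for s in test.samples if s.age >= 50)
        young_total = sum(reports["under50"].inconclusive[1:])
        old_total = sum(reports["50plus"].inconclusive[1:])
        assert young_total + old_total == len(outcomes)
        assert young_total <= n_young and old_total <= n_old
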