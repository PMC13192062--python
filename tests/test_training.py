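import numpy as np
import pandas as pd
import pytest

from boolimpl import network as net
from boolimpl import synthetic as syn
from boolimpl import training as tr


def brute_force_auc(values, y):
    """Exhaustive pairwise-comparison AUC estimator."""
    pos = [v for v, t in zip(values, y) if t]
    neg = [v for v, t in zip(values, y) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestGeneAuc:
    def test_perfect_separation(self):
        assert tr.gene_auc([1, 2, 5, 6], np.array([False, False, True, True])) == 1.0

    def test_all_tied_values(self):
        assert tr.gene_auc([3, 3, 3, 3], np.array([True, False, True, False])) == 0.5

    def test_pairwise_example(self):
        values = [3, 5, 1, 2, 4]
        y = np.array([True, True, False, False, False])
        assert tr.gene_auc(values, y) == pytest.approx(5 / 6)

    def test_one_class_empty(self):
        with pytest.raises(ValueError, match="both classes"):
            tr.gene_auc([1, 2], np.array([True, True]))

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(50):
            values = rng.integers(0, 6, size=30).astype(float)
            y = rng.random(30) < 0.4
            if y.all() or not y.any():
                continue
            assert tr.gene_auc(values, y) == pytest.approx(
                brute_force_auc(values, y), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        values = rng.normal(size=200)
        y = rng.random(200) < 0.5
        assert tr.gene_auc(values, y) == pytest.approx(
            roc_auc_score(y, values), abs=1e-12
        )

    def test_negation_antisymmetry(self, rng):
        values = rng.normal(size=80)
        y = rng.random(80) < 0.5
        assert tr.gene_auc(-values, y) == pytest.approx(
            1 - tr.gene_auc(values, y), abs=1e-12
        )


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = tr.welch_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_textbook_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        t, df, p = tr.welch_t(x, y)
        vx, vy = x.var(ddof=1) / 3, y.var(ddof=1) / 6
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (vx**2 / 2 + vy**2 / 5)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-9)
        from scipy.stats import t as tdist

        assert p == pytest.approx(2 * tdist.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(1, 1, size=14)
        t1, df1, p1 = tr.welch_t(x, y)
        t2, df2, p2 = tr.welch_t(y, x)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)
        assert df2 == pytest.approx(df1)

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="at least 2"):
            tr.welch_t([1.0], [1.0, 2.0])


class TestBhFdr:
    def test_step_up_hand_example(self):
        q = tr.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert tr.bh_fdr([0.37]) == pytest.approx([0.37])

    def test_all_ones(self):
        assert tr.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tr.bh_fdr([0.1, 1.5])

    def test_permutation_invariant_and_monotone(self, rng):
        p = rng.random(40)
        q = tr.bh_fdr(p)
        perm = rng.permutation(40)
        assert tr.bh_fdr(p[perm]) == pytest.approx(q[perm])
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_step_up_oracle(self, rng):
        """Direct step-up definition: q_(i) = min over j>=i of p_(j)*m/j."""
        p = rng.random(25)
        m = len(p)
        order = np.argsort(p)
        sorted_p = p[order]
        q_sorted = np.minimum.accumulate(
            (sorted_p * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert tr.bh_fdr(p) == pytest.approx(oracle, abs=1e-12)


class TestClusterSelectionAndTraining:
    def test_planted_cluster_ranked_first(self, trio):
        _, datasets, truths = trio
        truth = truths[0]
        primary, _ = datasets[0]
        bin_ = net.BooleanImplicationNetwork().fit(primary.T)
        selected = tr.select_clusters(bin_.clusters_, datasets, positive=1)
        top_members = set(selected[0].members) | set(selected[1].members)
        signature = set(truth.signature_up) | set(truth.signature_down)
        assert top_members <= signature

    def test_n_clusters_clamped(self, trio):
        _, datasets, _ = trio
        primary, _ = datasets[0]
        bin_ = net.BooleanImplicationNetwork().fit(primary.T)
        selected = tr.select_clusters(
            bin_.clusters_, datasets, positive=1, n_clusters=10_000
        )
        assert len(selected) == len(bin_.clusters_)

    def test_impossible_auc_filter_errors(self, trio):
        _, datasets, _ = trio
        primary, _ = datasets[0]
        bin_ = net.BooleanImplicationNetwork().fit(primary.T)
        selected = tr.select_clusters(bin_.clusters_, datasets, positive=1)
        with pytest.raises(ValueError, match="survive"):
            tr.train_signature(selected, datasets, positive=1, auc_up=1.01)

    def test_cap_is_a_maximum_not_padding(self, trio):
        """With fewer survivors than the cap, the list is shorter, unpadded."""
        _, datasets, truths = trio
        truth = truths[0]
        clusters = [
            net.Cluster("up", members=truth.signature_up[:12],
                        representatives=truth.signature_up[:3]),
            net.Cluster("dn", members=truth.signature_down,
                        representatives=truth.signature_down[:3]),
        ]
        model = tr.train_signature(clusters, datasets, positive=1)
        assert len(model.up_genes) == 12
        assert len(model.down_genes) == 20

    def test_trained_model_planted_and_capped(self, trio):
        _, datasets, truths = trio
        truth = truths[0]
        primary, _ = datasets[0]
        bin_ = net.BooleanImplicationNetwork().fit(primary.T)
        selected = tr.select_clusters(bin_.clusters_, datasets, positive=1)
        model = tr.train_signature(selected, datasets, positive=1)
        assert len(model.up_genes) == 20
        assert len(model.down_genes) == 20
        assert set(model.up_genes) <= set(truth.signature_up)
        assert set(model.down_genes) <= set(truth.signature_down)

    def test_null_signal_errors_out(self):
        cfg = syn.SynthConfig(delta=0.0)
        datasets, truths = syn.simulate_training_trio(cfg, seed=5)
        truth = truths[0]
        clusters = [
            net.Cluster("up", members=truth.signature_up,
                        representatives=truth.signature_up[:3]),
            net.Cluster("dn", members=truth.signature_down,
                        representatives=truth.signature_down[:3]),
        ]
        with pytest.raises(ValueError, match="survive"):
            tr.train_signature(clusters, datasets, positive=1)


class TestEvaluateModel:
    def _model(self, truth):
        return tr.SignatureModel(
            up_genes=truth.signature_up[:20], down_genes=truth.signature_down[:20]
        )

    def test_training_cohort_auc_high(self, trio):
        _, datasets, truths = trio
        rep = tr.evaluate_model(
            self._model(truths[0]), datasets[0][0], datasets[0][1], positive=1
        )
        assert rep.roc_auc > 0.95
        assert rep.p_value < 1e-10
        assert not rep.degraded

    def test_permuted_labels_null_auc(self, trio, rng):
        _, datasets, truths = trio
        matrix, labels = datasets[0]
        model = self._model(truths[0])
        aucs = []
        for _ in range(20):
            shuffled = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            rep = tr.evaluate_model(model, matrix, shuffled, positive=1,
                                    keep_scores=False)
            aucs.append(rep.roc_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_missing_down_genes_degraded(self, trio):
        _, datasets, truths = trio
        matrix, labels = datasets[0]
        model = self._model(truths[0])
        up_only = matrix.loc[[g for g in matrix.index
                              if g not in set(model.down_genes)]]
        rep = tr.evaluate_model(model, up_only, labels, positive=1)
        assert rep.degraded
        assert rep.roc_auc > 0.9  # up set alone still discriminates

    def test_no_overlap_errors(self, trio):
        _, datasets, _ = trio
        matrix, labels = datasets[0]
        model = tr.SignatureModel(up_genes=["ghost1"], down_genes=["ghost2"])
        with pytest.raises(ValueError, match="overlap"):
            tr.evaluate_model(model, matrix, labels, positive=1)


class TestClassifierEstimator:
    def test_fit_predict_on_cohorts(self, trio):
        _, datasets, truths = trio
        X = pd.concat([m.T for m, _ in datasets], axis=0)
        y = np.concatenate([lab.to_numpy() for _, lab in datasets])
        cohorts = np.concatenate(
            [[i] * m.shape[1] for i, (m, _) in enumerate(datasets)]
        )
        clf = tr.BooleanSignatureClassifier(positive_class=1)
        clf.fit(X, y, cohorts=cohorts)
        assert len(clf.up_genes_) == 20 and len(clf.down_genes_) == 20
        held, truth_h = syn.simulate_cohort(
            syn.SynthConfig(), seed=4242, n_samples=150, offset=0.2,
            noise_mult=1.1,
        )
        scores = clf.decision_function(held.T)
        auc = tr.gene_auc(scores, truth_h.labels.to_numpy() == 1)
        assert auc > 0.95
        preds = clf.predict(held.T)
        assert (preds == truth_h.labels.to_numpy()).mean() > 0.85

    def test_sklearn_protocol(self):
        from sklearn.base import clone

        clf = tr.BooleanSignatureClassifier(k_cap=10)
        assert clone(clf).get_params()["k_cap"] == 10
        with pytest.raises(ValueError, match="2 classes"):
            clf.fit(np.zeros((8, 4)), np.zeros(8))
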