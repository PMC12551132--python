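"""Cross-validation splits, the seven-metric report, and the experiment
drivers (noise, sparsity, degree groups, cold start)."""

import itertools

import numpy as np
import pytest

import dgsl
from dgsl.encoder import EncoderConfig
from dgsl.evaluation import (
    compute_metrics,
    degree_group_report,
    make_cold_start_plan,
    make_fold_plan,
)
from dgsl.graphs import AssociationMatrix
from dgsl.training import TrainConfig

FAST = dict(enc=EncoderConfig(embed_dim=8), cfg=TrainConfig(seed=0, epochs=25))


def _assoc(rng, m=20, n=25, density=0.3):
    vals = (rng.random((m, n)) < density).astype(float)
    vals[0, 0] = 1.0
    return AssociationMatrix(vals, [f"d{i}" for i in range(m)], [f"g{j}" for j in range(n)])


class TestFoldPlan:
    def test_even_partition_with_balanced_negatives(self, rng):
        vals = np.zeros((5, 10))
        idx = rng.choice(50, size=20, replace=False)
        vals[idx // 10, idx % 10] = 1.0
        assoc = AssociationMatrix(vals, [f"d{i}" for i in range(5)], [f"g{j}" for j in range(10)])
        plan = make_fold_plan(assoc, 10, seed=4)
        for fold in range(10):
            assert len(plan.positives_of_fold(fold)) == 2
            assert len(plan.test_negatives[fold]) == 2

    def test_partition_and_negative_contracts(self, rng):
        assoc = _assoc(rng)
        plan = make_fold_plan(assoc, 10, seed=9)
        positives = set(assoc.positives())
        seen = [p for f in range(10) for p in plan.positives_of_fold(f)]
        assert len(seen) == len(positives) and set(seen) == positives
        for fold_negs in plan.test_negatives:
            assert len(set(fold_negs)) == len(fold_negs)
            assert not set(fold_negs) & positives

    def test_deterministic(self, rng):
        assoc = _assoc(rng)
        a = make_fold_plan(assoc, 10, seed=5)
        b = make_fold_plan(assoc, 10, seed=5)
        assert a.fold_of_positive == b.fold_of_positive
        assert a.test_negatives == b.test_negatives

    def test_too_few_positives_rejected(self):
        assoc = AssociationMatrix(np.eye(3), list("abc"), list("xyz"))
        with pytest.raises(ValueError, match="at least"):
            make_fold_plan(assoc, 10, seed=0)


class TestComputeMetrics:
    def test_perfect_separation(self):
        rep = compute_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        for name in ("auroc", "auprc", "accuracy", "precision", "recall", "f1", "mcc"):
            assert getattr(rep, name) == 1.0

    def test_full_inversion(self):
        assert compute_metrics([0.4, 0.6], [1, 0]).auroc == 0.0

    def test_contingency_example(self):
        # TP=2, FP=1, FN=1, TN=2
        scores = [0.9, 0.8, 0.1, 0.7, 0.2, 0.3]
        labels = [1, 1, 1, 0, 0, 0]
        rep = compute_metrics(scores, labels)
        assert rep.precision == pytest.approx(2 / 3)
        assert rep.recall == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.mcc == pytest.approx((4 - 1) / 9)

    def test_auroc_matches_concordance_oracle(self, rng):
        for _ in range(5):
            scores = rng.permutation(50) / 50.0  # untied
            labels = (rng.random(50) < 0.5).astype(int)
            if labels.sum() in (0, 50):
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            concordant = sum(1 for p in pos for q in neg if p > q)
            oracle = concordant / (len(pos) * len(neg))
            assert compute_metrics(scores, labels).auroc == pytest.approx(oracle, abs=1e-10)

    def test_mcc_matches_determinant_formula(self):
        # every 2x2 contingency table with entries <= 4 and both classes present
        for tp, fp, fn, tn in itertools.product(range(5), repeat=4):
            if tp + fn == 0 or fp + tn == 0:
                continue
            scores = [0.9] * tp + [0.1] * fn + [0.9] * fp + [0.1] * tn
            labels = [1] * (tp + fn) + [0] * (fp + tn)
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
            assert compute_metrics(scores, labels).mcc == pytest.approx(expected, abs=1e-10)

    def test_order_invariance(self, rng):
        scores = rng.random(30)
        labels = (rng.random(30) < 0.5).astype(int)
        labels[0], labels[1] = 1, 0
        perm = rng.permutation(30)
        a = compute_metrics(scores, labels)
        b = compute_metrics(scores[perm], labels[perm])
        assert a.as_dict() == b.as_dict()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics([0.1, 0.9], [1, 1])


class TestDegreeGroups:
    def test_single_group_equals_global(self, rng):
        assoc = _assoc(rng)
        pairs = [(0, 0), (1, 2), (2, 3), (3, 4)]
        scores = [0.9, 0.2, 0.8, 0.1]
        labels = [1, 0, 1, 0]
        groups = degree_group_report(pairs, scores, labels, assoc, group_edges=[10**6])
        assert list(groups) == [0]
        assert groups[0].as_dict() == compute_metrics(scores, labels).as_dict()

    def test_boundary_goes_to_higher_group(self):
        vals = np.zeros((2, 4))
        vals[0, :2] = 1.0  # disease 0 has degree 2
        vals[1, :] = 1.0  # disease 1 has degree 4
        assoc = AssociationMatrix(vals, ["lo", "hi"], list("wxyz"))
        pairs = [(0, 0), (0, 2), (1, 0), (1, 2)]
        scores = [0.9, 0.1, 0.8, 0.2]
        labels = [1, 0, 1, 0]
        groups = degree_group_report(pairs, scores, labels, assoc, group_edges=[2])
        # degree exactly 2 lands in group 1, degree 4 beyond the only edge too
        assert list(groups) == [1]

    def test_groups_partition_pairs(self, rng):
        assoc = _assoc(rng)
        plan = make_fold_plan(assoc, 5, seed=1)
        pairs = plan.positives_of_fold(0) + plan.test_negatives[0]
        labels = [1] * len(plan.positives_of_fold(0)) + [0] * len(plan.test_negatives[0])
        scores = rng.random(len(pairs))
        deg = assoc.values.sum(axis=1)
        edges = [int(np.median(deg))]
        group_of = np.searchsorted(edges, deg[[i for i, _ in pairs]], side="right")
        sizes = {g: int((group_of == g).sum()) for g in set(group_of)}
        assert sum(sizes.values()) == len(pairs)


class TestExperiments:
    def test_noise_relative_baseline_and_counts(self, rng):
        assoc = _assoc(rng)
        gd = gg = None
        enc = EncoderConfig(embed_dim=8, use_disease_view=False, use_gene_view=False)
        out = dgsl.noise_experiment(
            assoc, gd, gg, ratios=[1], seed=2, n_folds=5, enc=enc, cfg=TrainConfig(seed=2, epochs=25)
        )
        assert set(out) == {0.0, 1.0}
        assert all(v == 1.0 for v in out[0.0].values())
        assert np.isfinite(out[1.0]["auroc"])

    def test_pseudo_edges_avoid_positives(self, rng):
        from dgsl._rng import substream
        from dgsl.evaluation import _sample_complement_cells

        assoc = _assoc(rng)
        forbidden = set(assoc.positives())
        cells = _sample_complement_cells(substream(0, "noise"), forbidden, assoc.shape, 50)
        assert len(cells) == 50 and len(set(cells)) == 50
        assert not set(cells) & forbidden

    def test_sparsity_drop_counts_and_isolation(self, rng):
        assoc = _assoc(rng)
        enc = EncoderConfig(embed_dim=8, use_disease_view=False, use_gene_view=False)
        out = dgsl.sparsity_experiment(
            assoc, None, None, drop_fracs=[0.4], seed=3, n_folds=5, enc=enc, cfg=TrainConfig(seed=3, epochs=25)
        )
        assert set(out) == {0.0, 0.4}
        assert all(v == 1.0 for v in out[0.0]["relative"].values())
        assert 0.0 <= out[0.4]["absolute"]["auroc"] <= 1.0

    def test_cold_start_plan_contracts(self, rng):
        assoc = _assoc(rng)
        plan = make_cold_start_plan(assoc, "disease", 0.2, seed=6)
        held = set(plan.held_out_entities)
        per_entity_pos = {}
        for i, j in plan.test_positives:
            assert i in held
            per_entity_pos[i] = per_entity_pos.get(i, 0) + 1
        per_entity_neg = {}
        for i, j in plan.test_negatives:
            assert i in held
            assert assoc.values[i, j] == 0
            per_entity_neg[i] = per_entity_neg.get(i, 0) + 1
        assert per_entity_pos == per_entity_neg
        for e in held:
            assert per_entity_pos[e] == int(assoc.values[e].sum())

    def test_cold_start_training_excludes_held_entities(self, rng):
        assoc = _assoc(rng, m=15, n=20)
        report, plan = dgsl.cold_start_experiment(
            assoc, None, None, "disease", 0.2, seed=7,
            enc=EncoderConfig(embed_dim=8, use_disease_view=False, use_gene_view=False),
            cfg=TrainConfig(seed=7, epochs=25),
        )
        assert 0.0 <= report.auroc <= 1.0
        train_masked = assoc.masked([(e, j) for e in plan.held_out_entities for j in range(20)])
        assert not train_masked.values[plan.held_out_entities].any()

    def test_invalid_proportion_rejected(self, rng):
        with pytest.raises(ValueError, match="proportion"):
            make_cold_start_plan(_assoc(rng), "disease", 1.5, seed=0)
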