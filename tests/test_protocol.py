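"""Fold plans, the label-budget protocol, label hygiene, pseudo-prospective mode."""

import numpy as np
import pytest

from ieegssl.autoencoder import AEConfig
from ieegssl.evaluation import (
    ProtocolConfig, ProtocolError, make_folds, pseudo_prospective_eval,
    run_protocol, run_split, f1_scores, _binary_auroc,
)
from ieegssl.spectro import SpectroConfig
from ieegssl.synthetic import (
    GeneratorParams, generate_dataset, generate_recording, generate_segment,
    _child_seed,
)

SMOKE_AE = AEConfig(embedding_dim=16, gru_hidden=32, epochs=2, batch_size=128,
                    teacher_forcing=False, seed=0)
SMOKE_SPECTRO = SpectroConfig(log_transform=False)


class TestMakeFolds:
    def test_exact_stratification(self, params):
        segs = generate_dataset({c: 10 for c in range(4)}, params, seed=1)
        plan = make_folds(segs, k=10, seed=0)
        labels = {s.segment_id: s.label for s in segs}
        for fold in range(10):
            fold_labels = sorted(labels[i] for i in plan.fold_ids(fold))
            assert fold_labels == [0, 1, 2, 3]

    def test_disjoint_and_covering(self, small_dataset):
        plan = make_folds(small_dataset, k=5, seed=3)
        all_ids = [i for f in range(5) for i in plan.fold_ids(f)]
        assert sorted(all_ids) == sorted(s.segment_id for s in small_dataset)

    def test_deterministic_in_seed(self, small_dataset):
        a = make_folds(small_dataset, k=5, seed=9)
        b = make_folds(small_dataset, k=5, seed=9)
        assert a.assignment == b.assignment

    def test_class_smaller_than_k_rejected(self, params):
        segs = generate_dataset({0: 3, 1: 10, 2: 10, 3: 10}, params, seed=0)
        with pytest.raises(ProtocolError, match="class 0"):
            make_folds(segs, k=5, seed=0)


@pytest.fixture(scope="module")
def smoke_report(params):
    """k=3 protocol on 60 segments/class with a small label budget."""
    segs = generate_dataset({c: 60 for c in range(4)}, params, seed=100)
    plan = make_folds(segs, k=3, seed=0)
    # train_fraction 0.6 so the 3-fold validation split can supply 10 labels/class
    cfg = ProtocolConfig(label_budget=10, train_fraction=0.6, seed=0,
                         ae=SMOKE_AE, spectro=SMOKE_SPECTRO)
    return segs, plan, cfg, run_protocol(segs, plan, cfg)


class TestRunProtocol:
    def test_smoke_protocol_beats_chance(self, smoke_report):
        _, _, _, report = smoke_report
        mean_auroc, _ = report.aggregate("macro_auroc")
        assert mean_auroc > 0.5
        assert len(report.per_fold) == 3

    def test_rerun_is_identical(self, smoke_report):
        segs, plan, cfg, report = smoke_report
        again = run_protocol(segs, plan, cfg)
        for a, b in zip(report.per_fold, again.per_fold):
            for key in a:
                np.testing.assert_array_equal(a[key], b[key])

    def test_confusion_rows_match_fold_supports(self, smoke_report):
        segs, plan, _, report = smoke_report
        labels = {s.segment_id: s.label for s in segs}
        for fold, metrics in enumerate(report.per_fold):
            supports = np.bincount([labels[i] for i in plan.fold_ids(fold)], minlength=4)
            np.testing.assert_array_equal(metrics["confusion"].sum(axis=1), supports)

    def test_label_reads_restricted_to_budget_draw_and_scoring(self, smoke_report):
        """No gold-standard label of any unsupervised-training segment is ever read."""
        segs, plan, cfg, report = smoke_report
        assert report.audit.purposes() <= {"vs_draw", "test_scoring"}
        for fold in range(plan.k):
            test_ids = set(plan.fold_ids(fold))
            rest = sorted(i for i in plan.assignment if plan.assignment[i] != fold)
            rng = np.random.default_rng([cfg.seed, 0x5917, fold])
            order = rng.permutation(len(rest))
            n_train = min(max(int(round(cfg.train_fraction * len(rest))), 1), len(rest) - 1)
            train_ids = {rest[i] for i in order[:n_train]}
            val_ids = {rest[i] for i in order[n_train:]}
            fold_reads = {(p, s) for f, p, s in report.audit.entries if f == fold}
            assert {s for p, s in fold_reads if p == "vs_draw"} <= val_ids
            assert {s for p, s in fold_reads if p == "test_scoring"} == test_ids
            assert not {s for _, s in fold_reads} & train_ids

    def test_budget_shortfall_names_class(self, params):
        segs = generate_dataset({c: 20 for c in range(4)}, params, seed=5)
        plan = make_folds(segs, k=2, seed=0)
        cfg = ProtocolConfig(label_budget=50, seed=0, ae=SMOKE_AE, spectro=SMOKE_SPECTRO)
        with pytest.raises(ProtocolError, match="short by"):
            run_protocol(segs, plan, cfg)


class TestRunSplit:
    def test_duplicate_ids_rejected(self, params):
        segs = generate_dataset({c: 12 for c in range(4)}, params, seed=6)
        with pytest.raises(ProtocolError, match="duplicate"):
            run_split(segs, segs, segs,
                      ProtocolConfig(label_budget=2, seed=0, ae=SMOKE_AE))


@pytest.fixture(scope="module")
def small_pipeline(params):
    """A modest 4-class-pretrained model + classifier for deployment tests."""
    def ds(n, seed):
        return generate_dataset({c: n for c in range(4)}, params, seed=seed)

    cfg = ProtocolConfig(
        label_budget=20, seed=0, spectro=SMOKE_SPECTRO,
        ae=AEConfig(embedding_dim=16, gru_hidden=32, epochs=4, batch_size=64,
                    teacher_forcing=False, seed=0))
    return run_split(ds(60, 501), ds(40, 502), ds(20, 503), cfg), cfg


class TestPseudoProspective:
    def test_score_vector_length_and_range(self, small_pipeline, params):
        result, cfg = small_pipeline
        rec = generate_recording(150, 0.2, params, seed=42)
        out = pseudo_prospective_eval(result.model, result.classifier, rec,
                                      spectro=cfg.spectro)
        assert out["scores"].shape == (len(rec),)
        assert ((out["scores"] >= 0) & (out["scores"] <= 1)).all()
        assert out["n_segments"] == len(rec)

    def test_auroc_matches_direct_concordance(self, small_pipeline, params):
        result, cfg = small_pipeline
        rec = generate_recording(150, 0.2, params, seed=42)
        out = pseudo_prospective_eval(result.model, result.classifier, rec,
                                      spectro=cfg.spectro)
        y = np.array([s.label for s in rec])
        assert out["auroc"] == _binary_auroc(out["scores"], y == 1)

    def test_f1_consistent_with_thresholded_predictions(self, small_pipeline, params):
        result, cfg = small_pipeline
        rec = generate_recording(150, 0.2, params, seed=42)
        out = pseudo_prospective_eval(result.model, result.classifier, rec,
                                      spectro=cfg.spectro)
        y = np.array([s.label for s in rec])
        macro, _, _ = f1_scores((out["scores"] >= 0.5).astype(int), y, classes=(0, 1))
        assert out["macro_f1"] == macro

    def test_nonbinary_labels_rejected(self, small_pipeline, params):
        result, cfg = small_pipeline
        seg = generate_segment(2, params, seed=_child_seed(1, 0))
        with pytest.raises(ProtocolError, match="binary"):
            pseudo_prospective_eval(result.model, result.classifier, [seg],
                                    spectro=cfg.spectro)
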