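"""Label-budget cross-validation protocol and its metrics.

The protocol mirrors a semi-supervised annotation workflow: segments are split
into k stratified folds; for each held-out test fold the remainder is divided
90/10 into an unlabeled training set (TRSw/o) and a validation set; the
autoencoder trains on TRSw/o with labels discarded; N gold-standard labels per
class are then drawn from the validation set (the VS) to fit the KDE
classifier; the test fold is scored with one-vs-rest AUROC/AUPRC, F1 and a
confusion matrix.  Every label access during the protocol passes through an
audit log, so label hygiene (no training-set label ever read) is checkable
after the fact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, confusion_matrix, f1_score

from .autoencoder import AEConfig, TemporalAutoencoder, TrainHistory, train_autoencoder
from .kde import KDEClassifier, fit_kde
from .spectro import SpectroConfig, SpectrogramTensor, build_tensor
from .synthetic import SegmentRecord

__all__ = [
    "FoldPlan", "ProtocolConfig", "MetricsReport", "LabelAudit",
    "make_folds", "run_protocol", "run_split", "auroc_ovr", "auprc",
    "f1_scores", "pseudo_prospective_eval", "embed_tensors",
]


class ProtocolError(ValueError):
    pass


# ----------------------------------------------------------------- audit log

@dataclass
class LabelAudit:
    """Append-only log of every gold-standard label read during a protocol run."""

    entries: list[tuple[int, str, str]] = field(default_factory=list)  # (fold, purpose, segment_id)

    def record(self, fold: int, purpose: str, segment_id: str) -> None:
        self.entries.append((fold, purpose, segment_id))

    def purposes(self) -> set[str]:
        return {p for _, p, _ in self.entries}

    def segment_ids(self, purpose: str | None = None) -> set[str]:
        return {s for _, p, s in self.entries if purpose is None or p == purpose}

    def to_lines(self) -> list[str]:
        return [f"{f}\t{p}\t{s}" for f, p, s in self.entries]


class _AuditedLabels:
    """Gold-standard label store whose every read is logged."""

    def __init__(self, segments: list[SegmentRecord], audit: LabelAudit):
        self._labels = {s.segment_id: s.label for s in segments}
        self._audit = audit

    def read(self, segment_id: str, purpose: str, fold: int) -> int:
        self._audit.record(fold, purpose, segment_id)
        return self._labels[segment_id]


# ---------------------------------------------------------------- fold plans

@dataclass
class FoldPlan:
    k: int
    assignment: dict[str, int]  # segment_id -> fold index
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [s for s, f in self.assignment.items() if f == fold]


def make_folds(segments: list[SegmentRecord], k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified-by-class random fold assignment, deterministic in the seed."""
    rng = np.random.default_rng([int(seed), 0xF01D])
    by_class: dict[int, list[str]] = {}
    for s in segments:
        by_class.setdefault(s.label, []).append(s.segment_id)
    assignment: dict[str, int] = {}
    for label in sorted(by_class):
        ids = by_class[label]
        if len(ids) < k:
            raise ProtocolError(f"class {label} has {len(ids)} segments, fewer than k={k}")
        order = rng.permutation(len(ids))
        for pos, idx in enumerate(order):
            assignment[ids[idx]] = pos % k
    return FoldPlan(k=k, assignment=assignment, seed=int(seed))


# -------------------------------------------------------------------- config

@dataclass
class ProtocolConfig:
    label_budget: int = 100
    train_fraction: float = 0.9
    ae: AEConfig = field(default_factory=AEConfig)
    spectro: SpectroConfig = field(default_factory=SpectroConfig)
    eps_bw: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label_budget < 1:
            raise ProtocolError("label_budget must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ProtocolError("train_fraction must be in (0, 1)")


@dataclass
class MetricsReport:
    """Per-fold metric dictionaries plus mean +/- std aggregates."""

    per_fold: list[dict]
    audit: LabelAudit

    def aggregate(self, key: str) -> tuple[float, float]:
        vals = np.array([f[key] for f in self.per_fold], dtype=np.float64)
        return float(vals.mean()), float(vals.std())

    def summary(self) -> dict[str, dict[str, float]]:
        keys = [k for k, v in self.per_fold[0].items() if np.isscalar(v)]
        return {k: dict(zip(("mean", "std"), self.aggregate(k))) for k in keys}


# ------------------------------------------------------------------- metrics

def _binary_auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney concordance (ties counted 1/2) of scores for the positive mask."""
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auroc_ovr(posteriors: np.ndarray, labels: np.ndarray,
              classes: tuple[int, ...] = (0, 1, 2, 3)) -> tuple[dict[int, float], float]:
    """One-vs-rest AUROC per class + unweighted macro over defined classes."""
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=np.float64))
    labels = np.asarray(labels)
    per_class: dict[int, float] = {}
    for j, c in enumerate(classes):
        auc = _binary_auroc(posteriors[:, j], labels == c)
        if np.isnan(auc):
            warnings.warn(f"class {c} absent (or exhaustive) in labels; excluded from macro AUROC")
        per_class[c] = auc
    defined = [v for v in per_class.values() if not np.isnan(v)]
    if not defined:
        raise ProtocolError("no class has both positive and negative examples")
    return per_class, float(np.mean(defined))


def auprc(posteriors: np.ndarray, labels: np.ndarray,
          classes: tuple[int, ...] = (0, 1, 2, 3)) -> tuple[dict[int, float], float]:
    """One-vs-rest area under the precision-recall step curve (average precision)."""
    posteriors = np.atleast_2d(np.asarray(posteriors, dtype=np.float64))
    labels = np.asarray(labels)
    per_class: dict[int, float] = {}
    for j, c in enumerate(classes):
        mask = labels == c
        if mask.all() or not mask.any():
            warnings.warn(f"class {c} absent (or exhaustive) in labels; excluded from macro AUPRC")
            per_class[c] = float("nan")
            continue
        per_class[c] = float(average_precision_score(mask.astype(int), posteriors[:, j]))
    defined = [v for v in per_class.values() if not np.isnan(v)]
    if not defined:
        raise ProtocolError("no class has both positive and negative examples")
    return per_class, float(np.mean(defined))


def f1_scores(predictions: np.ndarray, labels: np.ndarray,
              classes: tuple[int, ...] = (0, 1, 2, 3)) -> tuple[float, float, np.ndarray]:
    """(macro F1, support-weighted F1, confusion matrix with true rows / predicted columns)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ProtocolError(f"length mismatch: {predictions.shape} vs {labels.shape}")
    macro = float(f1_score(labels, predictions, labels=list(classes), average="macro", zero_division=0))
    weighted = float(f1_score(labels, predictions, labels=list(classes), average="weighted", zero_division=0))
    cm = confusion_matrix(labels, predictions, labels=list(classes))
    return macro, weighted, cm


# ------------------------------------------------------------------ pipeline

def embed_tensors(model: TemporalAutoencoder, tensors: list[SpectrogramTensor],
                  batch_size: int = 256) -> np.ndarray:
    """(M, D) embedding matrix in input order."""
    X = np.stack([t.frames() for t in tensors])
    return np.concatenate([
        model.encode_batch(X[i:i + batch_size]) for i in range(0, len(X), batch_size)
    ])


def _draw_label_budget(val_ids: list[str], labels: _AuditedLabels, n_per_class: int,
                       classes: tuple[int, ...], rng: np.random.Generator,
                       fold: int) -> dict[int, list[str]]:
    """Reveal validation labels in random order until N per class are collected.

    Labels revealed but not kept are discarded (the read is still logged).
    """
    order = rng.permutation(len(val_ids))
    picked: dict[int, list[str]] = {c: [] for c in classes}
    for idx in order:
        if all(len(v) >= n_per_class for v in picked.values()):
            break
        sid = val_ids[idx]
        label = labels.read(sid, "vs_draw", fold)
        if label in picked and len(picked[label]) < n_per_class:
            picked[label].append(sid)
    short = {c: n_per_class - len(v) for c, v in picked.items() if len(v) < n_per_class}
    if short:
        desc = ", ".join(f"class {c} short by {m}" for c, m in sorted(short.items()))
        raise ProtocolError(f"validation set cannot supply N={n_per_class} per class: {desc}")
    return picked


@dataclass
class FoldResult:
    model: TemporalAutoencoder
    history: TrainHistory
    classifier: KDEClassifier
    metrics: dict


def _run_case(train_ids: list[str], val_ids: list[str], test_ids: list[str],
              tensors: dict[str, SpectrogramTensor], labels: _AuditedLabels,
              config: ProtocolConfig, fold: int,
              classes: tuple[int, ...] = (0, 1, 2, 3)) -> FoldResult:
    """One train/validate/test pass of the semi-supervised pipeline."""
    ae_cfg = AEConfig(**{**asdict(config.ae), "seed": int(config.ae.seed + 1000 * fold)})
    model, history = train_autoencoder(
        [tensors[i] for i in train_ids], [tensors[i] for i in val_ids], ae_cfg)

    val_emb = embed_tensors(model, [tensors[i] for i in val_ids])
    test_emb = embed_tensors(model, [tensors[i] for i in test_ids])
    emb_by_id = {i: e for i, e in zip(val_ids, val_emb)}

    rng = np.random.default_rng([int(config.seed), 0xB4D6E7, fold])
    picked = _draw_label_budget(val_ids, labels, config.label_budget, classes, rng, fold)
    clf = fit_kde({c: np.stack([emb_by_id[i] for i in ids]) for c, ids in picked.items()},
                  eps_bw=config.eps_bw)

    preds, post = clf.predict_batch(test_emb)
    y_true = np.array([labels.read(i, "test_scoring", fold) for i in test_ids])
    per_auroc, macro_auroc = auroc_ovr(post, y_true, classes)
    per_auprc, macro_auprc = auprc(post, y_true, classes)
    macro_f1, weighted_f1, cm = f1_scores(preds, y_true, classes)
    supports = cm.sum(axis=1)
    recalls = np.divide(np.diag(cm), supports, out=np.full(len(classes), np.nan),
                        where=supports > 0)
    metrics = {
        "fold": fold,
        "macro_auroc": macro_auroc,
        "macro_auprc": macro_auprc,
        "macro_f1": macro_f1,
        "weighted_f1": weighted_f1,
        "best_val_cosine": (max(history.val_cosine) if history.val_cosine else float("nan")),
        **{f"auroc_class_{c}": v for c, v in per_auroc.items()},
        **{f"auprc_class_{c}": v for c, v in per_auprc.items()},
        **{f"recall_class_{c}": float(r) for c, r in zip(classes, recalls)},
        "confusion": cm,
    }
    return FoldResult(model=model, history=history, classifier=clf, metrics=metrics)


def _split_train_val(ids: list[str], train_fraction: float,
                     rng: np.random.Generator) -> tuple[list[str], list[str]]:
    order = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    return [ids[i] for i in order[:n_train]], [ids[i] for i in order[n_train:]]


def run_protocol(segments: list[SegmentRecord], plan: FoldPlan,
                 config: ProtocolConfig) -> MetricsReport:
    """Full k-fold label-budget protocol; deterministic in the config seeds."""
    audit = LabelAudit()
    ids = [s.segment_id for s in segments]
    if len(set(ids)) != len(ids):
        raise ProtocolError("duplicate segment_ids in the dataset")
    labels = _AuditedLabels(segments, audit)
    tensors = {s.segment_id: build_tensor(s, config.spectro) for s in segments}
    per_fold = []
    for fold in range(plan.k):
        test_ids = sorted(plan.fold_ids(fold))
        rest = sorted(i for i in tensors if plan.assignment[i] != fold)
        rng = np.random.default_rng([int(config.seed), 0x5917, fold])
        train_ids, val_ids = _split_train_val(rest, config.train_fraction, rng)
        result = _run_case(train_ids, val_ids, test_ids, tensors, labels, config, fold)
        per_fold.append(result.metrics)
    return MetricsReport(per_fold=per_fold, audit=audit)


def run_split(train_segments: list[SegmentRecord], val_segments: list[SegmentRecord],
              test_segments: list[SegmentRecord], config: ProtocolConfig) -> FoldResult:
    """Single explicit train/validation/test split of the same pipeline.

    Returns the trained model and classifier so they can be deployed on novel
    recordings (pseudo-prospective use).
    """
    audit = LabelAudit()
    all_segments = list(train_segments) + list(val_segments) + list(test_segments)
    ids = [s.segment_id for s in all_segments]
    if len(set(ids)) != len(ids):
        raise ProtocolError("duplicate segment_ids across the train/validation/test splits")
    labels = _AuditedLabels(all_segments, audit)
    tensors = {s.segment_id: build_tensor(s, config.spectro) for s in all_segments}
    result = _run_case([s.segment_id for s in train_segments],
                       [s.segment_id for s in val_segments],
                       [s.segment_id for s in test_segments],
                       tensors, labels, config, fold=0)
    result.metrics["audit"] = audit
    return result


def pseudo_prospective_eval(model: TemporalAutoencoder, clf: KDEClassifier,
                            segments: list[SegmentRecord],
                            spectro: SpectroConfig = SpectroConfig(),
                            pathological_code: int = 2,
                            threshold: float = 0.5) -> dict:
    """Binary IED scoring of a long recording with a 4-class-pretrained pipeline.

    The IED score of a segment is the posterior mass of the pathological class.
    Segment labels must be binary: 0 = physiological, 1 = IED.
    """
    y = np.array([s.label for s in segments])
    if not set(np.unique(y)) <= {0, 1}:
        raise ProtocolError("pseudo-prospective labels must be binary {0, 1}")
    tensors = [build_tensor(s, spectro) for s in segments]
    emb = embed_tensors(model, tensors)
    _, post = clf.predict_batch(emb)
    col = clf.classes.index(pathological_code)
    scores = post[:, col]
    preds = (scores >= threshold).astype(int)
    macro_f1, weighted_f1, cm = f1_scores(preds, y, classes=(0, 1))
    return {
        "scores": scores,
        "auroc": _binary_auroc(scores, y == 1),
        "auprc": float(average_precision_score(y, scores)),
        "macro_f1": macro_f1,
        "weighted_f1": weighted_f1,
        "confusion": cm,
        "n_segments": len(segments),
    }
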