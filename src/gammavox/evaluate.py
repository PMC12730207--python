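"""Decision fusion and the repeated-split evaluation protocol.

Frame-level classifier outputs are fused three ways: majority voting over
consecutive groups of m frames, a single modal decision per vocalization,
and a dual-network rule in which two classifiers trained on different frame
durations must agree on the vocalization label or the test is rejected.
Metrics are the confusion matrix, accuracy, and macro-averaged per-class
precision / recall / F1 (F1_i = 2 P_i R_i / (P_i + R_i)).

The protocol repeats a per-class shuffled 45/5 (90%/10%) train/test split
several times with fresh seeds — repeated random splits rather than disjoint
folds, which keeps each training set large on a small corpus — and averages
the reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import network
from .network import NetworkConfig, TrainedNetwork, balance_classes
from .preprocess import AudioClip
from .vectors import FeatureParams, build_vectors

__all__ = [
    "REJECT",
    "EvaluationReport",
    "SplitPlan",
    "majority_vote",
    "vocalization_decision",
    "dual_decision",
    "compute_metrics",
    "RecordingFeatures",
    "extract_features",
    "run_protocol",
    "run_dual_protocol",
]

log = logging.getLogger(__name__)

#: Sentinel returned by the dual-network rule when the two networks disagree.
REJECT = "<reject>"


@dataclass
class EvaluationReport:
    confusion: np.ndarray  # (K, K) counts, rows true / columns predicted
    classes: list
    accuracy: float
    per_class_precision: np.ndarray
    per_class_recall: np.ndarray
    per_class_F1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_F1: float
    n_tests: int
    rejected: int = 0

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_F1": self.macro_F1,
            "per_class_precision": self.per_class_precision.tolist(),
            "per_class_recall": self.per_class_recall.tolist(),
            "per_class_F1": self.per_class_F1.tolist(),
            "n_tests": self.n_tests,
            "rejected": self.rejected,
        }


@dataclass(frozen=True)
class SplitPlan:
    """Repeated per-class random splits: 45 train / 5 test by default."""

    n_repeats: int = 5
    per_class_train: int = 45
    per_class_test: int = 5
    seeds: tuple[int, ...] | None = None

    def repeat_seeds(self, base_seed: int) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) != self.n_repeats:
                raise ValueError("seeds length must equal n_repeats")
            return list(self.seeds)
        ss = np.random.SeedSequence(base_seed)
        return [int(s) & 0x7FFFFFFF for s in ss.generate_state(self.n_repeats)]


def _modal_label(labels) -> object:
    """Most frequent label; ties broken by earliest first appearance."""
    labels = list(labels)
    counts: dict = {}
    first: dict = {}
    for i, lab in enumerate(labels):
        counts[lab] = counts.get(lab, 0) + 1
        first.setdefault(lab, i)
    return max(counts, key=lambda lab: (counts[lab], -first[lab]))


def majority_vote(labels, group_size: int) -> list:
    """One modal decision per consecutive group of ``group_size`` labels.

    The trailing partial group is voted as-is.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels to vote on")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    return [
        _modal_label(labels[i : i + group_size])
        for i in range(0, len(labels), group_size)
    ]


def vocalization_decision(frame_labels) -> object:
    """Single modal label over all of a recording's frame decisions."""
    frame_labels = list(frame_labels)
    if not frame_labels:
        raise ValueError("no frame labels for this recording")
    return _modal_label(frame_labels)


def dual_decision(label_a, label_b):
    """Accept the common label of two networks, otherwise reject the test."""
    return label_a if label_a == label_b else REJECT


def compute_metrics(
    confusion: np.ndarray, classes=None, rejected: int = 0
) -> EvaluationReport:
    """Accuracy and macro precision / recall / F1 from a confusion matrix.

    A class never predicted gets precision 0 (logged); a class with
    P_i + R_i = 0 gets F1_i = 0.
    """
    C = np.asarray(confusion)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(C < 0) or not np.issubdtype(C.dtype, np.number):
        raise ValueError("confusion entries must be non-negative counts")
    total = C.sum()
    if total <= 0:
        raise ValueError("confusion matrix has no entries")
    K = C.shape[0]
    if classes is None:
        classes = list(range(K))
    diag = np.diag(C).astype(float)
    col = C.sum(axis=0).astype(float)
    row = C.sum(axis=1).astype(float)
    empty_cols = col == 0
    if empty_cols.any():
        log.info("classes never predicted (precision set to 0): %s",
                 [classes[i] for i in np.nonzero(empty_cols)[0]])
    precision = np.divide(diag, col, out=np.zeros(K), where=col > 0)
    recall = np.divide(diag, row, out=np.zeros(K), where=row > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros(K), where=pr > 0)
    return EvaluationReport(
        confusion=C, classes=list(classes),
        accuracy=float(diag.sum() / total),
        per_class_precision=precision, per_class_recall=recall, per_class_F1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_F1=float(f1.mean()),
        n_tests=int(total) + int(rejected), rejected=int(rejected),
    )


def _confusion_from_pairs(true_labels, pred_labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    C = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        C[index[t], index[p]] += 1
    return C


# ------------------------------------------------------------ feature cache

@dataclass
class RecordingFeatures:
    """Extracted vectors of one recording under fixed feature parameters."""

    source_id: str
    label: str
    matrix: np.ndarray  # (n_vectors, dim); one row for vocalization modes
    mode: str


def extract_features(
    clips: list[AudioClip], mode: str, params: FeatureParams
) -> list[RecordingFeatures]:
    """Extract features once per recording (shared across protocol repeats)."""
    from .vectors import _design_bank  # shared bank across recordings
    out: list[RecordingFeatures] = []
    bank = None
    for clip in clips:
        if bank is None:
            NS = int(round(clip.fs * params.frame_duration_ms / 1000.0))
            bank = _design_bank(params, clip.fs, NS)
        vecs = build_vectors(clip, mode, params, bank=bank)
        if not vecs:
            log.warning("recording %s produced no feature vectors", clip.source_id)
            continue
        out.append(
            RecordingFeatures(
                source_id=clip.source_id, label=clip.label,
                matrix=np.vstack([v.values for v in vecs]), mode=mode,
            )
        )
    return out


def _split_per_class(
    features: list[RecordingFeatures], plan: SplitPlan, seed: int
) -> tuple[list[RecordingFeatures], list[RecordingFeatures]]:
    if plan.per_class_test < 1 or plan.per_class_train < 1:
        raise ValueError("per-class train and test counts must be >= 1")
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[RecordingFeatures]] = {}
    for f in features:
        by_label.setdefault(f.label, []).append(f)
    need = plan.per_class_train + plan.per_class_test
    short = {lab: len(v) for lab, v in by_label.items() if len(v) < need}
    if short:
        raise ValueError(
            f"need {need} recordings per class, got insufficient counts: {short}"
        )
    train, test = [], []
    for lab in sorted(by_label):
        recs = by_label[lab]
        order = rng.permutation(len(recs))
        train += [recs[i] for i in order[: plan.per_class_train]]
        test += [recs[i] for i in order[plan.per_class_train : need]]
    return train, test


def _stack(features: list[RecordingFeatures]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([f.matrix for f in features])
    y = np.concatenate([[f.label] * f.matrix.shape[0] for f in features])
    return X, y


def _train_on(
    train_set: list[RecordingFeatures],
    frame_mode: bool,
    seed: int,
    net_config: NetworkConfig | None,
) -> TrainedNetwork:
    X, y = _stack(train_set)
    if frame_mode:
        X, y = balance_classes(X, y, seed)
    from dataclasses import replace

    cfg = replace(net_config or NetworkConfig(), seed=seed)
    return network.train(cfg, X, y)


def run_protocol(
    features: list[RecordingFeatures],
    plan: SplitPlan = SplitPlan(),
    base_seed: int = 0,
    group_sizes: tuple[int, ...] = (5, 10, 25),
    net_config: NetworkConfig | None = None,
) -> dict:
    """Repeated-split evaluation of one feature mode.

    For every repeat: per-class shuffle and 45/5 split, balance training
    frames (frame modes), train, then evaluate at frame granularity, at
    each m-frame voting group size, and at vocalization granularity.
    Vocalization modes (one vector per recording) are evaluated directly.

    Returns per-repeat reports and cross-repeat averages (mean accuracy of
    the averaged report equals the arithmetic mean of repeat accuracies).
    """
    if not features:
        raise ValueError("no feature sets supplied")
    mode = features[0].mode
    frame_mode = mode in ("P2", "P4")
    classes = sorted({f.label for f in features})
    seeds = plan.repeat_seeds(base_seed)

    repeats: list[dict] = []
    for r, seed in enumerate(seeds):
        train_set, test_set = _split_per_class(features, plan, seed)
        net = _train_on(train_set, frame_mode, seed, net_config)

        entry: dict = {"seed": seed}
        if frame_mode:
            true_f, pred_f = [], []
            per_rec_pred: list[tuple[str, np.ndarray]] = []
            for rec in test_set:
                labels = network.predict(net, rec.matrix)
                per_rec_pred.append((rec.label, labels))
                true_f += [rec.label] * len(labels)
                pred_f += list(labels)
            entry["frame"] = compute_metrics(
                _confusion_from_pairs(true_f, pred_f, classes), classes
            )
            for m in group_sizes:
                t_g, p_g = [], []
                for lab, labels in per_rec_pred:
                    votes = majority_vote(list(labels), m)
                    t_g += [lab] * len(votes)
                    p_g += votes
                entry[f"group_{m}"] = compute_metrics(
                    _confusion_from_pairs(t_g, p_g, classes), classes
                )
            t_v = [lab for lab, labels in per_rec_pred]
            p_v = [vocalization_decision(list(labels)) for _, labels in per_rec_pred]
            entry["vocalization"] = compute_metrics(
                _confusion_from_pairs(t_v, p_v, classes), classes
            )
        else:
            true_v = [rec.label for rec in test_set]
            pred_v = [network.predict(net, rec.matrix)[0] for rec in test_set]
            entry["vocalization"] = compute_metrics(
                _confusion_from_pairs(true_v, pred_v, classes), classes
            )
        entry["stop_reason"] = net.training_log["stop_reason"]
        entry["n_iter"] = net.training_log["n_iter"]
        repeats.append(entry)
        log.info("repeat %d/%d done (seed %d)", r + 1, len(seeds), seed)

    levels = [k for k in repeats[0] if isinstance(repeats[0][k], EvaluationReport)]
    averaged = {}
    for level in levels:
        averaged[level] = {
            stat: {
                "mean": float(np.mean([getattr(rep[level], stat) for rep in repeats])),
                "std": float(np.std([getattr(rep[level], stat) for rep in repeats])),
            }
            for stat in ("accuracy", "macro_precision", "macro_recall", "macro_F1")
        }
    return {"mode": mode, "repeats": repeats, "averaged": averaged, "classes": classes}


def run_dual_protocol(
    features_a: list[RecordingFeatures],
    features_b: list[RecordingFeatures],
    plan: SplitPlan = SplitPlan(),
    base_seed: int = 0,
    net_config: NetworkConfig | None = None,
) -> dict:
    """Dual-network evaluation: two frame-mode feature sets (two frame
    durations), one network each; a test vocalization is accepted only when
    the two vocalization-level decisions agree.

    Reports the recognition rate over non-rejected tests, the rejection
    rate, and each single network's vocalization-level report on all tests
    and on the accepted subset.
    """
    ids_a = {f.source_id for f in features_a}
    ids_b = {f.source_id for f in features_b}
    common = ids_a & ids_b
    features_a = [f for f in features_a if f.source_id in common]
    features_b = [f for f in features_b if f.source_id in common]
    by_id_b = {f.source_id: f for f in features_b}
    classes = sorted({f.label for f in features_a})
    seeds = plan.repeat_seeds(base_seed)

    repeats = []
    for seed in seeds:
        train_a, test_a = _split_per_class(features_a, plan, seed)
        train_b = [by_id_b[f.source_id] for f in train_a]
        test_b = [by_id_b[f.source_id] for f in test_a]
        net_a = _train_on(train_a, True, seed, net_config)
        net_b = _train_on(train_b, True, seed, net_config)

        decisions = []
        for rec_a, rec_b in zip(test_a, test_b):
            da = vocalization_decision(list(network.predict(net_a, rec_a.matrix)))
            db = vocalization_decision(list(network.predict(net_b, rec_b.matrix)))
            decisions.append((rec_a.label, da, db, dual_decision(da, db)))

        accepted = [(t, d) for t, _, _, d in decisions if d != REJECT]
        rejected = len(decisions) - len(accepted)
        entry = {
            "seed": seed,
            "n_tests": len(decisions),
            "rejected": rejected,
            "rejection_rate": rejected / len(decisions),
        }
        if accepted:
            t_acc, p_acc = zip(*accepted)
            entry["dual"] = compute_metrics(
                _confusion_from_pairs(t_acc, p_acc, classes), classes,
                rejected=rejected,
            )
            # single networks restricted to the accepted tests
            acc_idx = [i for i, (_, _, _, d) in enumerate(decisions) if d != REJECT]
            for name, col in (("net_a", 1), ("net_b", 2)):
                preds = [decisions[i][col] for i in acc_idx]
                truths = [decisions[i][0] for i in acc_idx]
                entry[f"{name}_accepted"] = compute_metrics(
                    _confusion_from_pairs(truths, preds, classes), classes
                )
        for name, col in (("net_a", 1), ("net_b", 2)):
            preds = [d[col] for d in decisions]
            truths = [d[0] for d in decisions]
            entry[f"{name}_all"] = compute_metrics(
                _confusion_from_pairs(truths, preds, classes), classes
            )
        repeats.append(entry)

    return {
        "repeats": repeats,
        "classes": classes,
        "mean_dual_accuracy": float(np.mean(
            [r["dual"].accuracy for r in repeats if "dual" in r]
        )),
        "mean_rejection_rate": float(np.mean([r["rejection_rate"] for r in repeats])),
    }
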