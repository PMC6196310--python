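"""SVM training and evaluation over precomputed tree-kernel Gram matrices.

The binary stage separates interacting from non-interacting pairs with two
score cutoffs (> pos_cut interacting, < neg_cut non-interacting, the dead
zone in between defaulting to non-interacting); the multi-class stage
applies one-vs-all models to the binary positives and assigns the
highest-scoring class.  A range decision rule (score within [0, 1]) is
available for the protein-protein task.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

CUTOFF_RULE = "cutoff"   # > pos_cut interacting, < neg_cut not, dead zone -> not
RANGE_RULE = "range"     # interacting iff score within [0, 1]


@dataclass
class TrainedModel:
    positive_label: str
    support_indices: List[int]     # into the training tree id list
    dual_coef: List[float]
    bias: float
    training_ids: List[str]

    def decision(self, kernel_row: np.ndarray) -> float:
        """Decision value from one row of test-vs-training kernel values."""
        row = np.asarray(kernel_row, dtype=float)
        if row.shape[-1] != len(self.training_ids):
            raise ValueError(
                f"kernel row has {row.shape[-1]} columns, model expects "
                f"{len(self.training_ids)}")
        return float(np.dot(self.dual_coef, row[self.support_indices]) + self.bias)


@dataclass
class PredictionResult:
    instance_id: str
    doc_id: str
    arg1: str
    arg2: str
    label: str
    score: float
    class_scores: Dict[str, float] = field(default_factory=dict)


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class EvalReport:
    per_class: Dict[str, ClassMetrics]
    micro_f1: float


def train_binary(gram: np.ndarray, labels: Sequence[int], C: float = 1.0,
                 training_ids: Optional[Sequence[str]] = None,
                 positive_label: str = "+1",
                 class_weight: Optional[dict] = None) -> TrainedModel:
    """Soft-margin SVM on a precomputed symmetric Gram matrix with +-1 labels."""
    gram = np.asarray(gram, dtype=float)
    y = np.asarray(labels, dtype=int)
    if gram.shape[0] != gram.shape[1] or gram.shape[0] != len(y):
        raise ValueError("gram must be square and aligned with labels")
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels contain a single class")
    svc = SVC(kernel="precomputed", C=C, class_weight=class_weight)
    svc.fit(gram, y)
    ids = list(training_ids) if training_ids is not None else [
        str(i) for i in range(gram.shape[0])]
    return TrainedModel(
        positive_label=positive_label,
        support_indices=[int(i) for i in svc.support_],
        dual_coef=[float(v) for v in svc.dual_coef_[0]],
        bias=float(svc.intercept_[0]),
        training_ids=ids)


def train_multiclass_ova(gram: np.ndarray, labels: Sequence[str],
                         C: float = 1.0,
                         training_ids: Optional[Sequence[str]] = None,
                         positive_classes: Optional[Sequence[str]] = None,
                         class_weight: Optional[dict] = None
                         ) -> Dict[str, TrainedModel]:
    """One binary model per positive class (one-vs-all)."""
    labels = list(labels)
    classes = list(positive_classes) if positive_classes is not None else sorted(
        set(labels))
    models: Dict[str, TrainedModel] = {}
    for cls in classes:
        y = [1 if lab == cls else -1 for lab in labels]
        n_pos = sum(1 for v in y if v == 1)
        if n_pos < 2 or n_pos > len(y) - 2:
            logger.warning("class %s has too few instances (%d); model skipped",
                           cls, n_pos)
            continue
        cw = None
        if class_weight == "balanced":
            cw = {1: len(y) / (2.0 * n_pos), -1: len(y) / (2.0 * (len(y) - n_pos))}
        models[cls] = train_binary(gram, y, C, training_ids,
                                   positive_label=cls, class_weight=cw)
    return models


def binary_decision(score: float, pos_cut: float = 0.0, neg_cut: float = -0.3,
                    rule: str = CUTOFF_RULE) -> bool:
    """Apply the binary decision rule to a raw SVM score."""
    if rule == RANGE_RULE:
        return 0.0 <= score <= 1.0
    if score > pos_cut:
        return True
    if score < neg_cut:
        return False
    return False  # dead zone defaults to non-interacting


def predict(binary_model: TrainedModel,
            ova_models: Dict[str, TrainedModel],
            test_rows: Dict[str, np.ndarray],
            instance_meta: Dict[str, Tuple[str, str, str]],
            negative_label: str = "NEG",
            cutoffs: Tuple[float, float] = (0.0, -0.3),
            rule: str = CUTOFF_RULE) -> List[PredictionResult]:
    """Score test kernel rows: binary gate first, then one-vs-all argmax on
    the binary positives."""
    pos_cut, neg_cut = cutoffs
    results = []
    for instance_id in sorted(test_rows):
        row = test_rows[instance_id]
        doc_id, arg1, arg2 = instance_meta[instance_id]
        score = binary_model.decision(row)
        if binary_decision(score, pos_cut, neg_cut, rule) and ova_models:
            class_scores = {cls: m.decision(row) for cls, m in ova_models.items()}
            label = max(sorted(class_scores), key=lambda c: class_scores[c])
        else:
            class_scores = {}
            label = negative_label
        results.append(PredictionResult(instance_id, doc_id, arg1, arg2,
                                        label, score, class_scores))
    return results


def evaluate(predicted: Dict[Tuple[str, str, str], str],
             gold: Dict[Tuple[str, str, str], str],
             negative_label: str = "NEG") -> EvalReport:
    """Per-class precision/recall/F1 plus the support-weighted micro-average.

    Both inputs map a (doc_id, arg1, arg2) key to a class label; pairs
    absent from a map count as the negative class.
    """
    if not gold:
        raise ValueError("empty gold standard")
    classes = sorted({c for c in list(gold.values()) + list(predicted.values())
                      if c != negative_label})
    per_class: Dict[str, ClassMetrics] = {}
    for cls in classes:
        tp = fp = fn = 0
        keys = set(gold) | set(predicted)
        for key in keys:
            g = gold.get(key, negative_label) == cls
            p = predicted.get(key, negative_label) == cls
            tp += g and p
            fp += p and not g
            fn += g and not p
        per_class[cls] = ClassMetrics(tp, fp, fn)
    supports = {cls: per_class[cls].tp + per_class[cls].fn for cls in classes}
    micro = micro_average([per_class[c].f1 for c in classes],
                          [supports[c] for c in classes])
    return EvalReport(per_class, micro)


def evaluate_binary(predicted_pairs: set, gold_pairs: set) -> ClassMetrics:
    """Interacting-vs-not contingency over pair keys."""
    tp = len(predicted_pairs & gold_pairs)
    return ClassMetrics(tp=tp, fp=len(predicted_pairs) - tp,
                        fn=len(gold_pairs) - tp)


def micro_average(f1_scores: Sequence[float], weights: Sequence[float]) -> float:
    """Weight-averaged F1 over evaluation sets with proportional weights."""
    if len(f1_scores) != len(weights):
        raise ValueError("scores and weights must be parallel")
    total = float(sum(weights))
    if total == 0:
        return 0.0
    return float(sum(f * w for f, w in zip(f1_scores, weights)) / total)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def model_to_dict(model: TrainedModel) -> dict:
    return {
        "positive_label": model.positive_label,
        "support_indices": model.support_indices,
        "dual_coef": model.dual_coef,
        "bias": model.bias,
        "training_ids": model.training_ids,
    }


def model_from_dict(data: dict) -> TrainedModel:
    return TrainedModel(
        positive_label=data["positive_label"],
        support_indices=list(data["support_indices"]),
        dual_coef=[float(v) for v in data["dual_coef"]],
        bias=float(data["bias"]),
        training_ids=list(data["training_ids"]))
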