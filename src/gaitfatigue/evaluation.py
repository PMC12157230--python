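"""Cross-validation protocols, confusion-count metrics and report artifacts.

Two protocols:

* **LOSOCV** (subject-independent): each fold holds out every segment of one
  subject; the model never sees the test subject. One fold per subject.
* **9-fold subject-dependent**: fold *j* tests window index *j* of every
  subject in both states, so every subject contributes to both train and
  test and each fold is exactly label-balanced. Because adjacent windows
  overlap by 50 %, neighbouring folds share frames — an intentional,
  documented property of this protocol that partly explains why
  subject-dependent accuracy exceeds subject-independent accuracy.

Metrics are computed from integer confusion counts with *fatigued* as the
positive class (per-class tables swap the positive class):

    accuracy  = (TP + TN) / (TP + FP + TN + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2·precision·recall / (precision + recall)

Division-by-zero cases return 0 and set a flag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from gaitfatigue.combinations import CombinationSpec, select_channels
from gaitfatigue.model import ModelConfig, build_model, train, predict, attention_weights
from gaitfatigue.segmentation import SegmentSet

POSITIVE_CLASS = 1  # fatigued


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    protocol: str  # "losocv" | "kfold9"

    def check(self, n_total: int) -> None:
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError(f"fold {self.fold_id}: train/test overlap")
        if len(self.train_idx) + len(self.test_idx) != n_total:
            raise ValueError(f"fold {self.fold_id}: indices do not partition the set")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                               positive: int = POSITIVE_CLASS) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos_t, pos_p = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def compute_metrics(c: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/F1 from counts; 0/0 cases → 0 with a flag."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    flags = []

    def _safe(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = _safe(c.tp, c.tp + c.fp, "precision")
    recall = _safe(c.tp, c.tp + c.fn, "recall")
    f1 = _safe(2 * precision * recall, precision + recall, "f1")
    return {
        "accuracy": (c.tp + c.tn) / c.total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "zero_division_flags": flags,
    }


def per_class_metrics(c: ConfusionCounts) -> dict:
    """Two-row metric table: fatigued as positive, then non-fatigued."""
    swapped = ConfusionCounts(tp=c.tn, fp=c.fn, tn=c.tp, fn=c.fp)
    return {"fatigued": compute_metrics(c), "non_fatigued": compute_metrics(swapped)}


def reconstruct_counts_from_recalls(recall_pos: float, recall_neg: float,
                                    n_per_class: int) -> ConfusionCounts:
    """Integer confusion counts implied by per-class recalls on a balanced set.

    With ``n_per_class`` segments in each class, the fatigued-class recall
    fixes TP = round(recall_pos·n) (hence FN) and the non-fatigued recall
    fixes TN (hence FP). Useful to check that reported per-class recalls,
    accuracies and precisions are mutually consistent.
    """
    tp = int(round(recall_pos * n_per_class))
    tn = int(round(recall_neg * n_per_class))
    return ConfusionCounts(tp=tp, fn=n_per_class - tp, tn=tn, fp=n_per_class - tn)


# ---------------------------------------------------------------------------
# splits


def losocv_split(segments: SegmentSet) -> list[FoldSplit]:
    """One fold per subject; the test fold is all of that subject's segments."""
    subjects = segments.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    labels, sub = segments.labels, segments.subject_ids
    for s in subjects:
        if len(np.unique(labels[sub == s])) < 2:
            raise ValueError(f"subject {s} lacks one of the two states")
    idx = np.arange(segments.n_segments)
    folds = []
    for k, s in enumerate(subjects):
        test = idx[sub == s]
        fold = FoldSplit(k, idx[sub != s], test, "losocv")
        fold.check(segments.n_segments)
        folds.append(fold)
    return folds


def kfold9_split(segments: SegmentSet) -> list[FoldSplit]:
    """Nine subject-dependent folds: fold j tests window j of every subject-state."""
    win = segments.window_ids
    expected = set(range(9))
    for s in segments.subjects:
        for lab in (0, 1):
            have = set(win[(segments.subject_ids == s) & (segments.labels == lab)].tolist())
            if have != expected:
                raise ValueError(
                    f"subject {s}, label {lab}: window indices {sorted(have)} "
                    "do not cover 0–8"
                )
    idx = np.arange(segments.n_segments)
    folds = []
    for j in range(9):
        test = idx[win == j]
        fold = FoldSplit(j, idx[win != j], test, "kfold9")
        fold.check(segments.n_segments)
        folds.append(fold)
    return folds


def make_splits(segments: SegmentSet, protocol: str) -> list[FoldSplit]:
    if protocol == "losocv":
        return losocv_split(segments)
    if protocol == "kfold9":
        return kfold9_split(segments)
    raise ValueError(f"unknown protocol {protocol!r}")


# ---------------------------------------------------------------------------
# cross-validated evaluation


@dataclass
class EvalReport:
    """Everything one cross-validated run produced."""

    protocol: str
    combination_id: int
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[dict]
    pooled_counts: ConfusionCounts
    pooled_metrics: dict          # per-class table (fatigued / non_fatigued)
    macro_accuracy: float         # mean of per-fold accuracies
    per_subject_accuracy: dict    # subject → accuracy over that subject's test segments
    histories: list[dict]
    attention_samples: dict       # label name → (T', T') weight matrix
    seed: int

    @property
    def pooled_accuracy(self) -> float:
        return self.pooled_metrics["fatigued"]["accuracy"]


def run_cv(segments: SegmentSet, spec: CombinationSpec | None, protocol: str,
           cfg: ModelConfig, seed: int = 0) -> EvalReport:
    """Train a fresh seeded model per fold and pool test predictions.

    ``spec`` restricts channels to one combination (None = use all). Per-fold
    model seeds are derived as ``seed + fold_id`` so folds are independent
    but the whole run is reproducible.
    """
    data = select_channels(segments, spec) if spec is not None else segments
    folds = make_splits(data, protocol)
    input_shape = data.data.shape[1:]

    fold_counts, fold_metrics, histories = [], [], []
    y_pred_all = np.full(data.n_segments, -1, dtype=int)
    attention_samples: dict[str, np.ndarray] = {}

    for fold in folds:
        fold_cfg = ModelConfig(**{**asdict(cfg), "seed": int(seed) + fold.fold_id})
        net = build_model(fold_cfg, input_shape)
        train_set = SegmentSet(
            data=data.data[fold.train_idx], labels=data.labels[fold.train_idx],
            subject_ids=data.subject_ids[fold.train_idx],
            window_ids=data.window_ids[fold.train_idx],
            channel_names=data.channel_names,
        )
        try:
            fitted = train(net, train_set, fold_cfg)
        except Exception as exc:  # surface which fold broke
            raise RuntimeError(f"training failed in fold {fold.fold_id}: {exc}") from exc
        _, y_hat = predict(fitted, data.data[fold.test_idx])
        y_pred_all[fold.test_idx] = y_hat
        counts = confusion_from_predictions(data.labels[fold.test_idx], y_hat)
        fold_counts.append(counts)
        fold_metrics.append(compute_metrics(counts))
        histories.append(fitted.history)
        if not attention_samples:
            for name, lab in (("non_fatigued", 0), ("fatigued", 1)):
                cand = fold.test_idx[data.labels[fold.test_idx] == lab]
                if cand.size:
                    attention_samples[name] = attention_weights(fitted, data.data[cand[0]])

    pooled = sum(fold_counts[1:], fold_counts[0])
    per_subject = {
        s: float(np.mean(y_pred_all[data.subject_ids == s]
                         == data.labels[data.subject_ids == s]))
        for s in data.subjects
    }
    return EvalReport(
        protocol=protocol,
        combination_id=spec.id if spec is not None else -1,
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        pooled_counts=pooled,
        pooled_metrics=per_class_metrics(pooled),
        macro_accuracy=float(np.mean([m["accuracy"] for m in fold_metrics])),
        per_subject_accuracy=per_subject,
        histories=histories,
        attention_samples=attention_samples,
        seed=int(seed),
    )


def render_reports(report: EvalReport, outdir: str | Path) -> list[Path]:
    """Write the report as machine-readable JSON/CSV artifacts.

    Emits a metrics JSON (pooled + per-fold), a pooled confusion-matrix CSV,
    a per-subject accuracy CSV (radial-chart data), per-fold learning-curve
    CSVs and attention heatmap matrices. Re-rendering is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    pooled = report.pooled_counts
    doc = {
        "protocol": report.protocol,
        "combination_id": report.combination_id,
        "seed": report.seed,
        "pooled_counts": asdict(pooled),
        "pooled_metrics": report.pooled_metrics,
        "macro_accuracy": report.macro_accuracy,
        "fold_counts": [asdict(c) for c in report.fold_counts],
        "fold_metrics": report.fold_metrics,
        "per_subject_accuracy": report.per_subject_accuracy,
    }
    p = outdir / "metrics.json"
    p.write_text(json.dumps(doc, indent=1, sort_keys=True))
    written.append(p)

    cm = pd.DataFrame(
        [[pooled.tn, pooled.fp], [pooled.fn, pooled.tp]],
        index=["true_non_fatigued", "true_fatigued"],
        columns=["pred_non_fatigued", "pred_fatigued"],
    )
    p = outdir / "confusion_matrix.csv"
    cm.to_csv(p)
    written.append(p)

    p = outdir / "per_subject_accuracy.csv"
    pd.DataFrame(
        sorted(report.per_subject_accuracy.items()),
        columns=["subject_id", "accuracy"],
    ).to_csv(p, index=False)
    written.append(p)

    for i, h in enumerate(report.histories):
        tracks = {k: v for k, v in h.items() if isinstance(v, list)}
        p = outdir / f"learning_curve_fold{i:02d}.csv"
        pd.DataFrame(tracks).to_csv(p, index_label="epoch")
        written.append(p)

    for name, mat in report.attention_samples.items():
        p = outdir / f"attention_{name}.csv"
        np.savetxt(p, mat, delimiter=",")
        written.append(p)
    return written
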