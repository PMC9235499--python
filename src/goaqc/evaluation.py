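"""One-vs-all evaluation with the consistent class as negatives.

For each inconsistency type the target class is positive and *everything*
else — including consistent (CO) instances — is negative, so metrics are
not inflated by the consistent majority.  The macro average runs over the
four inconsistency types only; NA rows (the rule baseline cannot emit IM or
IG) are excluded with the divisor reduced and the row flagged.

Prediction uncertainty is the Shannon entropy (bits) of the 5-class
probability vector, bounded by log2(5) ≈ 2.32.  Thresholded F1 counts a
prediction as positive only when its entropy falls strictly below the
threshold; a correct label whose uncertainty fails the threshold is a miss
(abstention), which keeps tp+fn constant per class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import GOAInstance, INCONSISTENCY_LABELS

#: uncertainty thresholds used by the selective-prediction analysis
DEFAULT_TAU_THRESHOLDS = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.3)

#: training-set noise fractions used by the robustness experiment
DEFAULT_NOISE_FRACTIONS = (0.0, 0.10, 0.15, 0.25, 0.40, 0.60, 0.80, 1.0)


@dataclass(frozen=True)
class OvaCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class MetricRow:
    precision: float
    recall: float
    f1: float
    label: str = ""
    flagged: bool = False  # a zero-division or NA exclusion occurred


def ova_counts(
    predictions: Sequence[str], gold_labels: Sequence[str], target_class: str
) -> OvaCounts:
    """tp/fp/fn for one target class under the one-vs-all convention."""
    if len(predictions) != len(gold_labels):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(gold_labels)} gold"
        )
    tp = fp = fn = 0
    for pred, gold in zip(predictions, gold_labels):
        if pred == target_class:
            if gold == target_class:
                tp += 1
            else:
                fp += 1
        elif gold == target_class:
            fn += 1
    return OvaCounts(tp, fp, fn)


def precision_recall_f1(counts: OvaCounts, label: str = "") -> MetricRow:
    """P/R/F1 with zero divisions yielding 0 and a flag."""
    flagged = False
    if counts.tp + counts.fp:
        p = counts.tp / (counts.tp + counts.fp)
    else:
        p, flagged = 0.0, True
    if counts.tp + counts.fn:
        r = counts.tp / (counts.tp + counts.fn)
    else:
        r, flagged = 0.0, True
    if p + r:
        f1 = 2 * p * r / (p + r)
    else:
        f1, flagged = 0.0, True
    return MetricRow(p, r, f1, label=label, flagged=flagged)


def macro_average(rows: Mapping[str, MetricRow | None]) -> MetricRow:
    """Unweighted mean over the four inconsistency classes; None rows are NA."""
    if set(rows) != set(INCONSISTENCY_LABELS):
        raise ValueError(f"macro average requires exactly the classes {INCONSISTENCY_LABELS}")
    present = [r for r in rows.values() if r is not None]
    if not present:
        return MetricRow(0.0, 0.0, 0.0, label="macro", flagged=True)
    flagged = len(present) < len(rows)
    return MetricRow(
        float(np.mean([r.precision for r in present])),
        float(np.mean([r.recall for r in present])),
        float(np.mean([r.f1 for r in present])),
        label="macro",
        flagged=flagged,
    )


def entropy(probs: Sequence[float]) -> float:
    """Shannon entropy in bits of a probability vector; 0·log2(0) := 0."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"not a probability simplex: {p}")
    p = np.clip(p, 0.0, 1.0)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()) + 0.0  # normalize -0.0


def thresholded_f1(
    predictions: Sequence[tuple[str, float]],
    gold_labels: Sequence[str],
    target_class: str,
    thresholds: Iterable[float] = DEFAULT_TAU_THRESHOLDS,
) -> dict[float, MetricRow]:
    """F1 per uncertainty threshold t, counting positives only when tau < t.

    A prediction with the target label but tau >= t is an abstention and
    counts as a miss (fn), so tp+fn equals the class support at every t.
    """
    if len(predictions) != len(gold_labels):
        raise ValueError("length mismatch between predictions and gold labels")
    out: dict[float, MetricRow] = {}
    for t in thresholds:
        tp = fp = fn = 0
        for (pred, tau), gold in zip(predictions, gold_labels):
            accepted = pred == target_class and tau < t
            if accepted and gold == target_class:
                tp += 1
            elif accepted:
                fp += 1
            elif gold == target_class:
                fn += 1
        out[t] = precision_recall_f1(OvaCounts(tp, fp, fn), label=target_class)
    return out


def metrics_table(
    predictions: Sequence[str], gold_labels: Sequence[str], **extra
) -> pd.DataFrame:
    """Per-inconsistency-class P/R/F1 plus the macro row, as a tidy table."""
    rows = {}
    records = []
    for cls in INCONSISTENCY_LABELS:
        row = precision_recall_f1(ova_counts(predictions, gold_labels, cls), label=cls)
        rows[cls] = row
        records.append({"class": cls, "precision": row.precision, "recall": row.recall,
                        "f1": row.f1, **extra})
    macro = macro_average(rows)
    records.append({"class": "macro", "precision": macro.precision,
                    "recall": macro.recall, "f1": macro.f1, **extra})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# experiment harnesses
# ---------------------------------------------------------------------------
# A train_fn is any callable (train, dev, seed) -> predict_fn, where
# predict_fn maps a list of instances to a list of predicted labels (or
# (label, tau) pairs; only the label is used here).


def _labels_of(preds: Sequence) -> list[str]:
    return [p[0] if isinstance(p, tuple) else getattr(p, "label", p) for p in preds]


def run_noise_experiment(
    train: list[GOAInstance],
    dev: list[GOAInstance],
    test: list[GOAInstance],
    fractions: Iterable[float],
    train_fn: Callable,
    seed: int = 0,
) -> pd.DataFrame:
    """One model per noise fraction, all evaluated on the same clean test set."""
    gold = [i.label for i in test]
    frames = []
    for k, fraction in enumerate(fractions):
        rng = np.random.default_rng([seed, 17, k])
        noisy = inject_noise(train, fraction, rng)
        predict_fn = train_fn(noisy, dev, seed)
        preds = _labels_of(predict_fn(test))
        frames.append(metrics_table(preds, gold, fraction=fraction))
    return pd.concat(frames, ignore_index=True)


def run_ood_experiment(
    id_train: list[GOAInstance],
    ood_train: list[GOAInstance],
    dev: list[GOAInstance],
    test: list[GOAInstance],
    train_fn: Callable,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired in-distribution vs out-of-distribution training, shared test set."""
    gold = [i.label for i in test]
    frames = []
    for condition, pool in (("ID", id_train), ("OOD", ood_train)):
        predict_fn = train_fn(pool, dev, seed)
        preds = _labels_of(predict_fn(test))
        frames.append(metrics_table(preds, gold, condition=condition))
    return pd.concat(frames, ignore_index=True)


def inject_noise(train, fraction, rng):
    from .synthesis import inject_label_noise

    return inject_label_noise(train, fraction, rng)
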