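"""Subject-wise evaluation: folds, per-class metrics, mode comparison.

Splits assign whole subjects to train or test, guarding against identity
leakage; the reference protocol enumerates all C(5,3)=10 ways of picking
3 training subjects out of 5.  Metrics are per-class precision, recall
and F1 with unweighted (macro) averages; zero-denominator cases are
defined as 0 and flagged.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .segmentation_io import ScanLocation, ValidationError


@dataclass
class EvaluationReport:
    """Per-class precision/recall/F1, macro averages, confusion matrix."""

    labels: list  # class order of the table and matrix rows/cols
    per_class: pd.DataFrame  # columns: label, precision, recall, f1, support, zero_division_flag
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    fold_id: Optional[int] = None
    seed: Optional[int] = None
    mode: Optional[str] = None  # hierarchical | non_hierarchical | substep1 | substep2

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": [str(l) for l in self.labels],
                "per_class": self.per_class.to_dict(orient="records"),
                "macro_precision": self.macro_precision,
                "macro_recall": self.macro_recall,
                "macro_f1": self.macro_f1,
                "confusion": self.confusion.tolist(),
                "fold_id": self.fold_id,
                "seed": self.seed,
                "mode": self.mode,
            },
            indent=2,
            sort_keys=True,
        )

    def to_csv(self, path) -> Path:
        self.per_class.to_csv(path, index=False)
        return Path(path)


def subject_folds(subjects: Sequence[str], train_k: int = 3) -> list[tuple[tuple, tuple]]:
    """All C(n, k) (train-subjects, test-subjects) splits, in the
    deterministic order of itertools.combinations over the input order."""
    subjects = list(subjects)
    if len(set(subjects)) != len(subjects):
        raise ValidationError("subjects must be distinct")
    if train_k >= len(subjects) or train_k < 1:
        raise ValidationError(
            f"train_k must satisfy 1 <= train_k < n_subjects; got k={train_k}, n={len(subjects)}"
        )
    folds = []
    for train in itertools.combinations(subjects, train_k):
        test = tuple(s for s in subjects if s not in train)
        folds.append((train, test))
    return folds


def score(
    predictions: Sequence[tuple],
    fold_id: Optional[int] = None,
    seed: Optional[int] = None,
    mode: Optional[str] = None,
) -> EvaluationReport:
    """Score (true_label, predicted_label) pairs.

    Labels must be valid scan-location codes.  Classes with zero support
    are absent from the per-class table; a zero-denominator precision or
    recall is reported as 0 with ``zero_division_flag`` set.
    """
    if not predictions:
        raise ValidationError("predictions must be non-empty")
    valid = {l.value for l in ScanLocation}
    y_true, y_pred = [], []
    for true, pred in predictions:
        ts = true.value if isinstance(true, ScanLocation) else str(true)
        ps = pred.value if isinstance(pred, ScanLocation) else str(pred)
        if ts not in valid or ps not in valid:
            raise ValidationError(f"unknown label in predictions: {true!r} / {pred!r}")
        y_true.append(ts)
        y_pred.append(ps)

    order = [l.value for l in ScanLocation if l.value in set(y_true) | set(y_pred)]
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=order, zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=order)
    pred_counts = cm.sum(axis=0)
    rows = []
    keep = []
    for i, lab in enumerate(order):
        if support[i] == 0:
            continue  # class absent from the ground truth
        keep.append(i)
        rows.append(
            {
                "label": lab,
                "precision": float(prec[i]),
                "recall": float(rec[i]),
                "f1": float(f1[i]),
                "support": int(support[i]),
                "zero_division_flag": bool(pred_counts[i] == 0),
            }
        )
    per_class = pd.DataFrame(rows)
    return EvaluationReport(
        labels=order,
        per_class=per_class,
        macro_precision=float(np.mean([r["precision"] for r in rows])),
        macro_recall=float(np.mean([r["recall"] for r in rows])),
        macro_f1=float(np.mean([r["f1"] for r in rows])),
        confusion=cm,
        fold_id=fold_id,
        seed=seed,
        mode=mode,
    )


def compare_modes(
    run_mode: Callable[[str, tuple, tuple, int], Sequence[tuple]],
    subjects: Sequence[str],
    modes: Sequence[str],
    seeds: Sequence[int],
    train_k: int = 3,
    folds: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Run each mode over folds x seeds and tabulate macro-F1.

    ``run_mode(mode, train_subjects, test_subjects, seed)`` returns
    (true, predicted) pairs for the fold; a failure is recorded for that
    cell and the comparison proceeds.  ``folds`` optionally restricts to
    a subset of fold indices.  The returned table has one row per mode
    with mean +/- sd macro-F1 and, for consecutive mode pairs, a
    directional verdict column.
    """
    if len(modes) < 2:
        raise ValidationError("need at least 2 modes to compare")
    all_folds = subject_folds(subjects, train_k)
    fold_ids = list(folds) if folds is not None else list(range(len(all_folds)))
    per_mode: dict[str, list] = {m: [] for m in modes}
    failures: dict[str, int] = {m: 0 for m in modes}
    for mode in modes:
        for seed in seeds:
            for fi in fold_ids:
                train, test = all_folds[fi]
                try:
                    preds = run_mode(mode, train, test, seed)
                    rep = score(preds, fold_id=fi, seed=seed, mode=mode)
                    per_mode[mode].append(rep.macro_f1)
                except Exception:
                    failures[mode] += 1
    rows = []
    for mode in modes:
        vals = np.asarray(per_mode[mode], dtype=float)
        rows.append(
            {
                "mode": mode,
                "n_runs": len(vals),
                "n_failures": failures[mode],
                "macro_f1_mean": float(vals.mean()) if len(vals) else np.nan,
                "macro_f1_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            }
        )
    table = pd.DataFrame(rows)
    verdicts = []
    for i in range(len(modes)):
        if i == 0:
            verdicts.append("")
        else:
            a, b = table.loc[i - 1, "macro_f1_mean"], table.loc[i, "macro_f1_mean"]
            verdicts.append(f"{modes[i-1]} {'>=' if a >= b else '<'} {modes[i]}")
    table["vs_previous"] = verdicts
    return table


def macro_f1_per_seed(
    run_mode: Callable[[str, tuple, tuple, int], Sequence[tuple]],
    subjects: Sequence[str],
    mode: str,
    seeds: Sequence[int],
    train_k: int = 3,
    folds: Optional[Sequence[int]] = None,
) -> list[float]:
    """Per-seed macro-F1 (averaged over the selected folds) for one mode."""
    all_folds = subject_folds(subjects, train_k)
    fold_ids = list(folds) if folds is not None else list(range(len(all_folds)))
    out = []
    for seed in seeds:
        vals = []
        for fi in fold_ids:
            train, test = all_folds[fi]
            preds = run_mode(mode, train, test, seed)
            vals.append(score(preds).macro_f1)
        out.append(float(np.mean(vals)))
    return out
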