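"""Cross-validated benchmarking of the assessment pipeline.

Three validation schemes over a labeled repetition corpus:

* ``kfold_10`` -- stratified 10-fold CV over all repetitions;
* ``within_subject`` -- stratified 5-fold CV inside each subject, every
  (subject, fold) pair contributing one fold to the average;
* ``leave_one_subject_out`` -- each fold withholds one subject entirely,
  measuring cross-person generalization.

Two metrics per fold, reported in percent with fold-level standard
deviations:

* type-classification accuracy -- fraction of validation repetitions whose
  exercise type is predicted correctly;
* improper-identification accuracy -- fraction whose (exercise type, posture
  error set) pair exactly matches ground truth; a repetition with a
  misclassified type counts as wrong regardless of its error flags.

The exercise classifier is retrained per fold; the posture rules use fixed
clinical tolerances and need no training.
"""

from __future__ import annotations

import dataclasses
import logging
import time

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import classifier as clf
from .config import PipelineConfig
from .features import FeatureVector, build_feature_vector
from .kinematics import AngleMeasures, angle_measures
from .preprocess import preprocess_session
from .rules import assess_repetition
from .segmentation import segment_session
from .signal_io import Session

logger = logging.getLogger(__name__)

SCHEMES = ("kfold_10", "within_subject", "leave_one_subject_out")

_SCHEME_ALIASES = {
    "kfold": "kfold_10",
    "kfold_10": "kfold_10",
    "within": "within_subject",
    "within_subject": "within_subject",
    "loso": "leave_one_subject_out",
    "leave_one_subject_out": "leave_one_subject_out",
}


@dataclasses.dataclass
class RepetitionRecord:
    """One segmented repetition with its features, measures and labels."""

    subject: str
    exercise: str
    variant: str
    true_errors: frozenset
    features: FeatureVector
    measures: AngleMeasures
    pred_errors: frozenset


@dataclasses.dataclass
class EvalReport:
    """Fold-level accuracies (percent) and the pooled confusion matrix."""

    scheme: str
    fold_type_acc: np.ndarray
    fold_improper_acc: np.ndarray
    per_exercise_type: dict[str, np.ndarray]
    per_exercise_improper: dict[str, np.ndarray]
    confusion: pd.DataFrame
    n_repetitions: int

    @property
    def type_accuracy(self) -> float:
        return float(np.mean(self.fold_type_acc))

    @property
    def type_accuracy_sd(self) -> float:
        return float(np.std(self.fold_type_acc, ddof=1)) if len(self.fold_type_acc) > 1 else 0.0

    @property
    def improper_accuracy(self) -> float:
        return float(np.mean(self.fold_improper_acc))

    @property
    def improper_accuracy_sd(self) -> float:
        return (
            float(np.std(self.fold_improper_acc, ddof=1))
            if len(self.fold_improper_acc) > 1
            else 0.0
        )


def build_records(
    sessions: list[Session], config: PipelineConfig | None = None
) -> list[RepetitionRecord]:
    """Run preprocess -> segment -> angles -> features -> rules on a corpus.

    Session-level ground-truth labels apply to every repetition segmented
    from that session.  Posture errors are assessed under the session's true
    exercise; evaluation scores a repetition's error set only when its type
    is also predicted correctly.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    records: list[RepetitionRecord] = []
    for session in sessions:
        if session.true_exercise is None:
            raise ValueError("corpus sessions must carry true_exercise labels")
        prepped = preprocess_session(session, config.filters)
        reps = segment_session(prepped, config.segmentation)
        for rep in reps:
            measures = angle_measures(prepped, rep, params=config.kinematics)
            fv = build_feature_vector(prepped, rep, measures, config.features)
            assessed = assess_repetition(session.true_exercise, measures, config.thresholds)
            records.append(
                RepetitionRecord(
                    subject=session.subject_id,
                    exercise=session.true_exercise,
                    variant=session.variant or "unknown",
                    true_errors=session.true_errors
                    if session.true_errors is not None
                    else frozenset(),
                    features=fv,
                    measures=measures,
                    pred_errors=assessed.error_set,
                )
            )
    logger.info(
        "built %d repetition records from %d sessions in %.2f s",
        len(records),
        len(sessions),
        time.perf_counter() - t0,
    )
    return records


def _folds(records: list[RepetitionRecord], scheme: str, seed: int):
    """Yield (train_idx, val_idx) index arrays for the requested scheme."""
    y = np.array([r.exercise for r in records])
    subjects = np.array([r.subject for r in records])
    idx = np.arange(len(records))
    if scheme == "kfold_10":
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        yield from skf.split(idx[:, None], y)
    elif scheme == "within_subject":
        for subject in sorted(set(subjects.tolist())):
            mask = subjects == subject
            sub_idx = idx[mask]
            skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
            for tr, va in skf.split(sub_idx[:, None], y[mask]):
                yield sub_idx[tr], sub_idx[va]
    elif scheme == "leave_one_subject_out":
        unique = sorted(set(subjects.tolist()))
        if len(unique) < 2:
            raise ValueError("leave_one_subject_out needs at least 2 subjects")
        for subject in unique:
            mask = subjects == subject
            yield idx[~mask], idx[mask]
    else:
        raise ValueError(f"unknown CV scheme '{scheme}'")


def _train_predict(
    records: list[RepetitionRecord],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    classifier: str,
    config: PipelineConfig,
    seed: int,
) -> np.ndarray:
    X_train = [records[i].features for i in train_idx]
    y_train = [records[i].exercise for i in train_idx]
    X_val = np.vstack([records[i].features.values for i in val_idx])
    if classifier == "tree":
        model = clf.train_tree(
            X_train, y_train, cv_folds=config.classifier.pruning_cv_folds, seed=seed
        )
        return model.predict(X_val)
    if classifier in ("bayes", "knn"):
        models = clf.train_baselines(X_train, y_train, k=config.classifier.knn_k)
        return models[classifier].predict(X_val)
    if classifier == "oracle":  # upper-bound reference: predicts the truth
        return np.array([records[i].exercise for i in val_idx])
    raise ValueError(f"unknown classifier '{classifier}'")


def run_cv(
    corpus,
    scheme: str = "kfold_10",
    config: PipelineConfig | None = None,
    seed: int = 0,
    classifier: str = "tree",
) -> EvalReport:
    """Cross-validate the full assessment pipeline on a labeled corpus.

    ``corpus`` is either a list of labeled :class:`Session` objects (the
    pipeline runs first) or a prebuilt list of :class:`RepetitionRecord`.
    Fold partitions are reproducible from ``seed``; validation folds are
    disjoint and exhaustive.
    """
    scheme = _SCHEME_ALIASES.get(scheme, scheme)
    config = config or PipelineConfig()
    if corpus and isinstance(corpus[0], Session):
        records = build_records(corpus, config)
    else:
        records = list(corpus)
    if not records:
        raise ValueError("empty corpus")

    exercises = sorted({r.exercise for r in records})
    true_type = np.array([r.exercise for r in records])
    errors_ok = np.array([r.pred_errors == r.true_errors for r in records])

    fold_type, fold_improper = [], []
    per_type = {e: [] for e in exercises}
    per_improper = {e: [] for e in exercises}
    confusion = pd.DataFrame(
        0, index=list(exercises), columns=list(exercises), dtype=int
    )
    t0 = time.perf_counter()
    for tr, va in _folds(records, scheme, seed):
        pred = _train_predict(records, tr, va, classifier, config, seed)
        truth = true_type[va]
        type_hit = pred == truth
        improper_hit = type_hit & errors_ok[va]
        fold_type.append(100.0 * np.mean(type_hit))
        fold_improper.append(100.0 * np.mean(improper_hit))
        for e in exercises:
            mask = truth == e
            per_type[e].append(100.0 * np.mean(type_hit[mask]) if mask.any() else np.nan)
            per_improper[e].append(
                100.0 * np.mean(improper_hit[mask]) if mask.any() else np.nan
            )
        for t, p in zip(truth, pred):
            confusion.loc[t, p] += 1
    logger.info(
        "%s CV (%s classifier): %d folds in %.2f s",
        scheme,
        classifier,
        len(fold_type),
        time.perf_counter() - t0,
    )
    return EvalReport(
        scheme=scheme,
        fold_type_acc=np.array(fold_type),
        fold_improper_acc=np.array(fold_improper),
        per_exercise_type={e: np.array(v) for e, v in per_type.items()},
        per_exercise_improper={e: np.array(v) for e, v in per_improper.items()},
        confusion=confusion,
        n_repetitions=len(records),
    )


def summarize(reports: list[EvalReport]) -> pd.DataFrame:
    """Per-exercise accuracy table (rows SAE/SLR/QSM/All per scheme).

    Returns a machine-readable DataFrame; :func:`format_report` renders the
    human-readable text.  ``DataFrame.to_csv`` round-trips the numbers.
    """
    if not reports:
        raise ValueError("summarize needs at least one report")
    rows = []
    for report in reports:
        for exercise in list(report.per_exercise_type) + ["All"]:
            if exercise == "All":
                t, imp = report.fold_type_acc, report.fold_improper_acc
            else:
                t = report.per_exercise_type[exercise]
                imp = report.per_exercise_improper[exercise]
            rows.append(
                {
                    "scheme": report.scheme,
                    "exercise": exercise,
                    "type_acc_mean": float(np.nanmean(t)),
                    "type_acc_sd": float(np.nanstd(t, ddof=1)) if len(t) > 1 else 0.0,
                    "improper_acc_mean": float(np.nanmean(imp)),
                    "improper_acc_sd": float(np.nanstd(imp, ddof=1)) if len(imp) > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def format_report(summary: pd.DataFrame) -> str:
    """Human-readable accuracy tables, one block per CV scheme."""
    lines = []
    for scheme, block in summary.groupby("scheme", sort=False):
        lines.append(f"== {scheme} ==")
        lines.append(
            f"{'Exercise':<10}{'Type Classification Accuracy':>32}"
            f"{'Improper Identification Accuracy':>36}"
        )
        for _, row in block.iterrows():
            lines.append(
                f"{row['exercise']:<10}"
                f"{row['type_acc_mean']:>24.2f}% ± {row['type_acc_sd']:.2f}%"
                f"{row['improper_acc_mean']:>26.2f}% ± {row['improper_acc_sd']:.2f}%"
            )
        lines.append("")
    return "\n".join(lines)
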