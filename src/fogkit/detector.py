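"""Cost-weighted random-forest FOG classifier and its evaluation protocol.

FOG detection from windowed IMU features is a heavily imbalanced problem —
normal walking vastly outweighs freezing — and a missed freeze is far more
costly than a spurious cue.  The classifier is therefore a small random
forest (25 trees, maximum depth 15, cost-complexity pruning enabled) whose
loss weights false negatives 10x heavier than false positives, implemented
as class weights (the expected-loss-equivalent formulation).

Evaluation follows leave-one-subject-out (LOSO) cross-validation: all
windows of one wearer are held out per fold, preventing leakage between
neighbouring windows of the same recording.  Window-level sensitivity and
specificity are reported per subject and averaged; the ROC curve is obtained
by sweeping the probability threshold over the pooled held-out predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import FogLabel, ValidationError
from .features import FEATURE_COLUMNS, FeatureSet


@dataclass(frozen=True)
class ForestConfig:
    """Random-forest configuration.

    ``max_depth`` reads the forest's "maximum size" as a depth cap — the
    natural size limit for fast binary trees on an embedded target.  The 10x
    false-negative cost enters as the FOG class weight.  ``ccp_alpha`` > 0
    enables minimal cost-complexity pruning.
    """

    n_trees: int = 25
    max_depth: int = 15
    ccp_alpha: float = 1e-4
    false_negative_cost_ratio: float = 10.0
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if self.false_negative_cost_ratio <= 0:
            raise ValidationError("false_negative_cost_ratio must be > 0")
        if not (0.0 <= self.decision_threshold <= 1.0):
            raise ValidationError("decision_threshold must lie in [0, 1]")


@dataclass
class FogPredictionTrack:
    """Per-window FOG probabilities and thresholded labels."""

    window_end_times: np.ndarray
    probabilities: np.ndarray
    labels_pred: np.ndarray  # bool: True = FOG
    labels_true: np.ndarray | None = None  # bool, None if unlabelled
    threshold: float = 0.5

    def __len__(self) -> int:
        return int(self.window_end_times.shape[0])


@dataclass
class SubjectScore:
    subject_id: str
    sensitivity: float | None  # None = undefined (no FOG windows held out)
    specificity: float | None
    n_fog_windows: int
    n_nofog_windows: int


@dataclass
class EvaluationReport:
    """LOSO evaluation: per-subject scores, averages, pooled ROC."""

    per_subject: list[SubjectScore]
    mean_sensitivity: float | None
    mean_specificity: float | None
    roc_points: np.ndarray  # (1 - specificity, sensitivity) rows
    auc: float
    pooled: FogPredictionTrack | None = None

    def to_dict(self) -> dict:
        return {
            "per_subject": [
                {
                    "subject_id": s.subject_id,
                    "sensitivity": s.sensitivity,
                    "specificity": s.specificity,
                    "n_fog_windows": s.n_fog_windows,
                    "n_nofog_windows": s.n_nofog_windows,
                }
                for s in self.per_subject
            ],
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "auc": self.auc,
            "roc_points": np.asarray(self.roc_points).tolist(),
        }


class FogModel:
    """Trained forest plus the feature-column contract it was fitted on."""

    def __init__(
        self,
        forest: RandomForestClassifier,
        config: ForestConfig,
        columns: tuple[str, ...] = FEATURE_COLUMNS,
    ) -> None:
        self.forest = forest
        self.config = config
        self.columns = tuple(columns)

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != self.n_features:
            raise ValidationError(
                f"feature dimensionality {matrix.shape} does not match "
                f"training ({self.n_features} columns)"
            )
        proba = self.forest.predict_proba(matrix)
        fog_col = list(self.forest.classes_).index(1)
        return proba[:, fog_col]

    # -- portable JSON serialization ------------------------------------
    def to_json(self, path: str | Path) -> None:
        """Serialize the forest structure to a portable JSON file."""
        trees = []
        for est in self.forest.estimators_:
            t = est.tree_
            # per-leaf class weight fractions -> P(FOG)
            value = t.value[:, 0, :]
            norm = value.sum(axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            p = value / norm
            fog_col = list(est.classes_).index(1)
            trees.append(
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "p_fog": p[:, fog_col].tolist(),
                }
            )
        payload = {
            "format": "fogkit-forest-v1",
            "columns": list(self.columns),
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "ccp_alpha": self.config.ccp_alpha,
                "false_negative_cost_ratio":
                    self.config.false_negative_cost_ratio,
                "decision_threshold": self.config.decision_threshold,
                "seed": self.config.seed,
            },
            "trees": trees,
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "PortableForest":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "fogkit-forest-v1":
            raise ValidationError("not a fogkit forest file")
        config = ForestConfig(**payload["config"])
        return PortableForest(
            payload["trees"], config, tuple(payload["columns"])
        )


class PortableForest:
    """Forest re-loaded from JSON; predicts by explicit tree traversal."""

    def __init__(
        self, trees: list[dict], config: ForestConfig, columns: tuple[str, ...]
    ) -> None:
        self.trees = [
            {k: np.asarray(v) for k, v in t.items()} for t in trees
        ]
        self.config = config
        self.columns = columns

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != self.n_features:
            raise ValidationError("feature dimensionality mismatch")
        out = np.zeros(matrix.shape[0])
        for t in self.trees:
            node = np.zeros(matrix.shape[0], dtype=int)
            active = t["children_left"][node] != -1
            while active.any():
                idx = np.nonzero(active)[0]
                nd = node[idx]
                go_left = (
                    matrix[idx, t["feature"][nd]] <= t["threshold"][nd]
                )
                node[idx] = np.where(
                    go_left, t["children_left"][nd], t["children_right"][nd]
                )
                active[idx] = t["children_left"][node[idx]] != -1
            out += t["p_fog"][node]
        return out / len(self.trees)


def train(
    features: FeatureSet, config: ForestConfig = ForestConfig()
) -> FogModel:
    """Fit the cost-weighted forest on labelled windows.

    Unannotated windows are excluded.  Both classes must be present.
    Deterministic under a fixed ``config.seed``: rows are put into a
    canonical (lexicographic) order before fitting so the model does not
    depend on how the training windows happened to be concatenated.
    """
    keep = features.labels != int(FogLabel.UNANNOTATED)
    X = features.matrix[keep]
    y = (features.labels[keep] == int(FogLabel.FOG)).astype(int)
    order = np.lexsort(
        (y,) + tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1))
    )
    X, y = X[order], y[order]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError(
            "degenerate labels: training set contains a single class"
        )
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        ccp_alpha=config.ccp_alpha,
        class_weight={0: 1.0, 1: config.false_negative_cost_ratio},
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return FogModel(forest, config, features.columns)


def predict(
    model: FogModel | PortableForest, features: FeatureSet
) -> FogPredictionTrack:
    """Per-window FOG probability (weighted tree vote) and label track."""
    proba = model.predict_proba(features.matrix)
    thr = model.config.decision_threshold
    truth = None
    if (features.labels != int(FogLabel.UNANNOTATED)).any():
        truth = features.labels == int(FogLabel.FOG)
    return FogPredictionTrack(
        window_end_times=features.times.copy(),
        probabilities=proba,
        labels_pred=proba >= thr,
        labels_true=truth,
        threshold=thr,
    )


def _sens_spec(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float | None, float | None, int, int]:
    tp = int(np.sum(y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    spec = tn / (tn + fp) if (tn + fp) > 0 else None
    return sens, spec, tp + fn, tn + fp


def roc_curve(
    track: FogPredictionTrack,
) -> tuple[np.ndarray, float]:
    """Threshold-sweep ROC over unique probabilities, plus trapezoidal AUC.

    Points are (1 - specificity, sensitivity) and always include (0, 0)
    and (1, 1).
    """
    if track.labels_true is None:
        raise ValidationError("ROC requires ground-truth labels")
    y = np.asarray(track.labels_true, dtype=bool)
    if y.all() or not y.any():
        raise ValidationError("ROC requires both classes in the truth")
    p = np.asarray(track.probabilities, dtype=float)
    order = np.argsort(-p, kind="stable")
    y_sorted = y[order]
    p_sorted = p[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(~y_sorted)
    # keep the last index of each run of equal probabilities
    distinct = np.nonzero(np.diff(p_sorted))[0]
    idx = np.concatenate([distinct, [len(p_sorted) - 1]])
    tpr = tps[idx] / tps[-1]
    fpr = fps[idx] / fps[-1]
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    if tpr[-1] != 1.0 or fpr[-1] != 1.0:
        tpr = np.concatenate([tpr, [1.0]])
        fpr = np.concatenate([fpr, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def leave_one_subject_out(
    features_by_subject: Mapping[str, FeatureSet],
    config: ForestConfig = ForestConfig(),
) -> EvaluationReport:
    """LOSO cross-validation with per-subject sensitivity/specificity.

    Subjects for which a metric is undefined (no windows of the relevant
    class held out) are flagged ``None`` and excluded from that metric's
    average rather than zero-filled.
    """
    subjects = list(features_by_subject)
    if len(subjects) < 2:
        raise ValidationError("LOSO requires at least 2 subjects")
    scores: list[SubjectScore] = []
    pooled_p: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    pooled_t: list[np.ndarray] = []
    for held_out in subjects:
        train_parts = [
            features_by_subject[s] for s in subjects if s != held_out
        ]
        merged = FeatureSet(
            times=np.concatenate([f.times for f in train_parts]),
            matrix=np.vstack([f.matrix for f in train_parts]),
            labels=np.concatenate([f.labels for f in train_parts]),
            subject_id="train",
            columns=train_parts[0].columns,
        )
        model = train(merged, config)
        test = features_by_subject[held_out]
        annotated = test.labels != int(FogLabel.UNANNOTATED)
        track = predict(model, test)
        y = test.labels == int(FogLabel.FOG)
        sens, spec, n_fog, n_nofog = _sens_spec(
            y[annotated], track.labels_pred[annotated]
        )
        scores.append(
            SubjectScore(held_out, sens, spec, n_fog, n_nofog)
        )
        pooled_p.append(track.probabilities[annotated])
        pooled_y.append(y[annotated])
        pooled_t.append(test.times[annotated])
    sens_vals = [s.sensitivity for s in scores if s.sensitivity is not None]
    spec_vals = [s.specificity for s in scores if s.specificity is not None]
    pooled = FogPredictionTrack(
        window_end_times=np.concatenate(pooled_t),
        probabilities=np.concatenate(pooled_p),
        labels_pred=np.concatenate(pooled_p) >= config.decision_threshold,
        labels_true=np.concatenate(pooled_y),
        threshold=config.decision_threshold,
    )
    points, auc = roc_curve(pooled)
    return EvaluationReport(
        per_subject=scores,
        mean_sensitivity=float(np.mean(sens_vals)) if sens_vals else None,
        mean_specificity=float(np.mean(spec_vals)) if spec_vals else None,
        roc_points=points,
        auc=auc,
        pooled=pooled,
    )
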