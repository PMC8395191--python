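"""Cross-validated evaluation, ablations and hyper-parameter sweeps.

The evaluation unit is the balanced sample set: every known association as a
positive plus an equal number of uniformly drawn unknown pairs as negatives.
Fivefold cross-validation splits that sample set (not the node sets); for
each fold the model is retrained on the remaining samples, with the test
fold's positive edges optionally masked out of the association graph so the
encoder cannot see them (``mask_test_edges``, on by default).

AUC is the tie-aware rank statistic (area under the ROC curve) and AUPR the
step-interpolated area under the precision-recall curve; accuracy,
precision, recall and F1 use a fixed decision threshold (0.5 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .classifier import ModelState, PairSample, TrainConfig, predict, sample_negatives, train
from .containers import AssociationMatrix, SimilarityMatrix
from .encoder import EncoderConfig

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "compute_metrics",
    "cross_validate",
    "run_ablation",
    "sweep",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "precision", "recall", "f1", "auc", "aupr")


@dataclass
class FoldPlan:
    """Disjoint k-fold split over a sample list; sizes differ by at most 1."""

    k: int
    folds: list[np.ndarray]

    @classmethod
    def make(cls, n_samples: int, k: int, seed: int) -> "FoldPlan":
        if not 2 <= k <= n_samples:
            raise ValueError(f"k={k} must be between 2 and the number of samples {n_samples}")
        perm = np.random.default_rng(seed).permutation(n_samples)
        return cls(k, [np.sort(chunk) for chunk in np.array_split(perm, k)])

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train indices, test indices) for one fold."""
        test = self.folds[fold]
        train_idx = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return np.sort(train_idx), test


@dataclass
class MetricsReport:
    """Per-fold metric rows plus ROC/PR curves; averages are fold means."""

    rows: list[dict[str, float]] = field(default_factory=list)
    curves: list[dict[str, np.ndarray]] = field(default_factory=list)

    def add(self, row: dict[str, float], curve: dict[str, np.ndarray] | None = None) -> None:
        self.rows.append(row)
        if curve is not None:
            self.curves.append(curve)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.loc["average"] = df.mean(axis=0)
        return df

    def mean(self, metric: str) -> float:
        vals = [r[metric] for r in self.rows if metric in r]
        return float(np.mean(vals))

    def means(self) -> dict[str, float]:
        keys: list[str] = []
        for row in self.rows:
            keys.extend(k for k in row if k not in keys)
        return {m: self.mean(m) for m in keys}


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[dict[str, float], dict[str, np.ndarray]]:
    """One metric row (accuracy/precision/recall/F1/AUC/AUPR) plus curves.

    Requires both classes to be present; AUC and AUPR are undefined on a
    single-class fold and rejected explicitly rather than returned as NaN.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"AUC/AUPR undefined: need both classes, got {n_pos} positives / {n_neg} negatives"
        )
    pred = (scores >= threshold).astype(float)
    tp = float(((pred == 1) & (labels == 1)).sum())
    fp = float(((pred == 1) & (labels == 0)).sum())
    fn = float(((pred == 0) & (labels == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    row = {
        "accuracy": float((pred == labels).mean()),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }
    fpr, tpr, _ = roc_curve(labels, scores)
    prec, rec, _ = precision_recall_curve(labels, scores)
    curves = {"fpr": fpr, "tpr": tpr, "precision": prec, "recall": rec}
    return row, curves


def _balanced_samples(
    Y: AssociationMatrix, negative_ratio: float, seed: int
) -> list[PairSample]:
    positives = [PairSample(i, j, 1) for i, j in Y.positive_pairs()]
    n_neg = int(round(negative_ratio * len(positives)))
    return positives + sample_negatives(Y, n_neg, seed)


def cross_validate(
    Y: AssociationMatrix,
    similarities: dict[str, SimilarityMatrix],
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    mask_test_edges: bool = True,
    threshold: float = 0.5,
    variant: str = "full",
) -> MetricsReport:
    """Repeated k-fold cross-validation of the full training pipeline.

    Each repeat resamples the negative set, splits the balanced samples into
    k folds, retrains per fold and scores the held-out fold. The report
    holds one row per (repeat, fold); fully reproducible from ``seed``.
    """
    encoder_config = encoder_config or EncoderConfig()
    train_config = train_config or TrainConfig()
    sc, sd = similarities["SC"], similarities["SD"]
    report = MetricsReport()
    master = np.random.default_rng(seed)
    for repeat in range(repeats):
        rep_seed = int(master.integers(0, 2**31 - 1))
        samples = _balanced_samples(Y, train_config.negative_ratio, rep_seed)
        plan = FoldPlan.make(len(samples), k, rep_seed)
        for fold in range(k):
            train_idx, test_idx = plan.split(fold)
            train_samples = [samples[i] for i in train_idx]
            test_samples = [samples[i] for i in test_idx]
            test_pos = {(s.circ, s.disease) for s in test_samples if s.label == 1}
            y_train = Y.copy()
            if mask_test_edges:
                for i, j in test_pos:
                    y_train.values[i, j] = 0.0
            fold_cfg = replace(train_config, seed=rep_seed + fold)
            enc_cfg = replace(encoder_config, seed=rep_seed + fold)
            model = train(
                y_train, sc, sd, enc_cfg, fold_cfg,
                samples=train_samples, variant=variant,
            )
            scores = predict(model, [(s.circ, s.disease) for s in test_samples])
            labels = np.array([s.label for s in test_samples], dtype=float)
            if len(set(labels)) < 2:
                # single-class test fold (can happen at k near N):
                # rank metrics are undefined, keep the threshold metrics only
                pred = (scores >= threshold).astype(float)
                row, curves = {"accuracy": float((pred == labels).mean())}, None
            else:
                row, curves = compute_metrics(scores, labels, threshold)
            row["repeat"], row["fold"] = float(repeat), float(fold)
            report.add(row, curves)
            logger.info(
                "repeat %d fold %d: auc=%.4f aupr=%.4f",
                repeat, fold, row.get("auc", np.nan), row.get("aupr", np.nan),
            )
    return report


def run_ablation(
    Y: AssociationMatrix,
    similarities: dict[str, SimilarityMatrix],
    variants: tuple[str, ...] = ("full", "no_features", "no_gat", "no_nn"),
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    mask_test_edges: bool = True,
) -> dict[str, MetricsReport]:
    """Cross-validate each pipeline variant under identical seeds."""
    return {
        v: cross_validate(
            Y, similarities, encoder_config, train_config,
            k=k, repeats=repeats, seed=seed, mask_test_edges=mask_test_edges, variant=v,
        )
        for v in variants
    }


_SWEEPABLE = ("dimension", "heads", "lambda")


def sweep(
    parameter: str,
    values: list,
    Y: AssociationMatrix,
    similarities: dict[str, SimilarityMatrix],
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    k: int = 5,
    repeats: int = 1,
    seed: int = 0,
    mask_test_edges: bool = True,
) -> pd.DataFrame:
    """One cross-validation per hyper-parameter value, constant seeds.

    Invalid dimension/head combinations (F not divisible by K on hidden
    layers) are skipped with a warning. Returns a table with one row per
    valid value, columns value/auc/aupr.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {_SWEEPABLE}, got {parameter!r}")
    encoder_config = encoder_config or EncoderConfig()
    train_config = train_config or TrainConfig()
    rows = []
    for value in values:
        enc_cfg, trn_cfg = encoder_config, train_config
        try:
            if parameter == "dimension":
                enc_cfg = replace(encoder_config, F=int(value))
            elif parameter == "heads":
                enc_cfg = replace(encoder_config, K=int(value))
            else:
                trn_cfg = replace(train_config, lam=float(value))
        except ValueError as exc:
            logger.warning("skipping %s=%s: %s", parameter, value, exc)
            continue
        report = cross_validate(
            Y, similarities, enc_cfg, trn_cfg,
            k=k, repeats=repeats, seed=seed, mask_test_edges=mask_test_edges,
        )
        rows.append({"value": value, "auc": report.mean("auc"), "aupr": report.mean("aupr")})
    return pd.DataFrame(rows)
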