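"""Multinomial classification under group-aware cross-validation.

Samples drawn from the same bottle are correlated, so an honest estimate
of out-of-sample accuracy must keep whole bottles on one side of every
train/validation split.  Two schemes are provided: leave-one-group-out
(one split per bottle) and repeated group-shuffle splits (75/25 by
default, at the level of bottles).  The classifier is an L2-regularized
multinomial logistic regression on z-scored features, with the
standardization statistics estimated from the training rows of each
split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme and its parameters.

    ``test_fraction`` is a fraction of *groups* (bottles), not samples:
    group-level rounding is the only interpretation that guarantees no
    bottle ever spans both sides of a split, whatever the cohort.
    """

    scheme: str = "group_shuffle"  # "logo" | "group_shuffle"
    test_fraction: float = 0.25
    n_repeats: int = 100
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.scheme not in ("logo", "group_shuffle"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class CVResult:
    """Per-split accuracies with their mean and standard deviation."""

    split_accuracies: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    n_splits: int
    config_used: CVConfig

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "n_splits": self.n_splits,
            "config": vars(self.config_used),
        }, indent=2))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"split": np.arange(self.n_splits),
                      "accuracy": self.split_accuracies}).to_csv(path,
                                                                 index=False)


def train_classifier(X: np.ndarray, y: np.ndarray, seed: int = 0,
                     standardize: bool = True, C: float = 1.0) -> Pipeline:
    """Fit the multinomial logistic model on z-scored features.

    Standardization parameters come from ``X`` only; deterministic given
    the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to fit a classifier")
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("logreg", LogisticRegression(
        C=C, max_iter=500, random_state=seed)))
    return Pipeline(steps).fit(X, y)


def accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Fraction of correctly classified records."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return float(np.mean(y_true == y_pred))


def logo_splits(groups: Sequence) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-group-out: one split per distinct group, that group's
    samples forming the validation set."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct groups")
    splits = []
    idx = np.arange(groups.shape[0])
    for g in uniq:
        mask = groups == g
        splits.append((idx[~mask], idx[mask]))
    return splits


def group_shuffle_splits(
    groups: Sequence, cfg: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``cfg.n_repeats`` random group-level partitions.

    In each repeat, ``round(test_fraction * n_groups)`` (at least 1)
    groups form the validation side; no group ever spans both sides.
    Each repeat draws from its own substream of the master seed, so
    split r is reproducible regardless of how many repeats are run.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 4:
        raise ValueError("need at least 4 distinct groups")
    n_val = max(1, int(round(cfg.test_fraction * uniq.size)))
    if n_val >= uniq.size:
        raise ValueError("test_fraction leaves no training groups")
    idx = np.arange(groups.shape[0])
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_repeats)
    splits = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        perm = rng.permutation(uniq)
        val_groups = set(perm[:n_val])
        mask = np.isin(groups, list(val_groups))
        splits.append((idx[~mask], idx[mask]))
    return splits


def make_splits(groups: Sequence,
                cfg: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    if cfg.scheme == "logo":
        return logo_splits(groups)
    return group_shuffle_splits(groups, cfg)


def cross_validate_matrix(
    X: np.ndarray,
    y: np.ndarray,
    splits: list[tuple[np.ndarray, np.ndarray]],
    cfg: CVConfig,
) -> CVResult:
    """Score a feature matrix over precomputed splits.

    Per split: standardize on the training rows, fit, score accuracy on
    the validation rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    accs = np.empty(len(splits))
    for i, (tr, va) in enumerate(splits):
        model = train_classifier(X[tr], y[tr], seed=cfg.seed,
                                 standardize=cfg.standardize)
        accs[i] = accuracy(y[va], model.predict(X[va]))
    return CVResult(
        split_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        std_accuracy=float(np.std(accs, ddof=0)),
        n_splits=len(splits),
        config_used=cfg,
    )


def cross_validate(table, feature_subset=None,
                   cfg: CVConfig = CVConfig()) -> CVResult:
    """Cross-validate a FeatureTable on a subset of its features.

    ``feature_subset`` may be FeatureIds, rendered id strings or column
    indices; None uses every column.
    """
    cols = resolve_columns(table, feature_subset)
    if cols.size == 0:
        raise ValueError("feature subset is empty")
    splits = make_splits(table.groups, cfg)
    return cross_validate_matrix(table.values[:, cols], table.labels,
                                 splits, cfg)


def resolve_columns(table, feature_subset) -> np.ndarray:
    """Map a subset spec (ids, strings, or indices) onto column indices."""
    if feature_subset is None:
        return np.arange(table.n_features)
    subset = list(feature_subset)
    if len(subset) == 0:
        return np.asarray([], dtype=int)
    if isinstance(subset[0], (int, np.integer)):
        return np.asarray(subset, dtype=int)
    rendered = {fid.render() if hasattr(fid, "render") else str(fid)
                for fid in subset}
    pos = {s: j for j, s in enumerate(table.id_strings())}
    missing = rendered - set(pos)
    if missing:
        raise KeyError(f"features not in table: {sorted(missing)[:3]} ...")
    return np.asarray(sorted(pos[s] for s in rendered), dtype=int)
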