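"""Feature selection: recursive forward wrapper and univariate filters.

The wrapper grows a feature set greedily: step 1 cross-validates a model
on every single feature and keeps the best; step k+1 tries every
remaining feature appended to the chosen set and keeps the best
extension.  Candidate subsets are scored with the same group-aware
cross-validation used for final evaluation, on splits drawn once per run
so all candidates in a run face identical folds; ties are broken by
lexicographic feature id, so run-to-run variability comes only from the
split seed.

Three univariate filter rankings are provided for comparison: Fisher
score (between- over within-class variance), plug-in mutual information
on quantile-binned values (in bits), and multi-class ReliefF with
nearest hits and prior-weighted nearest misses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import FeatureId, FeatureTable
from .model_eval import CVConfig, CVResult, accuracy, make_splits


@dataclass
class SelectionTrace:
    """Greedy selection path with per-step cross-validated accuracy."""

    ordered_features: list[FeatureId]
    step_mean_accuracy: np.ndarray
    step_std_accuracy: np.ndarray
    cv_config_used: CVConfig
    seed: int

    def __len__(self) -> int:
        return len(self.ordered_features)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(1, len(self) + 1),
            "feature": [f.render() for f in self.ordered_features],
            "mean_accuracy": self.step_mean_accuracy,
            "std_accuracy": self.step_std_accuracy,
        })


@dataclass
class FilterRanking:
    """Per-feature scores of one filter method, highest first."""

    method: str  # "MI" | "Fisher" | "ReliefF"
    scores: np.ndarray
    ids: list[FeatureId]

    def __post_init__(self) -> None:
        if len(self.ids) != self.scores.shape[0]:
            raise ValueError("scores and ids length mismatch")
        # descending score, ties broken by rendered id string
        order = sorted(range(len(self.ids)),
                       key=lambda j: (-self.scores[j], self.ids[j].render()))
        self.ranked_order = np.asarray(order, dtype=int)

    @property
    def ranked_ids(self) -> list[FeatureId]:
        return [self.ids[j] for j in self.ranked_order]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.ids) + 1),
            "feature": [f.render() for f in self.ranked_ids],
            "score": self.scores[self.ranked_order],
        })


def _standardized_folds(X, y, splits, standardize):
    """Per split, z-score all columns on train statistics once.

    Candidate subsets then reuse column slices, which is identical to
    standardizing each subset separately (z-scoring is columnwise).
    """
    folds = []
    for tr, va in splits:
        Xtr, Xva = X[tr], X[va]
        if standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0)
            sd = np.where(sd > 0, sd, 1.0)
            Xtr = (Xtr - mu) / sd
            Xva = (Xva - mu) / sd
        folds.append((Xtr, y[tr], Xva, y[va]))
    return folds


def _score_subset(folds, cols, seed) -> tuple[float, float]:
    accs = np.empty(len(folds))
    for i, (Xtr, ytr, Xva, yva) in enumerate(folds):
        clf = LogisticRegression(C=1.0, max_iter=500, random_state=seed)
        clf.fit(Xtr[:, cols], ytr)
        accs[i] = accuracy(yva, clf.predict(Xva[:, cols]))
    return float(np.mean(accs)), float(np.std(accs, ddof=0))


def forward_select(table: FeatureTable, max_k: int,
                   cv_cfg: CVConfig = CVConfig(n_repeats=25),
                   seed: int | None = None) -> SelectionTrace:
    """Recursive forward selection of up to ``max_k`` features.

    ``seed`` overrides ``cv_cfg.seed`` for the split stream.  Candidates
    are visited in lexicographic id order and only a strictly better
    mean accuracy displaces the incumbent, so ties resolve to the
    earliest id.
    """
    if max_k > table.n_features:
        raise ValueError("max_k exceeds the number of features")
    if seed is None:
        seed = cv_cfg.seed
    cfg = replace(cv_cfg, seed=seed)
    splits = make_splits(table.groups, cfg)
    folds = _standardized_folds(table.values, table.labels, splits,
                                cfg.standardize)
    # candidate visit order = lexicographic rendered id
    order = sorted(range(table.n_features),
                   key=lambda j: table.ids[j].render())
    chosen: list[int] = []
    means, stds = [], []
    remaining = list(order)
    for _ in range(max_k):
        best_j, best_mean, best_std = None, -np.inf, 0.0
        for j in remaining:
            m, s = _score_subset(folds, chosen + [j], cfg.seed)
            if m > best_mean:
                best_j, best_mean, best_std = j, m, s
        chosen.append(best_j)
        remaining.remove(best_j)
        means.append(best_mean)
        stds.append(best_std)
    return SelectionTrace(
        ordered_features=[table.ids[j] for j in chosen],
        step_mean_accuracy=np.asarray(means),
        step_std_accuracy=np.asarray(stds),
        cv_config_used=cfg,
        seed=seed,
    )


def repeat_selection(table: FeatureTable, max_k: int,
                     cv_cfg: CVConfig = CVConfig(n_repeats=25),
                     n_seeds: int = 5):
    """Run forward selection with ``n_seeds`` distinct split seeds.

    Correlated features mean different runs may pick different, similarly
    performing sets; the per-step accuracy curve is averaged over runs.
    Returns (mean curve, std-over-seeds curve, list of traces).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    traces = [forward_select(table, max_k, cv_cfg, seed=cv_cfg.seed + i)
              for i in range(n_seeds)]
    curves = np.vstack([t.step_mean_accuracy for t in traces])
    return curves.mean(axis=0), curves.std(axis=0, ddof=0), traces


# --- filter rankings ----------------------------------------------------

def _default_ids(n: int) -> list[FeatureId]:
    # anonymous ids for raw-matrix use; zero-padded so lexicographic
    # tie-break follows column order
    return [FeatureId(1, "G", "ads", f"f{j:05d}") for j in range(n)]


def fisher_scores(X: np.ndarray, y: Sequence,
                  ids: list[FeatureId] | None = None) -> FilterRanking:
    """Fisher score: between-class over within-class variance per feature.

    F_j = sum_c n_c (mu_cj - mu_j)^2 / sum_c n_c sigma^2_cj with class
    sample variances (n_c - 1 denominator); a zero denominator gives 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    mu = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[y == c]
        n_c = Xc.shape[0]
        between += n_c * (Xc.mean(axis=0) - mu) ** 2
        if n_c > 1:
            within += n_c * Xc.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(within > 0, between / within, 0.0)
    if ids is None:
        ids = _default_ids(X.shape[1])
    return FilterRanking("Fisher", scores, ids)


def mutual_information_scores(X: np.ndarray, y: Sequence, n_bins: int = 8,
                              ids: list[FeatureId] | None = None
                              ) -> FilterRanking:
    """Plug-in mutual information (bits) after quantile binning.

    Bin edges are deterministic sample quantiles, so the estimate is
    reproducible; constant features score 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    _, y_codes = np.unique(y, return_inverse=True)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        edges = np.unique(np.quantile(x, np.arange(1, n_bins) / n_bins))
        if edges.size == 0 or x.max() == x.min():
            scores[j] = 0.0
            continue
        b = np.searchsorted(edges, x, side="right")
        joint = np.zeros((edges.size + 1, y_codes.max() + 1))
        np.add.at(joint, (b, y_codes), 1.0)
        joint /= n
        px = joint.sum(axis=1, keepdims=True)
        py = joint.sum(axis=0, keepdims=True)
        nz = joint > 0
        scores[j] = float(np.sum(
            joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
    if ids is None:
        ids = _default_ids(X.shape[1])
    return FilterRanking("MI", np.maximum(scores, 0.0), ids)


def relieff_scores(X: np.ndarray, y: Sequence, k_neighbors: int = 10,
                   ids: list[FeatureId] | None = None) -> FilterRanking:
    """Multi-class ReliefF weights.

    Features are min-max scaled; distances are Manhattan.  Every
    instance is visited in order (m = n, no sampling).  For instance i
    of class c the weight update subtracts the mean feature difference
    to its k nearest hits and adds, for every other class c', the
    prior-weighted (P(c') / (1 - P(c))) mean difference to the k nearest
    misses of that class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts <= k_neighbors):
        small = classes[counts <= k_neighbors][0]
        raise ValueError(
            f"class {small!r} has <= k_neighbors={k_neighbors} members")
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    Z = (X - X.min(axis=0)) / span
    prior = {c: cnt / n for c, cnt in zip(classes, counts)}
    idx_of = {c: np.nonzero(y == c)[0] for c in classes}
    W = np.zeros(p)
    for i in range(n):
        c = y[i]
        d = np.abs(Z - Z[i]).sum(axis=1)
        # nearest hits, excluding self; stable sort keeps index-order ties
        hits = idx_of[c][idx_of[c] != i]
        hits = hits[np.argsort(d[hits], kind="stable")][:k_neighbors]
        W -= np.abs(Z[hits] - Z[i]).mean(axis=0) / n
        for c2 in classes:
            if c2 == c:
                continue
            miss = idx_of[c2]
            miss = miss[np.argsort(d[miss], kind="stable")][:k_neighbors]
            w_prior = prior[c2] / (1.0 - prior[c])
            W += w_prior * np.abs(Z[miss] - Z[i]).mean(axis=0) / n
    if ids is None:
        ids = _default_ids(p)
    return FilterRanking("ReliefF", W, ids)


def rank_features(table: FeatureTable, method: str,
                  **kwargs) -> FilterRanking:
    """Rank a FeatureTable's columns by one of the filter methods."""
    fns = {"mi": mutual_information_scores,
           "fisher": fisher_scores,
           "relieff": relieff_scores}
    key = method.lower()
    if key not in fns:
        raise ValueError(f"unknown filter method {method!r}")
    return fns[key](table.values, table.labels, ids=table.ids, **kwargs)


def filter_select(ranking: FilterRanking, k: int) -> list[FeatureId]:
    """Top-k features of a ranking (a prefix of ``ranked_ids``)."""
    if k > len(ranking.ids):
        raise ValueError("k exceeds the number of ranked features")
    return ranking.ranked_ids[:k]
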