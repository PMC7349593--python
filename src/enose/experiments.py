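"""Sensor-array reduction and feature-source experiments.

Reproducible harness runs over a feature table: cross-validation of
every nonempty sensor subset (63 combinations), forward selection
restricted to single sensors or to feature sources (conductance-only,
resistance-only, adsorption-only), wrapper-versus-filter comparisons on
a grid of feature counts, a 2-D PCA view of selected features, and a
full-study driver that writes CSV/JSON/plot outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .curves import N_SENSORS, SEGMENTS, SIGNALS
from .features import FeatureTable, build_feature_table
from .model_eval import CVConfig, CVResult, cross_validate
from .selection import (FilterRanking, SelectionTrace, filter_select,
                        forward_select, rank_features, repeat_selection)
from . import synthetic

logger = logging.getLogger(__name__)


@dataclass
class SubsetResult:
    """Cross-validated accuracy of one sensor subset."""

    sensor_subset: tuple[int, ...]
    n_features_used: int
    mean_accuracy: float
    std_accuracy: float


#: feature-source restrictions: name -> (signals, segments)
SOURCE_FILTERS = {
    "ALL": (("G", "R"), ("ads", "des", "full")),
    "ALL-G": (("G",), ("ads", "des", "full")),
    "ALL-R": (("R",), ("ads", "des", "full")),
    "ON": (("G", "R"), ("ads",)),
    "ON-G": (("G",), ("ads",)),
    "ON-R": (("R",), ("ads",)),
}


@dataclass(frozen=True)
class SourceFilter:
    """Named restriction of the feature catalogue by signal and segment.

    ``ALL`` keeps everything; the ``-G``/``-R`` suffix keeps only
    conductance or resistance features; the ``ON`` prefix keeps only
    features from the gas adsorption ("on") part of the response.
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in SOURCE_FILTERS:
            raise ValueError(f"unknown source filter {self.name!r}; "
                             f"choose from {sorted(SOURCE_FILTERS)}")

    @property
    def signals(self) -> tuple[str, ...]:
        return SOURCE_FILTERS[self.name][0]

    @property
    def segments(self) -> tuple[str, ...]:
        return SOURCE_FILTERS[self.name][1]


def sensor_subset_experiment(
    table: FeatureTable, cv_cfg: CVConfig = CVConfig()
) -> list[SubsetResult]:
    """Cross-validate every nonempty subset of the six sensors (63 runs),
    using all feature columns of the chosen sensors."""
    sensors_present = sorted({fid.sensor for fid in table.ids})
    if sensors_present != list(range(1, N_SENSORS + 1)):
        raise ValueError("sensor subset experiment needs the full "
                         "6-sensor table")
    results = []
    for size in range(1, N_SENSORS + 1):
        for combo in itertools.combinations(range(1, N_SENSORS + 1), size):
            cols = table.column_indices(sensors=combo)
            res = cross_validate(table, cols, cv_cfg)
            results.append(SubsetResult(
                sensor_subset=combo,
                n_features_used=cols.size,
                mean_accuracy=res.mean_accuracy,
                std_accuracy=res.std_accuracy,
            ))
    return results


def best_per_size(results: Sequence[SubsetResult]) -> list[SubsetResult]:
    """The best-accuracy subset at each subset size (1..6)."""
    best: dict[int, SubsetResult] = {}
    for r in results:
        k = len(r.sensor_subset)
        if k not in best or r.mean_accuracy > best[k].mean_accuracy:
            best[k] = r
    return [best[k] for k in sorted(best)]


def source_restricted_selection(
    table: FeatureTable,
    source: SourceFilter,
    sensors: Sequence[int] | None = None,
    max_k: int = 15,
    cv_cfg: CVConfig = CVConfig(n_repeats=25),
) -> SelectionTrace:
    """Forward selection on the columns allowed by a source filter."""
    sub = table.restrict(sensors=sensors, signals=source.signals,
                         segments=source.segments)
    if sub.n_features == 0:
        raise ValueError(f"restriction {source.name} leaves no features")
    if sub.n_features < max_k:
        raise ValueError(f"restriction leaves {sub.n_features} features, "
                         f"fewer than max_k={max_k}")
    return forward_select(sub, max_k, cv_cfg)


def single_sensor_sweep(
    table: FeatureTable,
    max_k: int = 15,
    cv_cfg: CVConfig = CVConfig(n_repeats=25),
) -> list[SelectionTrace]:
    """Forward selection restricted to each sensor's features in turn."""
    traces = []
    for s in range(1, N_SENSORS + 1):
        sub = table.restrict(sensors=[s])
        traces.append(forward_select(sub, max_k, cv_cfg))
    return traces


def accuracy_at(trace: SelectionTrace, ks: Sequence[int] = (5, 10, 15)
                ) -> dict[int, float]:
    """Trace accuracy at the given feature counts (k <= trace length)."""
    return {k: float(trace.step_mean_accuracy[k - 1]) for k in ks
            if k <= len(trace)}


def wrapper_vs_filter_experiment(
    table: FeatureTable,
    k_grid: Sequence[int],
    cv_cfg: CVConfig = CVConfig(n_repeats=25),
    wrapper_trace: SelectionTrace | None = None,
) -> pd.DataFrame:
    """Accuracy of top-k models under each selection method.

    For every k in ``k_grid``: the first k wrapper-selected features and
    the top k of each filter ranking (MI, Fisher, ReliefF) are
    cross-validated with the same scheme.  Returns a long-format frame
    with one row per (method, k).
    """
    k_grid = sorted(k_grid)
    if k_grid[0] < 1 or k_grid[-1] > table.n_features:
        raise ValueError("k_grid out of range")
    if wrapper_trace is None:
        wrapper_trace = forward_select(table, k_grid[-1], cv_cfg)
    # ReliefF needs k hits within the smallest class
    min_class = int(np.unique(table.labels, return_counts=True)[1].min())
    relief_k = min(10, min_class - 1)
    rankings = {
        "mi": rank_features(table, "mi"),
        "fisher": rank_features(table, "fisher"),
        "relieff": rank_features(table, "relieff", k_neighbors=relief_k),
    }
    rows = []
    for k in k_grid:
        subsets = {"RFS": wrapper_trace.ordered_features[:k]}
        for m, rk in rankings.items():
            subsets[{"mi": "MI", "fisher": "FS", "relieff": "RS"}[m]] = \
                filter_select(rk, k)
        for method, feats in subsets.items():
            res = cross_validate(table, feats, cv_cfg)
            rows.append({"method": method, "k": k,
                         "mean_accuracy": res.mean_accuracy,
                         "std_accuracy": res.std_accuracy})
    return pd.DataFrame(rows)


def pca_view(table: FeatureTable, feature_subset,
             n_components: int = 2) -> np.ndarray:
    """Project z-scored selected features onto the leading principal axes
    (for plotting sample clusters by class)."""
    from .model_eval import resolve_columns
    cols = resolve_columns(table, feature_subset)
    if cols.size < n_components:
        raise ValueError("need at least n_components features")
    Z = StandardScaler().fit_transform(table.values[:, cols])
    return PCA(n_components=n_components, random_state=0).fit_transform(Z)


def run_full_study(
    out_dir: str | Path,
    scenario: str = "default",
    seed: int = 0,
    max_k: int = 15,
    n_repeats: int = 25,
    n_seeds: int = 5,
    full_scale: bool = False,
    make_plots: bool = True,
    config=None,
) -> dict:
    """Generate data, extract features and run every experiment design.

    Writes CSV tables, a JSON summary and (optionally) PNG figures under
    ``out_dir``.  ``full_scale`` restores 100 CV repeats; ``config``
    overrides the named scenario with an explicit GeneratorConfig.
    Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = {
        "default": synthetic.default_scenario,
        "single_sensor": synthetic.single_informative_sensor_scenario,
        "desorption_only": synthetic.desorption_only_scenario,
    }
    if config is None and scenario not in scenarios:
        raise ValueError(f"stage=config: unknown scenario {scenario!r}")
    if full_scale:
        n_repeats = 100
    cfg = config if config is not None else scenarios[scenario](seed=seed)
    cfg_hash = hashlib.sha256(repr(cfg).encode()).hexdigest()[:12]
    logger.info("scenario %r seed %d config_hash %s n_repeats %d",
                scenario, seed, cfg_hash, n_repeats)
    dataset = synthetic.generate_dataset(cfg)
    table = build_feature_table(dataset)
    table.to_csv(out / "feature_table.csv")

    cv_full = CVConfig(scheme="group_shuffle", n_repeats=n_repeats,
                       seed=seed)
    cv_logo = CVConfig(scheme="logo", seed=seed)
    summary: dict = {"scenario": scenario, "seed": seed,
                     "n_samples": table.n_samples,
                     "n_features": table.n_features}

    res_shuffle = cross_validate(table, None, cv_full)
    res_logo = cross_validate(table, None, cv_logo)
    summary["all_features"] = {
        "group_shuffle": {"mean": res_shuffle.mean_accuracy,
                          "std": res_shuffle.std_accuracy},
        "logo": {"mean": res_logo.mean_accuracy,
                 "std": res_logo.std_accuracy},
    }

    subset_results = sensor_subset_experiment(table, cv_full)
    pd.DataFrame([{
        "sensors": "+".join(map(str, r.sensor_subset)),
        "n_features": r.n_features_used,
        "mean_accuracy": r.mean_accuracy,
        "std_accuracy": r.std_accuracy,
    } for r in subset_results]).to_csv(out / "sensor_subsets.csv",
                                       index=False)
    summary["best_subset_per_size"] = {
        len(r.sensor_subset): {"sensors": list(r.sensor_subset),
                               "mean": r.mean_accuracy}
        for r in best_per_size(subset_results)}

    sel_cfg = replace(cv_full, n_repeats=min(n_repeats, 25))
    curve_mean, curve_std, traces = repeat_selection(table, max_k, sel_cfg,
                                                     n_seeds=n_seeds)
    traces[0].to_dataframe().to_csv(out / "forward_selection_trace.csv",
                                    index=False)
    summary["forward_selection"] = {
        "accuracy_at": {k: float(curve_mean[k - 1])
                        for k in (5, 10, 15) if k <= max_k},
        "per_step_mean": curve_mean.tolist(),
    }

    sensor_traces = single_sensor_sweep(table, max_k, sel_cfg)
    pd.concat([t.to_dataframe().assign(sensor=i + 1)
               for i, t in enumerate(sensor_traces)]).to_csv(
        out / "single_sensor_traces.csv", index=False)
    summary["single_sensor_accuracy_at_10"] = {
        i + 1: accuracy_at(t).get(10) for i, t in enumerate(sensor_traces)}

    k_grid = [k for k in (1, 2, 5, 10, 15) if k <= max_k]
    wf = wrapper_vs_filter_experiment(table, k_grid, sel_cfg,
                                      wrapper_trace=traces[0])
    wf.to_csv(out / "wrapper_vs_filter.csv", index=False)
    summary["wrapper_vs_filter"] = wf.to_dict(orient="records")

    coords = pca_view(table, traces[0].ordered_features[:5])
    pd.DataFrame({"pc1": coords[:, 0], "pc2": coords[:, 1],
                  "class": table.labels}).to_csv(out / "pca_view.csv",
                                                 index=False)
    if make_plots:
        _write_plots(out, subset_results, curve_mean, wf, coords,
                     table.labels)
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=float))
    return summary


def _write_plots(out, subset_results, curve_mean, wf, coords, labels):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    best = best_per_size(subset_results)
    fig, ax = plt.subplots()
    ax.bar([len(r.sensor_subset) for r in best],
           [r.mean_accuracy for r in best],
           yerr=[r.std_accuracy for r in best])
    ax.set_xlabel("number of sensors")
    ax.set_ylabel("accuracy")
    fig.savefig(out / "fig_sensor_subsets.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(np.arange(1, curve_mean.size + 1), curve_mean, marker="o")
    ax.set_xlabel("features selected")
    ax.set_ylabel("mean accuracy")
    fig.savefig(out / "fig_selection_curve.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for method, grp in wf.groupby("method"):
        ax.plot(grp["k"], grp["mean_accuracy"], marker="o", label=method)
    ax.legend()
    ax.set_xlabel("features used")
    ax.set_ylabel("mean accuracy")
    fig.savefig(out / "fig_wrapper_vs_filter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for cls in np.unique(labels):
        m = labels == cls
        ax.scatter(coords[m, 0], coords[m, 1], label=cls, s=12)
    ax.legend()
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.savefig(out / "fig_pca.png", dpi=120)
    plt.close(fig)
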