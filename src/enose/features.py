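"""The transient-response feature catalogue.

Every measurement is reduced to a fixed table of curve-shape features.
For each of the 6 sensors, each baseline-normalized signal (R/R0 and
G/G0) and each phase segment (adsorption, desorption, and their
concatenation "full"), 23 scalar features are computed: the final and
extreme values, four moments, the curve integral, the extrema of the
exponential moving average of the increments at three smoothing
parameters, the extrema of the smoothed derivative and their times,
three fractional rise times, and the three parameters of an exponential
fit.  6 sensors x 2 signals x 3 segments x 23 types = 828 features.

All features are guaranteed finite: degenerate segments (zero range,
zero variance, failed fits) fall back to documented constants instead of
propagating NaN into model training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy.ndimage import uniform_filter1d

from .curves import (N_SENSORS, SEGMENTS, SIGNALS, CurveSegment,
                     SensorMeasurement, baseline_normalize, segment_curve)

logger = logging.getLogger(__name__)

DEFAULT_EMA_ALPHAS = (0.1, 0.01, 0.001)

#: the 23 per-segment feature types, in catalogue order
FEATURE_TYPES = (
    "final_value",
    "extremum",
    "mean",
    "std",
    "skewness",
    "kurtosis",
    "integral",
    "ema_a0.1_max",
    "ema_a0.1_min",
    "ema_a0.01_max",
    "ema_a0.01_min",
    "ema_a0.001_max",
    "ema_a0.001_min",
    "deriv_max",
    "deriv_min",
    "t_deriv_max_s",
    "t_deriv_min_s",
    "t_frac10_s",
    "t_frac25_s",
    "t_frac50_s",
    "expfit_A",
    "expfit_tau_s",
    "expfit_c",
)

N_FEATURE_TYPES = len(FEATURE_TYPES)
CROSSING_FRACTIONS = (0.10, 0.25, 0.50)
DERIV_SMOOTH_WINDOW = 15  # samples (~0.8 s at 18.5 Hz)


@dataclass(frozen=True)
class EmaParams:
    """Smoothing parameters for the exponential-moving-average features."""

    alphas: tuple[float, ...] = DEFAULT_EMA_ALPHAS

    def __post_init__(self) -> None:
        if any(not 0 < a <= 1 for a in self.alphas):
            raise ValueError("each alpha must be in (0, 1]")


class FeatureId(NamedTuple):
    sensor: int
    signal: str
    segment: str
    feature_type: str

    def render(self) -> str:
        return f"S{self.sensor}|{self.signal}|{self.segment}|{self.feature_type}"

    @classmethod
    def parse(cls, s: str) -> "FeatureId":
        sensor, sig, seg, ftype = s.split("|")
        return cls(int(sensor[1:]), sig, seg, ftype)


def full_catalogue(
    sensors: Sequence[int] = range(1, N_SENSORS + 1),
    signals: Sequence[str] = SIGNALS,
    segments: Sequence[str] = SEGMENTS,
) -> list[FeatureId]:
    """All FeatureIds for the given subsets, in lexicographic id order
    (feature types keep catalogue order within each segment)."""
    ids = []
    for s in sorted(sensors):
        for sig in sorted(signals):
            for seg in sorted(segments):
                for ft in FEATURE_TYPES:
                    ids.append(FeatureId(s, sig, seg, ft))
    return ids


def ema_transform(values: np.ndarray, dt_s: float, alpha: float) -> np.ndarray:
    """Exponential moving average of the curve increments.

    y[0] = 0; y[k] = (1 - alpha) * y[k-1] + alpha * (x[k] - x[k-1]).
    With alpha = 1 this returns the raw increments.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    dx = np.diff(x)
    y_rest = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], dx)
    return np.concatenate(([0.0], y_rest))


def _net_extremum_index(v: np.ndarray) -> int:
    """Index of the response extremum: argmax if the net excursion from
    the segment start is upward, argmin otherwise."""
    up = float(np.max(v) - v[0])
    down = float(v[0] - np.min(v))
    return int(np.argmax(v)) if up >= down else int(np.argmin(v))


def crossing_time(seg: CurveSegment, fraction: float) -> float:
    """First time (from segment start) at which the curve crosses
    ``start + fraction * range``, linearly interpolated between samples.

    ``range`` is the signed excursion from the first sample to the net
    extremum.  A zero-range (flat) segment returns the fallback 0.
    """
    v = seg.values
    t = seg.time_s - seg.time_s[0]
    i_ext = _net_extremum_index(v)
    rng = v[i_ext] - v[0]
    if rng == 0.0:
        logger.debug("zero-range segment: crossing time falls back to 0")
        return 0.0
    thr = v[0] + fraction * rng
    # work on the excursion sign so "crossing" is one-sided
    sign = 1.0 if rng > 0 else -1.0
    w = sign * v
    wt = sign * thr
    idx = np.nonzero(w >= wt)[0]
    if idx.size == 0:
        return float(t[-1])
    k = int(idx[0])
    if k == 0:
        return 0.0
    frac = (wt - w[k - 1]) / (w[k] - w[k - 1])
    return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def fit_exponential(seg: CurveSegment) -> tuple[float, float, float]:
    """Least-squares fit of ``y(t) = c + A * exp(-t / tau)``.

    Time is measured from the segment start.  tau is bounded to
    [dt, 10 x segment duration]; initialization is c = last value,
    A = first - last, tau = duration / 3.  Never raises: on solver
    failure the initialization values are returned (and logged).
    """
    v = seg.values
    if v.shape[0] < 5:
        raise ValueError("exponential fit needs at least 5 samples")
    t = seg.time_s - seg.time_s[0]
    duration = max(t[-1], seg.dt_s)
    c0 = float(v[-1])
    a0 = float(v[0] - v[-1])
    tau0 = duration / 3.0
    lo_tau, hi_tau = seg.dt_s, 10.0 * duration
    tau0 = min(max(tau0, lo_tau), hi_tau)

    def model(tt, a, tau, c):
        return c + a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, v, p0=(a0, tau0, c0),
            bounds=([-np.inf, lo_tau, -np.inf], [np.inf, hi_tau, np.inf]),
            maxfev=2000,
        )
        a, tau, c = (float(x) for x in popt)
        if not all(np.isfinite([a, tau, c])):
            raise RuntimeError("non-finite fit result")
        return a, tau, c
    except (RuntimeError, ValueError) as exc:
        logger.debug("exponential fit failed (%s); returning initialization",
                     exc)
        return a0, tau0, c0


def _smoothed_derivative(seg: CurveSegment) -> np.ndarray:
    """Central finite difference of a moving-average-smoothed segment."""
    n = seg.values.shape[0]
    w = min(DERIV_SMOOTH_WINDOW, n)
    smoothed = uniform_filter1d(seg.values, size=w, mode="nearest")
    return np.gradient(smoothed, seg.dt_s)


def segment_features(
    seg: CurveSegment, ema: EmaParams = EmaParams()
) -> np.ndarray:
    """The 23 catalogue features of one segment, in ``FEATURE_TYPES`` order."""
    v = seg.values
    t_rel = seg.time_s - seg.time_s[0]
    n = v.shape[0]
    out = np.empty(N_FEATURE_TYPES)

    out[0] = v[-1]
    out[1] = v[_net_extremum_index(v)]
    mu = float(np.mean(v))
    out[2] = mu
    sd = float(np.std(v, ddof=1))
    out[3] = sd
    if sd > 0:
        centered = v - mu
        out[4] = float(np.mean(centered**3)) / sd**3
        out[5] = float(np.mean(centered**4)) / sd**4 - 3.0
    else:  # zero-variance segment: moments are degenerate
        out[4] = 0.0
        out[5] = 0.0
    out[6] = float(np.sum(v)) * seg.dt_s  # left-Riemann: exact partition sum

    k = 7
    for alpha in ema.alphas:
        y = ema_transform(v, seg.dt_s, alpha)
        out[k] = np.max(y)
        out[k + 1] = np.min(y)
        k += 2

    dv = _smoothed_derivative(seg)
    i_max, i_min = int(np.argmax(dv)), int(np.argmin(dv))
    out[13] = dv[i_max]
    out[14] = dv[i_min]
    out[15] = t_rel[i_max]
    out[16] = t_rel[i_min]

    for j, frac in enumerate(CROSSING_FRACTIONS):
        out[17 + j] = crossing_time(seg, frac)

    out[20], out[21], out[22] = fit_exponential(seg)
    return out


def extract_features(
    meas: SensorMeasurement,
    sensors: Sequence[int] = range(1, N_SENSORS + 1),
    signals: Sequence[str] = SIGNALS,
    segments: Sequence[str] = SEGMENTS,
    ema: EmaParams = EmaParams(),
) -> tuple[np.ndarray, list[FeatureId]]:
    """Normalize, segment and featurize one measurement.

    Returns the feature vector and its ids in lexicographic FeatureId
    order.  With all sensors, both signals and all three segments the
    vector has 6 x 2 x 3 x 23 = 828 entries.
    """
    if not (sensors and signals and segments):
        raise ValueError("sensor/signal/segment subsets must be nonempty")
    norm = baseline_normalize(meas)
    ids = full_catalogue(set(sensors), set(signals), set(segments))
    values = np.empty(len(ids))
    k = 0
    for s in sorted(set(sensors)):
        for sig in sorted(set(signals)):
            for seg_name in sorted(set(segments)):
                seg = segment_curve(norm, s, sig, seg_name)
                values[k:k + N_FEATURE_TYPES] = segment_features(seg, ema)
                k += N_FEATURE_TYPES
    return values, ids


@dataclass
class FeatureTable:
    """n_samples x n_features matrix with structured column ids."""

    values: np.ndarray
    ids: list[FeatureId]
    labels: np.ndarray  # class per sample
    groups: np.ndarray  # bottle per sample
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        self.sample_ids = np.asarray(self.sample_ids)
        n, m = self.values.shape
        if len(self.ids) != m:
            raise ValueError("ids must match column count")
        if not (len(self.labels) == len(self.groups)
                == len(self.sample_ids) == n):
            raise ValueError("labels/groups/sample_ids must match row count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def id_strings(self) -> list[str]:
        return [fid.render() for fid in self.ids]

    def column_indices(
        self,
        sensors: Iterable[int] | None = None,
        signals: Iterable[str] | None = None,
        segments: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Column indices whose FeatureId matches every given restriction."""
        sensors = set(sensors) if sensors is not None else None
        signals = set(signals) if signals is not None else None
        segments = set(segments) if segments is not None else None
        keep = []
        for j, fid in enumerate(self.ids):
            if sensors is not None and fid.sensor not in sensors:
                continue
            if signals is not None and fid.signal not in signals:
                continue
            if segments is not None and fid.segment not in segments:
                continue
            keep.append(j)
        return np.asarray(keep, dtype=int)

    def restrict(self, **kwargs) -> "FeatureTable":
        """A new table keeping only the matching columns."""
        idx = self.column_indices(**kwargs)
        return FeatureTable(
            values=self.values[:, idx],
            ids=[self.ids[j] for j in idx],
            labels=self.labels,
            groups=self.groups,
            sample_ids=self.sample_ids,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.id_strings())
        df.insert(0, "bottle_id", self.groups)
        df.insert(0, "class", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        meta = ["sample_id", "class", "bottle_id"]
        feat_cols = [c for c in df.columns if c not in meta]
        return cls(
            values=df[feat_cols].to_numpy(float),
            ids=[FeatureId.parse(c) for c in feat_cols],
            labels=df["class"].to_numpy(),
            groups=df["bottle_id"].to_numpy(),
            sample_ids=df["sample_id"].to_numpy(),
        )


def build_feature_table(
    dataset,
    sensors: Sequence[int] = range(1, N_SENSORS + 1),
    signals: Sequence[str] = SIGNALS,
    segments: Sequence[str] = SEGMENTS,
    ema: EmaParams = EmaParams(),
) -> FeatureTable:
    """Extract the catalogue for every measurement of a dataset."""
    if len(dataset.measurements) == 0:
        raise ValueError("dataset is empty")
    rows = []
    ids: list[FeatureId] | None = None
    for meas in dataset.measurements:
        vec, these_ids = extract_features(meas, sensors, signals, segments,
                                          ema)
        if ids is None:
            ids = these_ids
        elif len(these_ids) != len(ids):
            raise ValueError("inconsistent measurement shapes in dataset")
        rows.append(vec)
    return FeatureTable(
        values=np.vstack(rows),
        ids=ids,
        labels=np.asarray(dataset.labels),
        groups=np.asarray(dataset.groups),
        sample_ids=np.asarray([m.sample_id for m in dataset.measurements]),
    )
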