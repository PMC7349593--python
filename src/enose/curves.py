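"""Data model, CSV I/O, baseline normalization and phase segmentation.

A measurement is one exposure cycle of a six-sensor metal-oxide (MOX)
array: a baseline phase in pure air, an adsorption phase while the odor
is pumped through the chamber, and a desorption phase while the chamber
is flushed.  The raw record is the transient resistance of each sensor
on a uniform time grid.  Downstream analysis works on the baseline-
normalized ratios R/R0 and G/G0 (G = 1/R), which make the curves unit-
and device-scale-free.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_LABELS = ("HQ", "AQ", "LQ", "Ea")
UNKNOWN_LABEL = "unknown"
N_SENSORS = 6
SIGNALS = ("G", "R")
SEGMENTS = ("ads", "des", "full")

# filename convention: CLASS_name_Bnn_Rnn, e.g. AQ_Wine02_B04_R01
_FILENAME_RE = re.compile(r"^(?P<cls>[A-Za-z]+)_[^_]+_(?P<bottle>B\d+)_R\d+")


@dataclass
class SensorMeasurement:
    """One sample's six-sensor resistance time series with metadata.

    ``phase_bounds_s`` is ``(baseline_end, adsorption_end)``; the
    desorption phase runs from ``adsorption_end`` to the last sample.
    """

    sample_id: str
    class_label: str
    bottle_id: str
    time_s: np.ndarray
    resistance: np.ndarray  # (n_points, 6), strictly positive
    sampling_rate_hz: float
    phase_bounds_s: tuple[float, float]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        if self.resistance.ndim != 2 or self.resistance.shape[1] != N_SENSORS:
            raise ValueError(
                f"resistance must be (n_points, {N_SENSORS}), "
                f"got {self.resistance.shape}"
            )
        if self.resistance.shape[0] != self.time_s.shape[0]:
            raise ValueError("time_s and resistance length mismatch")
        if not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.all(self.resistance > 0):
            raise ValueError("resistance must be strictly positive")
        b_end, a_end = self.phase_bounds_s
        if not (0 < b_end < a_end < self.time_s[-1]):
            raise ValueError("phase bounds must satisfy 0 < baseline_end "
                             "< adsorption_end < last time")
        for name, (lo, hi) in self.phase_slices().items():
            if hi - lo < 3:
                raise ValueError(f"phase {name!r} has fewer than 3 samples")

    @property
    def n_points(self) -> int:
        return self.time_s.shape[0]

    def phase_slices(self) -> dict[str, tuple[int, int]]:
        """Half-open index ranges of the three phases.

        A phase ends at the sample at or immediately before its boundary
        time; the next phase starts at the following sample.
        """
        b_end, a_end = self.phase_bounds_s
        i_base = int(np.searchsorted(self.time_s, b_end, side="right"))
        i_ads = int(np.searchsorted(self.time_s, a_end, side="right"))
        return {
            "baseline": (0, i_base),
            "ads": (i_base, i_ads),
            "des": (i_ads, self.n_points),
        }


@dataclass
class NormalizedCurves:
    """Baseline-normalized responses r = R/R0 and g = G/G0 = R0/R."""

    r: np.ndarray
    g: np.ndarray
    R0: np.ndarray
    time_s: np.ndarray
    phase_bounds_s: tuple[float, float]
    sampling_rate_hz: float

    def phase_slices(self) -> dict[str, tuple[int, int]]:
        b_end, a_end = self.phase_bounds_s
        i_base = int(np.searchsorted(self.time_s, b_end, side="right"))
        i_ads = int(np.searchsorted(self.time_s, a_end, side="right"))
        return {
            "baseline": (0, i_base),
            "ads": (i_base, i_ads),
            "des": (i_ads, self.time_s.shape[0]),
        }


@dataclass
class CurveSegment:
    """One sensor's normalized signal restricted to a measurement phase."""

    sensor_index: int  # 1-based, 1..6
    signal: str  # "R" or "G"
    segment: str  # "full" | "ads" | "des"
    values: np.ndarray
    time_s: np.ndarray
    dt_s: float

    @property
    def duration_s(self) -> float:
        return float(self.values.shape[0]) * self.dt_s


def parse_measurement_filename(name: str) -> tuple[str, str]:
    """Extract (class_label, bottle_id) from a CLASS_name_Bnn_Rnn token.

    Returns ("unknown", "unknown") when the pattern does not match.
    """
    m = _FILENAME_RE.match(Path(name).stem)
    if m is None:
        return UNKNOWN_LABEL, UNKNOWN_LABEL
    cls = m.group("cls")
    if cls not in CLASS_LABELS:
        cls = UNKNOWN_LABEL
    return cls, m.group("bottle")


def read_measurement_csv(
    path: str | Path,
    phase_bounds_s: tuple[float, float] = (10.0, 90.0),
    class_label: str | None = None,
    bottle_id: str | None = None,
    column_map: dict[str, str] | None = None,
) -> SensorMeasurement:
    """Read one measurement from a ``time_s,R1..R6`` CSV.

    Metadata is parsed from the filename (``CLASS_name_Bnn_Rnn``) unless
    given explicitly.  ``column_map`` renames foreign column layouts onto
    the expected names before validation.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed measurement file {path}: {exc}") from exc
    if column_map:
        df = df.rename(columns=column_map)
    expected = ["time_s"] + [f"R{i}" for i in range(1, N_SENSORS + 1)]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    resistance = df[[f"R{i}" for i in range(1, N_SENSORS + 1)]].to_numpy(float)
    bad = np.argwhere(~(resistance > 0))
    if bad.size:
        row, col = bad[0]
        raise ValueError(
            f"{path}: non-positive resistance at data line {row + 2} "
            f"(sensor R{col + 1})"
        )
    cls, bottle = parse_measurement_filename(path.name)
    if class_label is not None:
        cls = class_label
    if bottle_id is not None:
        bottle = bottle_id
    if cls == UNKNOWN_LABEL:
        logger.warning("no class metadata for %s; label set to %r",
                       path.name, UNKNOWN_LABEL)
    time_s = df["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(time_s)))
    return SensorMeasurement(
        sample_id=path.stem,
        class_label=cls,
        bottle_id=bottle,
        time_s=time_s,
        resistance=resistance,
        sampling_rate_hz=1.0 / dt,
        phase_bounds_s=phase_bounds_s,
    )


def write_measurement_csv(meas: SensorMeasurement, path: str | Path) -> None:
    """Write the measurement as ``time_s,R1..R6`` at full float precision."""
    path = Path(path)
    cols = {"time_s": meas.time_s}
    for i in range(N_SENSORS):
        cols[f"R{i + 1}"] = meas.resistance[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g",
                              lineterminator="\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV (sample_id, class, bottle_id, path)."""
    df = pd.read_csv(path)
    required = {"sample_id", "class", "bottle_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    return df


def baseline_normalize(meas: SensorMeasurement) -> NormalizedCurves:
    """Normalize each sensor by its baseline-phase reference.

    R0 is the median resistance over the baseline window (median rather
    than mean, for robustness to spikes); r = R/R0 and g = G/G0 = R0/R.
    """
    lo, hi = meas.phase_slices()["baseline"]
    if hi - lo < 3:
        raise ValueError("baseline phase needs at least 3 samples")
    R0 = np.median(meas.resistance[lo:hi], axis=0)
    r = meas.resistance / R0
    return NormalizedCurves(
        r=r,
        g=1.0 / r,
        R0=R0,
        time_s=meas.time_s.copy(),
        phase_bounds_s=meas.phase_bounds_s,
        sampling_rate_hz=meas.sampling_rate_hz,
    )


def segment_curve(
    norm: NormalizedCurves, sensor: int, signal: str, segment: str
) -> CurveSegment:
    """Extract one sensor's normalized signal over one phase segment.

    The baseline window is excluded from every segment; ``full`` is the
    concatenation of the adsorption and desorption segments (a disjoint
    partition of the post-baseline samples).
    """
    if not 1 <= sensor <= N_SENSORS:
        raise ValueError(f"sensor index must be 1..{N_SENSORS}, got {sensor}")
    if signal not in SIGNALS:
        raise ValueError(f"signal must be one of {SIGNALS}, got {signal!r}")
    if segment not in SEGMENTS:
        raise ValueError(f"segment must be one of {SEGMENTS}, got {segment!r}")
    sl = norm.phase_slices()
    if segment == "full":
        lo, hi = sl["ads"][0], sl["des"][1]
    else:
        lo, hi = sl[segment]
    if hi - lo < 3:
        raise ValueError(f"segment {segment!r} has fewer than 3 samples")
    series = norm.r if signal == "R" else norm.g
    return CurveSegment(
        sensor_index=sensor,
        signal=signal,
        segment=segment,
        values=series[lo:hi, sensor - 1].copy(),
        time_s=norm.time_s[lo:hi].copy(),
        dt_s=1.0 / norm.sampling_rate_hz,
    )
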