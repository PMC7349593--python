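"""Synthetic e-nose measurements with the wine-spoilage cohort structure.

The generator emulates the statistical structure of a wine-quality
sniffing experiment: four odor classes (high-, average-, low-quality
wine and diluted ethanol), a fixed number of bottles per class, 10-12
repeated sniffs per bottle, and a six-sensor MOX array made of three
same-type sensor pairs.  Kinetics are first-order exponential in
conductance: during adsorption the conductance rises as
``G0*(1 + A*(1 - exp(-(t-t_on)/tau_ads)))`` and during desorption it
relaxes back toward ``G0`` with time constant ``tau_des``, continuous at
the phase boundary.  The response amplitude ``A`` factorizes into a
sensor-instance gain, a (sensor type, class) mean amplitude, a per-bottle
concentration factor and per-sample jitter, which produces the
within-bottle correlation that group-aware validation is designed to
handle.  Stored series are resistances R = 1/G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .curves import CLASS_LABELS, N_SENSORS, SensorMeasurement

logger = logging.getLogger(__name__)

SENSOR_TYPES = ("MQ3", "MQ4", "MQ6")
#: sensor slot (1-based) -> type; same-series pairs (1,4), (2,5), (3,6)
SENSOR_TYPE_OF_SLOT = {1: "MQ3", 2: "MQ4", 3: "MQ6",
                       4: "MQ3", 5: "MQ4", 6: "MQ6"}

_AMP_FLOOR = 1e-6  # relative amplitude floor: never a degenerate curve


@dataclass
class GeneratorConfig:
    """Cohort structure, kinetic parameters and noise levels.

    ``amplitude``, ``tau_ads_s`` and ``tau_des_s`` are keyed by
    ``(sensor_type, class_label)``.  Standard deviations of the
    lognormal factors (``sensor_gain_sd``, ``bottle_effect_sd``) are on
    the log scale; ``sample_noise_sd`` and ``obs_noise_sd`` are relative
    (multiplicative Gaussian).
    """

    sampling_rate_hz: float = 18.5
    phase_durations_s: tuple[float, float, float] = (10.0, 80.0, 90.0)
    bottles_per_class: dict[str, int] = field(
        default_factory=lambda: {"HQ": 5, "AQ": 4, "LQ": 13, "Ea": 6})
    samples_per_bottle: tuple[int, int] = (10, 12)
    baseline_conductance: tuple[float, ...] = (1.0,) * N_SENSORS
    amplitude: dict[tuple[str, str], float] = field(default_factory=dict)
    tau_ads_s: dict[tuple[str, str], float] = field(default_factory=dict)
    tau_des_s: dict[tuple[str, str], float] = field(default_factory=dict)
    sensor_gain_sd: float = 0.10
    bottle_effect_sd: float = 0.15
    sample_noise_sd: float = 0.05
    kinetic_noise_sd: float = 0.08
    obs_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if any(d <= 0 for d in self.phase_durations_s):
            raise ValueError("phase durations must be positive")
        if set(self.bottles_per_class) != set(CLASS_LABELS):
            raise ValueError(
                f"bottles_per_class must cover exactly {CLASS_LABELS}")
        if any(n <= 0 for n in self.bottles_per_class.values()):
            raise ValueError("bottle counts must be positive")
        lo, hi = self.samples_per_bottle
        if not (1 <= lo <= hi):
            raise ValueError("samples_per_bottle must be a nonempty range")
        if any(g0 <= 0 for g0 in self.baseline_conductance):
            raise ValueError("baseline conductances must be positive")
        for name in ("amplitude", "tau_ads_s", "tau_des_s"):
            for key, v in getattr(self, name).items():
                if name != "amplitude" and v <= 0:
                    raise ValueError(f"{name}[{key}] must be positive")
                if name == "amplitude" and v < 0:
                    raise ValueError(f"amplitude[{key}] must be nonnegative")

    @property
    def total_bottles(self) -> int:
        return sum(self.bottles_per_class.values())

    def kinetics(self, slot: int, cls: str) -> tuple[float, float, float]:
        """(mean amplitude, tau_ads, tau_des) for a sensor slot and class."""
        st = SENSOR_TYPE_OF_SLOT[slot]
        return (self.amplitude[(st, cls)],
                self.tau_ads_s[(st, cls)],
                self.tau_des_s[(st, cls)])


@dataclass
class SyntheticDataset:
    """Generated measurements plus per-sample labels and bottle groups."""

    measurements: list[SensorMeasurement]
    labels: list[str]
    groups: list[str]
    config_used: GeneratorConfig

    def __post_init__(self) -> None:
        n = len(self.measurements)
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels/groups must match measurement count")
        seen: dict[str, str] = {}
        for g, c in zip(self.groups, self.labels):
            if seen.setdefault(g, c) != c:
                raise ValueError(f"bottle {g} maps to more than one class")

    def __len__(self) -> int:
        return len(self.measurements)


def default_scenario(seed: int = 0) -> GeneratorConfig:
    """The documented default cohort: 28 bottles, 4 classes, 6 sensors.

    Mean relative conductance rises are largest for spoiled (LQ) wine and
    smallest for high-quality wine; the AQ and Ea amplitude means are set
    within one ``bottle_effect_sd`` of each other on the log scale, so
    the two classes overlap in overall response strength and are told
    apart mainly by their transient kinetics (ethanol adsorbs and
    desorbs faster than the wine matrix).
    """
    amp: dict[tuple[str, str], float] = {}
    tau_a: dict[tuple[str, str], float] = {}
    tau_d: dict[tuple[str, str], float] = {}
    # relative conductance rise a(type, class)
    amp_table = {
        "MQ3": {"HQ": 0.80, "AQ": 2.00, "LQ": 4.00, "Ea": 2.20},
        "MQ4": {"HQ": 0.50, "AQ": 1.20, "LQ": 2.50, "Ea": 1.30},
        "MQ6": {"HQ": 0.40, "AQ": 0.90, "LQ": 1.80, "Ea": 0.95},
    }
    tau_ads_table = {
        "MQ3": {"HQ": 12.0, "AQ": 12.0, "LQ": 14.0, "Ea": 6.0},
        "MQ4": {"HQ": 15.0, "AQ": 14.0, "LQ": 16.0, "Ea": 8.0},
        "MQ6": {"HQ": 18.0, "AQ": 17.0, "LQ": 19.0, "Ea": 10.0},
    }
    tau_des_table = {
        "MQ3": {"HQ": 30.0, "AQ": 30.0, "LQ": 35.0, "Ea": 15.0},
        "MQ4": {"HQ": 35.0, "AQ": 33.0, "LQ": 40.0, "Ea": 18.0},
        "MQ6": {"HQ": 40.0, "AQ": 38.0, "LQ": 45.0, "Ea": 22.0},
    }
    for st in SENSOR_TYPES:
        for cls in CLASS_LABELS:
            amp[(st, cls)] = amp_table[st][cls]
            tau_a[(st, cls)] = tau_ads_table[st][cls]
            tau_d[(st, cls)] = tau_des_table[st][cls]
    return GeneratorConfig(amplitude=amp, tau_ads_s=tau_a, tau_des_s=tau_d,
                           seed=seed)


def single_informative_sensor_scenario(seed: int = 0) -> GeneratorConfig:
    """Only the MQ-4 pair (slots 2 and 5) separates the classes.

    MQ-3 and MQ-6 sensors respond identically to every class, so all of
    the class signal is carried by one sensor type.  Used to study how
    close a single-sensor model can come to the full array.
    """
    cfg = default_scenario(seed)
    amp = dict(cfg.amplitude)
    tau_a = dict(cfg.tau_ads_s)
    tau_d = dict(cfg.tau_des_s)
    for st in ("MQ3", "MQ6"):
        for cls in CLASS_LABELS:
            amp[(st, cls)] = 1.0
            tau_a[(st, cls)] = 12.0
            tau_d[(st, cls)] = 30.0
    return replace(cfg, amplitude=amp, tau_ads_s=tau_a, tau_des_s=tau_d)


def desorption_only_scenario(seed: int = 0) -> GeneratorConfig:
    """Classes differ only in their desorption time constants.

    Amplitudes and adsorption kinetics are identical across classes, so
    the adsorption phase carries no class information; everything is in
    how fast the sensors recover.
    """
    cfg = default_scenario(seed)
    amp: dict[tuple[str, str], float] = {}
    tau_a: dict[tuple[str, str], float] = {}
    tau_d: dict[tuple[str, str], float] = {}
    tau_des_by_class = {"HQ": 12.0, "AQ": 22.0, "LQ": 40.0, "Ea": 70.0}
    for st in SENSOR_TYPES:
        for cls in CLASS_LABELS:
            amp[(st, cls)] = 1.5
            tau_a[(st, cls)] = 10.0
            tau_d[(st, cls)] = tau_des_by_class[cls]
    return replace(cfg, amplitude=amp, tau_ads_s=tau_a, tau_des_s=tau_d)


def _time_grid(cfg: GeneratorConfig) -> tuple[np.ndarray, float, float]:
    """Uniform grid covering the three phases; returns (t, t_on, t_off)."""
    d_base, d_ads, d_des = cfg.phase_durations_s
    total = d_base + d_ads + d_des
    n = int(round(total * cfg.sampling_rate_hz))
    t = np.arange(n) / cfg.sampling_rate_hz
    return t, d_base, d_base + d_ads


def generate_measurement(
    cfg: GeneratorConfig,
    class_label: str,
    bottle_factor: float,
    rng: np.random.Generator,
    sensor_gains: np.ndarray | None = None,
    sample_id: str = "synthetic",
    bottle_id: str = "B00",
) -> SensorMeasurement:
    """Simulate one exposure cycle for all six sensors.

    ``sensor_gains`` are the per-sensor-instance multiplicative gains
    (drawn once per dataset); default 1.  Deterministic given the RNG
    state and arguments.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_label!r}")
    if bottle_factor <= 0:
        raise ValueError("bottle_factor must be positive")
    if sensor_gains is None:
        sensor_gains = np.ones(N_SENSORS)
    t, t_on, t_off = _time_grid(cfg)
    n = t.shape[0]
    G = np.empty((n, N_SENSORS))
    ads = (t >= t_on) & (t < t_off)
    des = t >= t_off
    eps_sample = rng.normal(0.0, cfg.sample_noise_sd, size=N_SENSORS) \
        if cfg.sample_noise_sd > 0 else np.zeros(N_SENSORS)
    # per-sample kinetic jitter: sniff-to-sniff variation of the reaction
    # time constants (flow, temperature, surface state)
    tau_jit = np.exp(rng.normal(0.0, cfg.kinetic_noise_sd,
                                size=(N_SENSORS, 2))) \
        if cfg.kinetic_noise_sd > 0 else np.ones((N_SENSORS, 2))
    for s in range(N_SENSORS):
        a, tau_ads, tau_des = cfg.kinetics(s + 1, class_label)
        tau_ads = tau_ads * tau_jit[s, 0]
        tau_des = tau_des * tau_jit[s, 1]
        G0 = cfg.baseline_conductance[s]
        A = sensor_gains[s] * a * bottle_factor * (1.0 + eps_sample[s])
        if A < _AMP_FLOOR:
            logger.debug("sensor %d amplitude %.3g clipped to floor", s + 1, A)
            A = _AMP_FLOOR
        g = np.full(n, G0)
        g[ads] = G0 * (1.0 + A * (1.0 - np.exp(-(t[ads] - t_on) / tau_ads)))
        # continuous at the boundary: decay starts from the level reached
        peak = G0 * (1.0 + A * (1.0 - np.exp(-(t_off - t_on) / tau_ads)))
        g[des] = G0 + (peak - G0) * np.exp(-(t[des] - t_off) / tau_des)
        G[:, s] = g
    if cfg.obs_noise_sd > 0:
        G = G * (1.0 + rng.normal(0.0, cfg.obs_noise_sd, size=G.shape))
        np.clip(G, 1e-12, None, out=G)
    return SensorMeasurement(
        sample_id=sample_id,
        class_label=class_label,
        bottle_id=bottle_id,
        time_s=t,
        resistance=1.0 / G,
        sampling_rate_hz=cfg.sampling_rate_hz,
        phase_bounds_s=(t_on, t_off),
    )


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Generate the full cohort: every bottle of every class.

    Per-sensor instance gains are drawn once per dataset; a per-bottle
    concentration factor is drawn once per bottle, so samples from the
    same bottle are correlated.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    gains = np.exp(rng.normal(0.0, cfg.sensor_gain_sd, size=N_SENSORS)) \
        if cfg.sensor_gain_sd > 0 else np.ones(N_SENSORS)
    measurements: list[SensorMeasurement] = []
    labels: list[str] = []
    groups: list[str] = []
    lo, hi = cfg.samples_per_bottle
    for cls in CLASS_LABELS:
        for b in range(cfg.bottles_per_class[cls]):
            bottle_id = f"{cls}_B{b + 1:02d}"
            factor = float(np.exp(rng.normal(0.0, cfg.bottle_effect_sd))) \
                if cfg.bottle_effect_sd > 0 else 1.0
            n_samples = int(rng.integers(lo, hi + 1))
            for r in range(n_samples):
                meas = generate_measurement(
                    cfg, cls, factor, rng, sensor_gains=gains,
                    sample_id=f"{cls}_Syn_{bottle_id[-3:]}_R{r + 1:02d}",
                    bottle_id=bottle_id,
                )
                measurements.append(meas)
                labels.append(cls)
                groups.append(bottle_id)
    return SyntheticDataset(measurements, labels, groups, cfg)


# --- config (de)serialization -------------------------------------------

def config_to_yaml(cfg: GeneratorConfig, path: str | Path) -> None:
    """Serialize a config as flat YAML (tuple keys joined with '/')."""
    d = {
        "sampling_rate_hz": cfg.sampling_rate_hz,
        "phase_durations_s": list(cfg.phase_durations_s),
        "bottles_per_class": dict(cfg.bottles_per_class),
        "samples_per_bottle": list(cfg.samples_per_bottle),
        "baseline_conductance": list(cfg.baseline_conductance),
        "amplitude": {f"{st}/{c}": v for (st, c), v in cfg.amplitude.items()},
        "tau_ads_s": {f"{st}/{c}": v for (st, c), v in cfg.tau_ads_s.items()},
        "tau_des_s": {f"{st}/{c}": v for (st, c), v in cfg.tau_des_s.items()},
        "sensor_gain_sd": cfg.sensor_gain_sd,
        "bottle_effect_sd": cfg.bottle_effect_sd,
        "sample_noise_sd": cfg.sample_noise_sd,
        "kinetic_noise_sd": cfg.kinetic_noise_sd,
        "obs_noise_sd": cfg.obs_noise_sd,
        "seed": cfg.seed,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_from_yaml(path: str | Path) -> GeneratorConfig:
    d = yaml.safe_load(Path(path).read_text())

    def unflat(m: Mapping[str, float]) -> dict[tuple[str, str], float]:
        out = {}
        for k, v in m.items():
            st, c = k.split("/")
            out[(st, c)] = float(v)
        return out

    return GeneratorConfig(
        sampling_rate_hz=float(d["sampling_rate_hz"]),
        phase_durations_s=tuple(d["phase_durations_s"]),
        bottles_per_class=dict(d["bottles_per_class"]),
        samples_per_bottle=tuple(d["samples_per_bottle"]),
        baseline_conductance=tuple(d["baseline_conductance"]),
        amplitude=unflat(d["amplitude"]),
        tau_ads_s=unflat(d["tau_ads_s"]),
        tau_des_s=unflat(d["tau_des_s"]),
        sensor_gain_sd=float(d["sensor_gain_sd"]),
        bottle_effect_sd=float(d["bottle_effect_sd"]),
        sample_noise_sd=float(d["sample_noise_sd"]),
        kinetic_noise_sd=float(d.get("kinetic_noise_sd", 0.0)),
        obs_noise_sd=float(d["obs_noise_sd"]),
        seed=int(d["seed"]),
    )
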