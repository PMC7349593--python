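"""Shared fixtures.

``fast_*`` fixtures use a scaled-down measurement protocol (5 Hz, short
phases, 2 bottles per class) so unit tests run in seconds.  The
``default_table`` / ``selection_trace`` fixtures build the full
28-bottle default scenario once per session; they back the end-to-end
accuracy checks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from enose import synthetic
from enose.features import build_feature_table
from enose.model_eval import CVConfig
from enose.selection import forward_select


def scaled_down(cfg: synthetic.GeneratorConfig, seed: int = 0,
                bottles: int = 2,
                samples: tuple[int, int] = (3, 4)) -> synthetic.GeneratorConfig:
    """Shrink a scenario for fast tests: 5 Hz, (4, 20, 24) s phases."""
    return replace(
        cfg,
        sampling_rate_hz=5.0,
        phase_durations_s=(4.0, 20.0, 24.0),
        bottles_per_class={c: bottles for c in cfg.bottles_per_class},
        samples_per_bottle=samples,
        seed=seed,
    )


@pytest.fixture(scope="session")
def fast_config():
    return scaled_down(synthetic.default_scenario(), seed=7)


@pytest.fixture(scope="session")
def fast_dataset(fast_config):
    return synthetic.generate_dataset(fast_config)


@pytest.fixture(scope="session")
def fast_table(fast_dataset):
    return build_feature_table(fast_dataset)


@pytest.fixture(scope="session")
def fast_measurement(fast_dataset):
    return fast_dataset.measurements[0]


# --- full-scale fixtures (built once, shared by the end-to-end tests) ---

@pytest.fixture(scope="session")
def default_table():
    """Feature table of the default 28-bottle scenario (~310 samples)."""
    ds = synthetic.generate_dataset(synthetic.default_scenario(seed=11))
    return build_feature_table(ds)


@pytest.fixture(scope="session")
def selection_trace(default_table):
    """Forward selection of 10 features on the default scenario.

    Candidate ranking uses 5 group-shuffle repeats; the chosen set is
    re-scored at full repeats by the tests that need it.
    """
    return forward_select(default_table, max_k=10,
                          cv_cfg=CVConfig(n_repeats=5, seed=11))
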