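import numpy as np
import pytest

from twofoldmi.panel import (
    CATEGORICAL,
    CONTINUOUS,
    LongitudinalPanel,
    SurvivalOutcome,
    VariableSpec,
)


def make_panel(specs, n, t, fill=None, rng=None):
    """Small panel builder: fill='complete' fills every cell with draws
    (continuous standard normal, categorical uniform levels)."""
    panel = LongitudinalPanel(np.arange(n), range(1, t + 1), specs)
    if fill == "complete":
        rng = rng or np.random.default_rng(0)
        for s in specs:
            shape = (n, t) if s.time_dependent else (n,)
            where = np.ones(shape, dtype=bool)
            if s.is_categorical:
                panel.set_cells(s.name, where, rng.integers(0, len(s.levels), shape).astype(np.int16))
            else:
                panel.set_cells(s.name, where, rng.standard_normal(shape))
    return panel


def continuous_spec(name, td=True, imputable=True):
    return VariableSpec(name, CONTINUOUS, time_dependent=td, imputable=imputable)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_outcome():
    def _make(n, event_frac=0.3, rng=None, tmax=5.0):
        rng = rng or np.random.default_rng(1)
        event = (rng.random(n) < event_frac).astype(int)
        time = rng.uniform(0.1, tmax, n)
        return SurvivalOutcome(event, time)

    return _make
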