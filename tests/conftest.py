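import numpy as np
import pytest

import windshift as ws
from windshift.landscape import Landscape, SuitabilityStack


def make_stack(slices, cell_size=1000.0, nodata_mask=None, period_length=10):
    """SuitabilityStack from a list of binary arrays."""
    arrs = [np.asarray(s, dtype=np.uint8) for s in slices]
    n_rows, n_cols = arrs[0].shape
    landscape = Landscape(n_rows, n_cols, cell_size, nodata_mask=nodata_mask)
    return SuitabilityStack(
        landscape=landscape,
        slices=[(f"t{i}", a) for i, a in enumerate(arrs)],
        period_length=period_length,
    )


def make_config(stack, traits=None, wind=5.0, canopy=0.3, **kwargs):
    """SimulationConfig with uniform wind/canopy over the stack's landscape."""
    shape = stack.landscape.shape
    n_periods = max(len(stack) - 1, 1)
    wind_grid = np.full(shape, float(wind))
    kwargs.setdefault("replicates", 1)
    kwargs.setdefault("years", stack.period_length * (len(stack) - 1))
    return ws.SimulationConfig(
        suitability=stack,
        wind_mean=[wind_grid.copy() for _ in range(n_periods)],
        wind_max=[wind_grid.copy() * 2 for _ in range(n_periods)],
        canopy=np.full(shape, float(canopy)),
        traits=traits or ws.SpeciesTraits(Vt=0.03, H=1.0),
        **kwargs,
    )


def ring1_log_miss(shape, d_max=10):
    """Deterministic ring-1 kernel: P_disp = 1 for class 1, 0 elsewhere."""
    log_miss = np.zeros((d_max,) + shape)
    log_miss[0] = -np.inf
    return log_miss


@pytest.fixture(scope="session")
def default_spec():
    return ws.SynthSpec()


@pytest.fixture(scope="session")
def default_stack(default_spec):
    return ws.make_suitability_stack(default_spec)


@pytest.fixture()
def small_landscape():
    return Landscape(5, 5, 1000.0)
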