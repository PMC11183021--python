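import numpy as np
import pytest

from hepadce import perfusion as pf
from hepadce import synthetic as syn


@pytest.fixture(scope="session")
def time_grid():
    """Default 42-frame dynamic grid at 3 s spacing."""
    return syn.default_time_grid()


@pytest.fixture(scope="session")
def inputs(time_grid):
    """Default arterial/portal input functions."""
    return syn.generate_input_functions(syn.InputFunctionSpec(), time_grid)


@pytest.fixture(scope="session")
def small_phantom_spec():
    """A phantom small enough for full voxel-wise fitting in tests."""
    return syn.PhantomSpec(
        shape=(10, 10, 6),
        spacing_mm=(2.0, 2.0, 2.5),
        tumor_radius_mm=3.0,
        band_width_mm=4.0,
        noise="none",
    )


@pytest.fixture(scope="session")
def canonical_params():
    """The reference voxel used across fitting checks."""
    return pf.PerfusionParams.from_flows(30.0, 70.0, 25.0)
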