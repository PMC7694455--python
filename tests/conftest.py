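import numpy as np
import pandas as pd
import pytest

from phenokit.emergence import EmergenceCounts
from phenokit.synth import sample_emergence_times


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_emergence_units(b, g50, n_units, seeds_per_unit, inspection_times,
                         seed):
    """Simulate grouped emergence counts from the log-logistic event model."""
    gen = np.random.default_rng(seed)
    times = np.asarray(inspection_times, dtype=float)
    units = []
    for u in range(n_units):
        t_emerge = sample_emergence_times(b, g50, seeds_per_unit, gen)
        cum = (t_emerge[:, None] <= times[None, :]).sum(axis=0)
        units.append(EmergenceCounts(unit_id=f"u{u}", times=tuple(times),
                                     cum_counts=tuple(int(c) for c in cum),
                                     n_sown=seeds_per_unit))
    return units


@pytest.fixture
def weather_frame():
    """Three contiguous days of single-source weather with units 6, 0, 4."""
    return pd.DataFrame({
        "date": ["2020-10-01", "2020-10-02", "2020-10-03"],
        "tmin_c": [4.0, -2.0, 1.0],
        "tmax_c": [10.0, 0.0, 9.0],
        "source": ["air"] * 3,
    })
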