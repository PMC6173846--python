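import numpy as np
import pytest

from peakqc.datamodel import Label, TransitionKey, TransitionTrace, group_traces
from peakqc.simulate import SimulationConfig, clean_config, simulate_dataset


def make_trace(intensities, times=None, run="run01", peptide="PEPTIDEK",
               fragment="y4", label=Label.ENDOGENOUS, bounds=None,
               product_charge=1):
    intensities = np.asarray(intensities, dtype=float)
    if times is None:
        times = np.arange(len(intensities), dtype=float)
    key = TransitionKey(run, peptide, 2, fragment, product_charge, label)
    if bounds is None:
        bounds = (float(times[0]), float(times[-1]))
    return TransitionTrace(key=key, times=np.asarray(times, float),
                           intensities=intensities,
                           boundary_start=bounds[0], boundary_end=bounds[1])


@pytest.fixture(scope="session")
def small_dataset():
    """Defected multi-run dataset: 4 runs x 8 peptides x 4 fragments."""
    return simulate_dataset(SimulationConfig(n_runs=4, n_peptides=8, seed=7))


@pytest.fixture(scope="session")
def clean_dataset():
    """Defect-free counterpart of ``small_dataset``."""
    return simulate_dataset(clean_config(n_runs=4, n_peptides=8, seed=7))


@pytest.fixture(scope="session")
def clean_groups(clean_dataset):
    return list(group_traces(clean_dataset.traces).values())
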