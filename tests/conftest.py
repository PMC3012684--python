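import numpy as np
import pandas as pd
import pytest

from langcal import (
    LangmuirParams,
    SimulationConfig,
    SpikeInDataset,
    average_replicates,
    simulate,
)


@pytest.fixture(scope="session")
def noiseless_config():
    """Homogeneous, noise-free Latin-square experiment: every probe is an
    exact copy of the global isotherm."""
    return SimulationConfig(
        n_probes=8, probe_cv=0.0, noise_sd_log=0.0, frac_nonlangmuir=0.0, seed=7
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    raw, design, _ = simulate(noiseless_config)
    return average_replicates(raw, design)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Moderately heterogeneous, noisy experiment for integration checks."""
    cfg = SimulationConfig(
        n_probes=12, probe_cv=0.15, noise_sd_log=0.15, frac_nonlangmuir=0.0, seed=11
    )
    raw, design, _ = simulate(cfg)
    return average_replicates(raw, design)


def make_dataset(probe_params: dict, concentrations) -> SpikeInDataset:
    """Exact (noise-free) dataset from explicit per-probe parameters."""
    rows = []
    for probe, p in probe_params.items():
        for j, c in enumerate(concentrations):
            rows.append(
                {
                    "probe_id": probe,
                    "condition_id": f"cond_{j}",
                    "mean_intensity": p.a * c / (p.b + c) + p.d,
                    "nominal_concentration": float(c),
                    "n_replicates": 1,
                }
            )
    return SpikeInDataset(pd.DataFrame(rows))


@pytest.fixture
def toy_params():
    return LangmuirParams(a=1000.0, b=10.0, d=100.0)
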