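"""Shared fixtures.

The expensive Monte Carlo artefacts (the full permeability sweep and the
mixed-population fraction sweep) are session-scoped so that the acceptance
checks and the property checks share one computation.
"""

import numpy as np
import pytest

import aquadiff as aq
from aquadiff.campaigns import fraction_sweep, permeability_sweep

#: Permeability grid for the main sweep: the 0.034-0.39 um/ms range with
#: anchor points below and above so measured ADCs can be bracketed.
SWEEP_P_GRID = [0.0, 0.017, 0.034, 0.074, 0.14, 0.25, 0.39, 0.55, 0.9]
SWEEP_DELTA_EFF = [18.0, 398.0]
CONTROL_ADC = 377.57


@pytest.fixture(scope="session")
def default_lattice():
    return aq.build_fcc_lattice(seed=42)


@pytest.fixture(scope="session")
def main_sweep():
    """ADC vs permeability at Delta_eff = 18 and 398 ms, 1e4 walkers/point."""
    return permeability_sweep(
        SWEEP_P_GRID,
        SWEEP_DELTA_EFF,
        sim=aq.SimulationParams(n_walkers=10_000),
        seed=20_260_926,
    )


@pytest.fixture(scope="session")
def fraction_result():
    """ADC at 0% and 10% high-permeability cells, Delta_eff = 398 ms."""
    return fraction_sweep(
        [0.0, 0.10],
        n_arrangements=12,
        delta_eff_values_ms=[398.0],
        sim=aq.SimulationParams(n_walkers=2_000),
        seed=77,
    )
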