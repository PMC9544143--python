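import numpy as np
import pytest

from greenwave.design import build_design
from greenwave.observations import assemble_series
from greenwave.simulate import (CurveParams, EffectConfig, SamplingSchedule,
                                VarianceConfig, simulate_experiment)


@pytest.fixture(scope="session")
def small_design():
    """4 plots (2 richness levels) x 3 treatments x 3 years."""
    return build_design({1: 2, 16: 2},
                        ["control", "insecticide", "foliar_fungicide"],
                        years=[2010, 2011, 2012])


@pytest.fixture(scope="session")
def neutral_effects():
    return EffectConfig(
        amplitude_mult={1: 1.0, 16: 1.0},
        phenology_shift={1: 0.0, 16: 0.0},
        senescence_mult={"control": 1.0, "insecticide": 1.0,
                         "foliar_fungicide": 1.0},
    )


@pytest.fixture(scope="session")
def noiseless_records(small_design, neutral_effects):
    """Every subplot-year lies exactly on the same base curve, same days."""
    var = VarianceConfig(sd_year=0, sd_plot=0, sd_subplot=0, sd_resid=0, seed=0)
    sched = SamplingSchedule(jitter_days=0, miss_prob=0.0)
    return simulate_experiment(small_design, CurveParams(), neutral_effects,
                               var, sched)


@pytest.fixture(scope="session")
def noiseless_series(noiseless_records):
    return assemble_series(noiseless_records)
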