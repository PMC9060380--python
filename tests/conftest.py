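"""Shared fixtures: synthetic archetypes and a full-pipeline helper."""

import pytest

from otolithsr.io import PipelineConfig, process_run
from otolithsr.synthetic import (GeneratorParams, InstrumentModel,
                                 make_otolith, simulate_cohort)


@pytest.fixture(scope="session")
def ideal_inst():
    return InstrumentModel.ideal()


@pytest.fixture(scope="session")
def default_inst():
    return InstrumentModel()


@pytest.fixture(scope="session")
def gen_params():
    return GeneratorParams()


def analyze(oto, config=None):
    """Run reduction → cropping → alignment → smoothing → classification."""
    config = config or PipelineConfig()
    profile, smoothed, call = process_run(
        oto.raw_run, oto.standards, oto.annuli_um, config)
    return profile, smoothed, call


@pytest.fixture(scope="session")
def archetypes_ideal(ideal_inst, gen_params):
    """One otolith per life-history type, distortion-free instrument."""
    return [make_otolith(t, gen_params, ideal_inst, seed=300 + t)
            for t in range(1, 7)]


@pytest.fixture(scope="session")
def archetypes_ideal_analyzed(archetypes_ideal):
    return [(oto, *analyze(oto)) for oto in archetypes_ideal]


@pytest.fixture(scope="session")
def cohort42(default_inst):
    """The reference noisy cohort: 10 per type, default instrument, seed 42."""
    return simulate_cohort(10, default_inst, seed=42)


@pytest.fixture(scope="session")
def cohort42_analyzed(cohort42):
    return [(oto, *analyze(oto)) for oto in cohort42]
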