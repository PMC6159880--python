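"""Shared fixtures: tiny handwritten datasets and fast chain settings."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from ipdnma import (
    CovariateSpec,
    GeneratorConfig,
    IPDDataset,
    MCMCSettings,
    generate_network,
)

TOY_CSV = """\
trial,treatment,time,event,stage
T1,RT,1.0,1,0
T1,CTRT,2.0,0,1
T2,RT,0.5,1,2
T2,CTRT,3.0,1,
"""


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture
def stage_spec():
    return CovariateSpec("stage", bounds=(0.0, 2.0), ordinal=True)


@pytest.fixture
def toy_dataset(toy_csv, stage_spec):
    from ipdnma import read_ipd

    return read_ipd(toy_csv, covariate_spec=[stage_spec])


def small_network_config(**overrides) -> GeneratorConfig:
    """A 3-treatment, 6-trial network small enough for second-scale fits."""
    defaults = dict(
        seed=0,
        n_per_arm=50,
        treatments=("RT", "CTRT", "CT+RT"),
        designs=((("RT", "CTRT"), 3), (("RT", "CT+RT"), 2), (("CTRT", "CT+RT"), 1)),
        beta={"CTRT": -0.3, "CT+RT": 0.1},
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture
def small_network():
    return generate_network(small_network_config())


@pytest.fixture
def fast_settings():
    return MCMCSettings(n_burnin=300, n_iter=500, n_chains=2, seed=1)
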