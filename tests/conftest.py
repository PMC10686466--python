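import dataclasses

import pytest

from rwrhe.config import RunConfig
from rwrhe.evaluation import compute_measures, run_from_measures
from rwrhe.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec()


@pytest.fixture(scope="session")
def default_inputs(default_spec):
    return generate_fixture(default_spec)


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_measures(default_inputs, default_config):
    """Similarity measures on the default fixture, computed once per session."""
    return compute_measures(default_inputs, default_config)


@pytest.fixture(scope="session")
def variant_results(default_measures, default_inputs, default_config):
    """Pipeline results for all three variants, sharing the measure stage."""
    r_measures, t_measures = default_measures
    return {
        v: run_from_measures(
            r_measures, t_measures, default_inputs,
            dataclasses.replace(default_config, variant=v),
        )
        for v in ("full", "no_gip", "equal_weights")
    }


@pytest.fixture(scope="session")
def full_result(variant_results):
    return variant_results["full"]
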