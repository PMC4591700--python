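import pytest

from rhsa import PipelineConfig, generate_scenario, run_pipeline


@pytest.fixture(scope="session")
def scenario():
    return generate_scenario(seed=1)


@pytest.fixture(scope="session")
def pipeline_cube(scenario):
    return run_pipeline(
        scenario.ledger, scenario.volumes, scenario.costs, scenario.ctx, PipelineConfig()
    )
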