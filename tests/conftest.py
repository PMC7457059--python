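import pytest

from sijstrain import (
    OperatorNoiseModel,
    average_by_group,
    battery_to_frame,
    build_model,
    make_canonical_pelvis,
    render_ct,
    run_battery,
    run_trials,
)


@pytest.fixture(scope="session")
def canonical_lm():
    return make_canonical_pelvis()


@pytest.fixture(scope="session")
def model(canonical_lm):
    return build_model(canonical_lm)


@pytest.fixture(scope="session")
def battery(model):
    """Equilibrium results for the standard eight-scenario battery."""
    return run_battery(model)


@pytest.fixture(scope="session")
def records(model, battery):
    return battery_to_frame(model, battery)


@pytest.fixture(scope="session")
def grid(records):
    return average_by_group(records)


@pytest.fixture(scope="session")
def zero_noise_grids(canonical_lm):
    """Five-trial study with zero operator noise: trials must be identical."""
    return run_trials(canonical_lm, OperatorNoiseModel(sd=0.0, seed=1), n_trials=5)


@pytest.fixture(scope="session")
def phantom(canonical_lm):
    """Default CT-like phantom (226 transverse slices)."""
    return render_ct(canonical_lm)
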