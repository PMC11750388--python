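import pytest

from epievo import ModelParams


@pytest.fixture(scope="session")
def baseline() -> ModelParams:
    """Baseline heterogeneous-host parameter set."""
    return ModelParams.baseline()


@pytest.fixture(scope="session")
def gap_small() -> ModelParams:
    """Small host-quality-gap, fixed-trait scenario parameters."""
    return ModelParams.baseline().with_updates(cH=0.1, cL=0.0, yH=0.1, yL=0.2)


@pytest.fixture(scope="session")
def gap_large() -> ModelParams:
    """Large host-quality-gap, fixed-trait scenario parameters."""
    return ModelParams.baseline().with_updates(cH=1.0, cL=0.0, yH=0.1, yL=1.0)
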