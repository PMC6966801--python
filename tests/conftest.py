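import pytest

from cpaudit import DesignSpec, FutureHypothesis, InterimState


@pytest.fixture
def one_sided_design():
    """alpha=0.025 one-sided, 90% power at theta_d=0.3 => I_K ~ 116.75."""
    return DesignSpec(
        alpha=0.025, sidedness="one", planned_power=0.90, design_effect=0.30
    )


@pytest.fixture
def two_sided_design():
    return DesignSpec(
        alpha=0.05, sidedness="two", planned_power=0.80, design_effect=0.30
    )


@pytest.fixture
def halfway_interim():
    """A mid-trial look with a modest positive trend."""
    return InterimState(
        look_index=1, z_value=1.0, info_fraction=0.5, estimate=0.13, se=0.13
    )


@pytest.fixture
def null_hypothesis():
    return FutureHypothesis("null")


@pytest.fixture
def design_hypothesis():
    return FutureHypothesis("design")


@pytest.fixture
def trend_hypothesis():
    return FutureHypothesis("current_trend")
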