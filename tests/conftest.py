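import numpy as np
import pytest

from escrt_kinetics import (
    ChannelKinetics,
    EventSpec,
    SimulationConfig,
    default_config,
    render_movie,
    simulate_cohort,
)


def make_event(
    event_id=0,
    position=(20.0, 20.0),
    phenotype="delayed_late_channel",
    tau_early=5.0,
    tau_late=15.0,
    A2=5000.0,
    dx_a=2.0,
    dx_d=1.0,
    t0_a=10.0,
    locked=False,
    condition="WT",
):
    """Hand-built dual-channel event with fully controlled kinetics."""
    early = ChannelKinetics(
        A1=0.0, A2=A2, t0_a=t0_a, dx_a=dx_a, tau_ret=tau_early, dx_d=dx_d,
        locked=locked,
    )
    late = ChannelKinetics(
        A1=0.0, A2=A2, t0_a=t0_a, dx_a=dx_a, tau_ret=tau_late, dx_d=dx_d,
        locked=locked,
    )
    return EventSpec(
        event_id=event_id,
        position=position,
        phenotype=phenotype,
        channels={"early": early, "late": late},
        condition=condition,
    )


@pytest.fixture(scope="session")
def wt_config():
    return default_config("WT", n_events=6, seed=42)


@pytest.fixture(scope="session")
def noisefree_config():
    return default_config("WT", n_events=6, seed=42, noise=False)


@pytest.fixture(scope="session")
def noisefree_run(noisefree_config):
    """Small noise-free rendered cohort shared across tests."""
    events = simulate_cohort(noisefree_config, seed=42)
    movies, truth = render_movie(events, noisefree_config, seed=43)
    return events, movies, truth


@pytest.fixture(scope="session")
def noisy_run(wt_config):
    events = simulate_cohort(wt_config, seed=42)
    movies, truth = render_movie(events, wt_config, seed=43)
    return events, movies, truth


@pytest.fixture()
def times():
    return np.arange(300) * 0.2
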