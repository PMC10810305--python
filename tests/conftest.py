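import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoexo.controller import ControllerConfig
from myoexo.synthetic import (
    GeneratorConfig,
    MuscleAdaptation,
    TimelineEntry,
    generate_trial,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def short_timeline():
    """A compressed protocol: long enough for 30-stride windows everywhere."""
    return [
        TimelineEntry(condition="BootsOnly", minutes=1.0),
        TimelineEntry(condition="Unpowered", minutes=1.0),
        TimelineEntry(condition="Powered", minutes=3.0),
        TimelineEntry(condition="Deadaptation", minutes=1.0),
    ]


def fast_adaptation(changes=None):
    """Adaptation with a short time constant so the compressed Powered bout
    still reaches steady state."""
    changes = changes or {"sol": -0.12, "mg": -0.05, "lg": -0.17, "ta": 0.09}
    return {
        m: MuscleAdaptation(steady_state_change=c, time_constant_min=0.5)
        for m, c in changes.items()
    }


@pytest.fixture(scope="session")
def short_cfg() -> GeneratorConfig:
    return GeneratorConfig(
        n_subjects=2,
        seed=7,
        timeline=short_timeline(),
        adaptation=fast_adaptation(),
    )


@pytest.fixture(scope="session")
def short_subject_trials(short_cfg):
    """All four condition recordings for one subject of the compressed protocol."""
    return {
        e.condition: generate_trial(short_cfg, 0, e.condition)
        for e in short_cfg.timeline
    }


@pytest.fixture(scope="session")
def ctl_cfg() -> ControllerConfig:
    return ControllerConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
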