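import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from devdelay import (
    ExpressionMatrix,
    SimulationConfig,
    TimeCourseReference,
    generate_embryo_samples,
    generate_reference,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_reference() -> TimeCourseReference:
    """Six genes over the twelve canonical 2-hour bins; g6 is silent."""
    bins = [(2 * i, 2 * (i + 1)) for i in range(12)]
    values = np.array(
        [
            np.linspace(24, 2, 12),  # early-declining
            np.linspace(1, 23, 12),  # late-rising
            np.concatenate([np.linspace(0, 30, 6), np.linspace(30, 0, 6)]),  # peaked
            np.full(12, 7.0),  # flat
            np.linspace(10, 4, 12),  # mild decline
            np.zeros(12),  # silent
        ]
    )
    return TimeCourseReference(
        ["g1", "g2", "g3", "g4", "g5", "g6"], bins, values
    )


@pytest.fixture
def expression_pair() -> tuple[ExpressionMatrix, ExpressionMatrix]:
    genes = ["g1", "g2", "g3", "g4"]
    control = ExpressionMatrix(
        genes,
        np.array([[10.0, 11.0, 9.0], [5.0, 6.0, 4.0], [0.0, 0.0, 0.0], [2.0, 2.5, 1.5]]),
        condition_label="control",
    )
    mutant = ExpressionMatrix(
        genes,
        np.array([[30.0, 33.0, 27.0], [5.5, 5.0, 6.0], [0.0, 0.0, 0.0], [2.2, 1.8, 2.1]]),
        condition_label="mutant",
    )
    return control, mutant


@pytest.fixture
def sim_factory():
    """Build (reference, truth, control, mutant, config) for given overrides."""

    def build(window=(6.0, 12.0), **overrides):
        defaults = dict(n_genes=400, seed=11)
        defaults.update(overrides)
        config = SimulationConfig(**defaults)
        reference, truth = generate_reference(config)
        control, mutant, truth = generate_embryo_samples(
            reference, truth, config, window
        )
        return reference, truth, control, mutant, config

    return build
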