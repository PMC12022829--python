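import numpy as np
import pytest
from hypothesis import settings

from kamrisk.config import GeneratorConfig

settings.register_profile("ci", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-matched default cohort with signals (84 athletes, 1764 trials)."""
    from kamrisk.synthetic import make_cohort

    return make_cohort(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    from kamrisk.signal_processing import process_cohort

    cohort, _ = default_cohort
    return process_cohort(cohort)


@pytest.fixture(scope="session")
def default_solution(default_processed):
    from kamrisk.clustering import cluster_windows

    return cluster_windows(default_processed.windows)


@pytest.fixture(scope="session")
def default_table(default_cohort, default_processed, default_solution):
    from kamrisk.pipeline import build_feature_table

    cohort, _ = default_cohort
    return build_feature_table(cohort, default_processed, default_solution)


def small_config(seed=0, **kw):
    """A fast cohort config used by unit tests (not the study conditions)."""
    base = dict(
        n_athletes=10,
        n_injured=2,
        trials_per_athlete=6,
        female_fraction=1.0,
        seed=seed,
    )
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
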