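import warnings

import pytest

from ocsplus import GeneratorConfig, load_layout, simulate_cohort


@pytest.fixture(scope="session")
def layout():
    return load_layout()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with ground truth (session-realisable)."""
    cfg = GeneratorConfig(n_participants=40)
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def norming_cohort():
    """A cohort large enough to derive stable normative tables from."""
    cfg = GeneratorConfig(n_participants=600)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truths = simulate_cohort(cfg, seed=29)
    return cohort, truths
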