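import pytest

from capsule_eval import StudyDesign, default_panel, simulate_progression, \
    simulate_ranking, simulate_turing


@pytest.fixture(scope="session")
def design():
    return StudyDesign(seed=11)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def turing_responses(design, panel):
    return simulate_turing(design, panel)


@pytest.fixture(scope="session")
def ranking_responses(design, panel):
    return simulate_ranking(design, panel)


@pytest.fixture(scope="session")
def progression_responses(design, panel):
    return simulate_progression(design, panel)
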