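import pytest

from neopain import default_config, default_table, expert_template, novice_template, simulate_session


@pytest.fixture(scope="session")
def pipp_table():
    return default_table("PIPP")


@pytest.fixture(scope="session")
def pipp_r_table():
    return default_table("PIPP-R")


@pytest.fixture(scope="session")
def expert():
    return expert_template()


@pytest.fixture(scope="session")
def novice():
    return novice_template()


@pytest.fixture(scope="session")
def bundle(pipp_table):
    """One simulated expert-template session, fixed seed."""
    return simulate_session(default_config(20260920), pipp_table)
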