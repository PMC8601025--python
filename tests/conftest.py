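import datetime as dt

import pytest

from vaxquery import (
    classify_log,
    default_lexicon,
    generate_log,
    study_scenario,
)

D0 = dt.date(2021, 1, 1)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def small_scenario():
    """One modest study-scenario run shared across tests."""
    return study_scenario(queries_per_day=20_000, seed=42)


@pytest.fixture(scope="session")
def small_log(small_scenario):
    return generate_log(small_scenario)


@pytest.fixture(scope="session")
def small_classified(small_log, lexicon):
    return classify_log(small_log.records, lexicon)
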