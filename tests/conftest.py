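import numpy as np
import pytest

from biclog import EventLog, extract_features, simulate_ticket_cohort


@pytest.fixture
def worked_2x2():
    """Tiny matrix whose metric values are known by hand."""
    return np.array([[1.0, 2.0], [3.0, 5.0]])


@pytest.fixture
def ticket_log():
    """A minimal full-credit log: compare daily price, buy 4 individual trips."""
    return EventLog(
        "ex1",
        [
            ("start", 0.0),
            ("city_subway", 2.0),
            ("concession", 4.0),
            ("daily", 6.0),
            ("cancel", 8.0),
            ("individual", 10.0),
            ("trip_4", 12.0),
            ("buy", 14.0),
            ("end", 15.0),
        ],
    )


@pytest.fixture(scope="session")
def small_cohort():
    logs, labels = simulate_ticket_cohort(60, seed=42)
    return logs, labels


@pytest.fixture(scope="session")
def cohort_matrix(small_cohort):
    logs, _ = small_cohort
    return extract_features(logs)
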