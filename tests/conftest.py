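import numpy as np
import pandas as pd
import pytest

from dichotic import APConfig, BTConfig, HPConfig


@pytest.fixture(scope="session")
def hp_cfg() -> HPConfig:
    return HPConfig()


@pytest.fixture(scope="session")
def ap_cfg() -> APConfig:
    return APConfig()


@pytest.fixture(scope="session")
def bt_cfg() -> BTConfig:
    return BTConfig()


def long_table(scores: dict) -> pd.DataFrame:
    """Build a long-format subject table from {subject: {test: (phones, speakers)}}."""
    rows = []
    for subject, by_test in scores.items():
        for test, (h, l) in by_test.items():
            rows.append({"subject_id": subject, "test": test,
                         "equipment": "headphones", "n_correct": h})
            rows.append({"subject_id": subject, "test": test,
                         "equipment": "loudspeakers", "n_correct": l})
    return pd.DataFrame(rows)


@pytest.fixture
def toy_table() -> pd.DataFrame:
    """Three subjects with (headphone, loudspeaker) HP scores (6,6), (6,2), (4,1)."""
    return long_table({
        "A": {"HP": (6, 6)},
        "B": {"HP": (6, 2)},
        "C": {"HP": (4, 1)},
    })


def random_table(rng: np.random.Generator, n_subjects: int,
                 tests=("HP", "AP")) -> pd.DataFrame:
    """A random subject table with scores drawn uniformly from 0..6."""
    scores = {
        f"S{i:03d}": {t: (int(rng.integers(0, 7)), int(rng.integers(0, 7)))
                      for t in tests}
        for i in range(n_subjects)
    }
    return long_table(scores)
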