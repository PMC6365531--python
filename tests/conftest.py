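import numpy as np
import pytest

from ampseine.datasets import TADPOLE_PRECURSORS

#: Published characterization of the seven tadpole precursors:
#: (mature net charge, mature average MW in Da, mature pI).
TABLE1_PRINTED = {
    "HP2": (2, 3077.7, 8.6),
    "HP3": (5, 2236.6, 10.9),
    "HP4": (4, 2651.3, 9.6),
    "HP5": (1, 3908.5, 8.0),
    "HP6": (4, 3144.8, 10.2),
    "HP8": (2, 3417.1, 8.6),
    "HP9": (2, 3304.0, 8.6),
}


@pytest.fixture(scope="session")
def precursors() -> dict[str, str]:
    return dict(TADPOLE_PRECURSORS)


@pytest.fixture(scope="session")
def table1_printed() -> dict[str, tuple[int, float, float]]:
    return dict(TABLE1_PRINTED)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
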