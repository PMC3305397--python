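import numpy as np
import pytest

from crmscan import PFM, ScanConfig, default_site_pfm, pfm_to_pwm


@pytest.fixture
def two_col_pfm():
    """The 2-column matrix with rows A:[8,0] C:[2,0] G:[0,10] T:[0,0]."""
    counts = np.array([[8, 2, 0, 0], [0, 0, 10, 0]], dtype=float)
    return PFM(counts, matrix_id="TWO_COL")


@pytest.fixture
def sharp_pfm():
    return default_site_pfm()


@pytest.fixture
def sharp_pwm(sharp_pfm):
    return pfm_to_pwm(sharp_pfm)


@pytest.fixture
def scan_config():
    return ScanConfig()


def random_pfm(rng, length=None):
    length = length or int(rng.integers(4, 13))
    counts = rng.integers(0, 50, size=(length, 4)).astype(float)
    # guarantee a positive column total and a unique max/min structure
    counts[np.arange(length), rng.integers(0, 4, size=length)] += 50
    return PFM(counts, matrix_id=f"RAND{length}")


def random_sequence(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
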