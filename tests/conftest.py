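import pytest

from chcid import build_curves, fit_ladder, make_reference_table
from chcid.datasets import load_tf_compounds, nalkane_ladder


@pytest.fixture(scope="session")
def tf_table():
    """The packaged curated compound table."""
    return load_tf_compounds()


@pytest.fixture(scope="session")
def tf_calibration(tf_table):
    """RI calibration built from the table's n-alkane rows."""
    return fit_ladder(nalkane_ladder(tf_table))


@pytest.fixture(scope="session")
def model_curves():
    """Branch curves built from the simulator-consistent reference table."""
    return build_curves(make_reference_table())
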