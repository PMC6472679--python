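import numpy as np
import pandas as pd
import pytest

from sbcc_eval.evp_data import EXTERNAL, VelocityField
from sbcc_eval.synthetic import SyntheticSpec, gen_current_field


@pytest.fixture
def small_field() -> VelocityField:
    """3 x 2 external grid with one missing sample."""
    times = pd.date_range("2016-01-01", periods=3, freq="600s")
    speed = np.array([[0.10, 0.20], [np.nan, 0.25], [0.12, 0.30]])
    return VelocityField(
        times=times,
        heights=[1.24, 10.0],
        speed=speed,
        cadence=600.0,
        provenance=EXTERNAL,
        water_depth_ref=30.0,
    )


@pytest.fixture(scope="session")
def default_synth_field() -> VelocityField:
    """15-day default sheared tidal field (one full spring-neap beat)."""
    return gen_current_field(SyntheticSpec(duration_days=15.0, seed=7))
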