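import numpy as np
import pandas as pd
import pytest

from trioma.data import Channel, Condition, ExpressionMatrix, SampleDesign


@pytest.fixture
def maturation_design() -> SampleDesign:
    return SampleDesign(
        condition=Condition.MATURATION,
        timepoints={"Day2": 2.0, "Day4": 4.0, "Day6": 6.0, "Day8": 8.0},
        baseline="Day2",
    )


@pytest.fixture
def ogd_design() -> SampleDesign:
    return SampleDesign(
        condition=Condition.OGD,
        timepoints={"0hr": 0.0, "2hr": 2.0, "4hr": 4.0},
        baseline="0hr",
    )


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    df = pd.DataFrame(
        {
            "Day2": [100.0, 80.0, 400.0],
            "Day4": [200.0, 40.0, 400.0],
            "Day6": [400.0, 20.0, 400.0],
            "Day8": [800.0, 10.0, 400.0],
        },
        index=["up", "down", "flat"],
    )
    return ExpressionMatrix(channel=Channel.MRNA, data=df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
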