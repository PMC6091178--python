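import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from guidecoex.correlation import CorrelationTable, ThresholdSpec, correlate_guides
from guidecoex.io import ExpressionMatrix, GuideGeneSet, TFFamilyAnnotation

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_matrix(rows: dict[str, list[float]], sample_prefix: str = "S") -> ExpressionMatrix:
    n = len(next(iter(rows.values())))
    cols = [f"{sample_prefix}{i + 1}" for i in range(n)]
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=cols))


def make_table(r_by_guide: dict[str, dict[str, float]], n_samples: int = 11) -> CorrelationTable:
    """Correlation table straight from a nested dict (NaN = undefined)."""
    frame = pd.DataFrame.from_dict(r_by_guide, orient="index")
    return CorrelationTable(frame, n_samples=n_samples)


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples; guide row g1 correlates 1.0 / 0.8 / -1.0 / NA."""
    return make_matrix(
        {
            "g1": [1, 2, 3, 4],
            "g2": [1, 3, 2, 4],
            "g3": [4, 3, 2, 1],
            "g4": [2, 2, 2, 2],
        }
    )


@pytest.fixture
def toy_table(toy_matrix) -> CorrelationTable:
    return correlate_guides(toy_matrix, GuideGeneSet([("g1", "g1")]))


@pytest.fixture
def toy_annotation() -> TFFamilyAnnotation:
    return TFFamilyAnnotation(
        {
            "t1": "MYB",
            "t2": "MYB",
            "t3": "MYB",
            "t4": "bHLH",
            "t5": "bHLH",
            "t6": "NAC",
        }
    )


@pytest.fixture
def tau06() -> ThresholdSpec:
    return ThresholdSpec(0.6)


@pytest.fixture
def tau08() -> ThresholdSpec:
    return ThresholdSpec(0.8)
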