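import numpy as np
import pandas as pd
import pytest

from depscreen.io import GeneEffectMatrix, LineageAnnotation


@pytest.fixture
def small_effects():
    """10 genes x 30 lines; gene 'G01 (1)' implanted in lineage A, rest null."""
    rng = np.random.default_rng(42)
    lines = [f"ACH-{i:06d}" for i in range(1, 31)]
    genes = [f"G{i:02d} ({i})" for i in range(1, 11)]
    vals = rng.normal(0.0, 0.3, size=(30, 10))
    vals[:10, 0] -= 1.0  # lineage A lines are the first ten
    return GeneEffectMatrix(pd.DataFrame(vals, index=lines, columns=genes))


@pytest.fixture
def small_annotation():
    lines = [f"ACH-{i:06d}" for i in range(1, 31)]
    mapping = {l: ("A" if i < 10 else "B") for i, l in enumerate(lines)}
    return LineageAnnotation(mapping)
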