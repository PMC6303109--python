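import numpy as np
import pandas as pd
import pytest

from mstarr.core import CountMatrix


def toy_samples(n_reps: int = 2) -> pd.DataFrame:
    rows = []
    for cond in ("unmethylated", "methylated"):
        for rep in range(1, n_reps + 1):
            for typ in ("DNA", "RNA"):
                rows.append({
                    "sample": f"{typ}_{'u' if cond == 'unmethylated' else 'm'}{rep}",
                    "type": typ, "condition": cond, "treatment": "none",
                    "replicate": rep,
                })
    return pd.DataFrame(rows).set_index("sample")


@pytest.fixture
def samples_2rep() -> pd.DataFrame:
    return toy_samples(2)


@pytest.fixture
def samples_6rep() -> pd.DataFrame:
    return toy_samples(6)


@pytest.fixture
def toy_counts(samples_2rep) -> CountMatrix:
    """Eight samples, four windows, deterministic values."""
    rng = np.random.default_rng(7)
    counts = pd.DataFrame(
        rng.poisson(100, size=(4, len(samples_2rep))),
        index=[f"w{i}" for i in range(4)],
        columns=samples_2rep.index,
    )
    return CountMatrix(counts, samples_2rep)
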