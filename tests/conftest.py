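import numpy as np
import pandas as pd
import pytest

from phyloresponse import CountTable, ResponseSet, parse_newick


@pytest.fixture
def balanced_quartet():
    """((A,B),(C,D)) with all edges 0.1; root depth 0.2."""
    return parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")


@pytest.fixture
def quartet_response():
    return ResponseSet(
        pd.Series({"A": 1.0, "B": 0.5, "C": -1.0, "D": -0.25})
    )


def make_count_table(counts: np.ndarray, n_control: int, n_treatment: int,
                     location: str = "loc1") -> CountTable:
    n_samples = n_control + n_treatment
    assert counts.shape[1] == n_samples
    samples = [f"s{i}" for i in range(n_samples)]
    frame = pd.DataFrame(
        counts, index=[f"otu{i}" for i in range(counts.shape[0])],
        columns=samples,
    )
    meta = pd.DataFrame(
        {
            "location": location,
            "arm": ["control"] * n_control + ["treatment"] * n_treatment,
        },
        index=samples,
    )
    return CountTable(frame, meta)


@pytest.fixture
def toy_table():
    """3 OTUs x 4 samples, 2 control + 2 treatment."""
    counts = np.array([[10, 12, 20, 22], [5, 4, 5, 6], [0, 1, 3, 2]])
    return make_count_table(counts, 2, 2)
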