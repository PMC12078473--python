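import numpy as np
import pandas as pd
import pytest

from synmatch import CountMatrix, InterneuronProfile, SampleTable


@pytest.fixture
def tiny_study():
    """3 genes x 4 samples, 2 per population."""
    counts = pd.DataFrame(
        {
            "s1": [12, 100, 9],
            "s2": [15, 120, 11],
            "s3": [11, 80, 10],
            "s4": [20, 90, 14],
        },
        index=["gA", "gB", "gC"],
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "study_id": ["toy"] * 4,
            "population": ["IT", "IT", "ET", "ET"],
            "replicate": [1, 2, 1, 2],
        }
    )
    return CountMatrix(counts, study_id="toy"), SampleTable(meta)


@pytest.fixture
def labeled_profile():
    """12 cells in 3 subpopulations with a clearly enriched receptor."""
    rng = np.random.default_rng(7)
    genes = ["R1", "R2", "Cck", "Pvalb"]
    cells = [f"c{i}" for i in range(12)]
    expr = pd.DataFrame(rng.poisson(2.0, size=(12, 4)).astype(float),
                        index=cells, columns=genes)
    labels = pd.Series(["CCK"] * 4 + ["PV"] * 4 + ["Sst"] * 4, index=cells)
    expr.loc[labels == "CCK", "R1"] += 8.0
    return InterneuronProfile(expr, labels)


def make_deg_table(rows, study_id="toy"):
    """Build a DEG table frame from dicts keyed by gene."""
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "gene"
    frame.attrs["study_id"] = study_id
    return frame
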