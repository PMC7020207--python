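import dendropy
import numpy as np
import pandas as pd
import pytest


def make_survey(rows):
    """Build a survey DataFrame from (field, year, period, region, crop,
    plot, species, score) tuples."""
    return pd.DataFrame(
        rows,
        columns=["field_id", "year", "period", "region", "crop", "plot",
                 "species", "score"],
    )


@pytest.fixture
def small_survey():
    """Ten 2000s maize fields in one region; species A in 3, B in all."""
    rows = []
    for i in range(10):
        fid = f"f{i}"
        if i < 3:
            rows.append((fid, 2004, "P2000s", "East", "maize", "control",
                         "A", "3"))
        rows.append((fid, 2004, "P2000s", "East", "maize", "control", "B",
                     "1"))
    return make_survey(rows)


@pytest.fixture
def three_taxon_tree():
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick",
                             preserve_underscores=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
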