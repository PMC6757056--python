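import numpy as np
import pandas as pd
import pytest

from switchseq.library_model import build_switch_template
from switchseq.readcount import CountTable
from switchseq.synthetic_data import default_controls


@pytest.fixture
def template():
    """Small loop-II randomized template with a stand-in aptamer."""
    return build_switch_template("GGCAGCTTCAGGC", "loopI", degenerate_lengths={5})


@pytest.fixture
def controls():
    return [ctl for ctl, _ in default_controls()]


@pytest.fixture
def control_fractions():
    return {ctl.name: f for ctl, f in default_controls()}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_count_table(data: dict, controls=("sTRSVctl",)) -> CountTable:
    """Build a CountTable from {variant: {(assay, condition, rep): count}}."""
    frame = pd.DataFrame.from_dict(data, orient="index").fillna(0)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=("assay", "condition", "replicate"))
    return CountTable(frame.sort_index(axis=1), frozenset(controls))


@pytest.fixture
def small_counts():
    """Two replicates, two conditions; control plus three variants."""
    cols = {}
    for cond in ("minus", "plus"):
        for rep in (1, 2):
            cols[("DNA", cond, rep)] = {"sTRSVctl": 1000, "AAAAA": 500,
                                        "CCCCC": 800, "GGGGG": 1200}
    # control RNA/DNA ratio = 2 everywhere
    for cond, scale in (("minus", 1.0), ("plus", 1.0)):
        for rep in (1, 2):
            cols[("RNA", cond, rep)] = {"sTRSVctl": 2000, "AAAAA": 250,
                                        "CCCCC": 1600, "GGGGG": 600}
    frame = pd.DataFrame(cols)
    frame.columns = pd.MultiIndex.from_tuples(
        frame.columns, names=("assay", "condition", "replicate"))
    return CountTable(frame.sort_index(axis=1), frozenset({"sTRSVctl"}))
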