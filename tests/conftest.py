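import numpy as np
import pytest

from endoquant.synthetic import CompetitionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def planted_competition_spec():
    """Two blocking groups, a third group carrying a one-way pair, and three
    non-blockers — the shape of the published heat-map structure."""
    group_assignment = {
        "m01": "group1", "m02": "group1", "m03": "group1",
        "m04": "group2", "m05": "group2", "m06": "group2",
        "m11": "group3", "m12": "group3", "m13": "group3", "m14": "group3",
        "m07": "non-blocker", "m08": "non-blocker", "m09": "non-blocker",
    }
    return CompetitionSpec(
        mab_ids=sorted(group_assignment),
        group_assignment=group_assignment,
        one_way_pairs=[("m14", "m12")],  # m14 blocks m12; m12 does not block m14
        signal_control=1000.0,
        signal_self=50.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def planted_competition_truth():
    return {
        "groups": [
            frozenset({"m01", "m02", "m03"}),
            frozenset({"m04", "m05", "m06"}),
            frozenset({"m11", "m12", "m13", "m14"}),
        ],
        "non_blockers": frozenset({"m07", "m08", "m09"}),
        "one_way_pairs": [("m14", "m12")],
    }
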