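import numpy as np
import pytest

from bgfilt.core_network import BipartiteDistanceMatrix, TrialPowerTable


@pytest.fixture
def hand_2x2():
    """The worked 2x2 bipartite example: merges at 0.2, 0.4, 0.9."""
    return BipartiteDistanceMatrix(
        row_labels=("r1", "r2"),
        col_labels=("c1", "c2"),
        values=np.array([[0.2, 1.0], [0.9, 0.4]]),
    )


def make_table(rng, n_trials=20, n_rois=4, subject_id="sub-01", condition="R",
               band_epoch="cue_alpha", labels=None):
    if labels is None:
        labels = tuple(f"roi{k}.L" for k in range(n_rois))
    values = 1.0 + 0.1 * rng.standard_normal((n_trials, len(labels)))
    return TrialPowerTable(subject_id, condition, band_epoch, labels, values)


@pytest.fixture
def table_factory():
    return make_table
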