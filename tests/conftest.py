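import logging

import numpy as np
import pytest

from copulamri import SubgroupSpec, VoxelPairSample


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("copulamri").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sample(adc, rcbv, patient_id="P0"):
    return VoxelPairSample(adc=np.asarray(adc, float), rcbv=np.asarray(rcbv, float),
                           patient_id=patient_id)


def three_subgroup_specs(n_per_group=20, voxels=3000):
    """The three-archetype study conditions: near-independent, intermediate,
    strongly dependent."""
    return [
        SubgroupSpec(name, rho, n_per_group, voxels_per_patient=voxels)
        for name, rho in (("I", 0.05), ("II", 0.45), ("III", 0.90))
    ]


def midrank_oracle(values):
    """Sort-based midrank oracle: rank = (#strictly-less + #less-or-equal + 1)/2.

    Independent of scipy.stats.rankdata: uses only sorting and counting.
    """
    values = np.asarray(values, float)
    s = np.sort(values)
    less = np.searchsorted(s, values, side="left")
    leq = np.searchsorted(s, values, side="right")
    return (less + leq + 1) / 2.0
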