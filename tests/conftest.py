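import numpy as np
import pytest

from mtcontinuity.io_meta import HaplotypeAlignment
from mtcontinuity.synthetic_data import SyntheticScenario, make_dataset


def aln_from_strings(seqs, ids=None, coord_offset=1):
    """Build a HaplotypeAlignment from equal-length strings."""
    if ids is None:
        ids = [f"s{i+1}" for i in range(len(seqs))]
    matrix = np.frombuffer(
        "".join(seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), len(seqs[0])).copy()
    return HaplotypeAlignment(list(ids), matrix, coord_offset)


@pytest.fixture(scope="session")
def paper41():
    """Synthetic dataset sized like the study: 41 ancients + moderns."""
    scenario = SyntheticScenario(seed=7)
    aln, meta, tree = make_dataset(scenario)
    return scenario, aln, meta, tree
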