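import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from satb2quant import synth


@pytest.fixture
def two_level_pair():
    """Clean two-level image in both channels: every threshold method
    lands in the single gap, so masks are identical across methods."""
    img = np.full((64, 64), 0.1)
    img[20:40, 20:40] = 0.9
    img[0, 0], img[0, 1] = 0.0, 1.0  # anchor min/max off the modes
    return synth.ImagePair(protein=img.copy(), dna=img.copy())


@pytest.fixture
def cage_pair():
    return synth.generate_nucleus_image(
        synth.NucleusPhenotype.preset("dna_cage"), seed=11)


def make_reporter(conditions, seed=0, **common):
    """Shorthand for building simulated plates in tests."""
    defaults = dict(n_replicates=6, cv=0.1)
    defaults.update(common)
    conds = [("empty_vector", synth.ReporterSimParams(0.0, **defaults))]
    for label, rep in conditions:
        conds.append((label, synth.ReporterSimParams(rep, **defaults)))
    return synth.generate_reporter_table(conds, seed=seed)
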