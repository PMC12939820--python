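import numpy as np
import pandas as pd
import pytest

from isofrag.segio import SEGMENT_COLUMNS, CentromereMap, CentromereSpan
from isofrag.synthdata import default_genome

MB = 1_000_000


def seg_df(rows):
    """Build an internal (0-based half-open) segment table from tuples."""
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


@pytest.fixture
def genome():
    return default_genome()


@pytest.fixture
def centromeres(genome):
    return genome.centromere_map()


@pytest.fixture
def simple_cents():
    """One toy chromosome: 100 Mb, centromere 45-55 Mb, midpoint 50 Mb."""
    return CentromereMap({"chrA": CentromereSpan("chrA", 45 * MB, 55 * MB)})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
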