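import numpy as np
import pytest

from ampliconid import (
    AlignmentScoring,
    PanelIndex,
    ReadRecord,
    builtin_pool,
    build_panel,
    filter_alignments,
    length_filter,
    map_reads,
    simulate_library,
    synthetic_references,
    trim_primers,
)
from ampliconid.simulate import EfficiencyModel, ErrorModel


@pytest.fixture(scope="session")
def panel13():
    """Full 13-species panel from synthetic references (3 primer pairs)."""
    refs = synthetic_references(seed=20240901)
    return build_panel(refs)


@pytest.fixture(scope="session")
def panel13_index(panel13):
    return PanelIndex(panel13)


@pytest.fixture(scope="session")
def panel3():
    """Small 3-species panel for cheap alignment tests."""
    refs = synthetic_references(species=("pig", "horse", "cattle"), seed=7)
    return build_panel(refs)


def run_identification(
    panel,
    pool,
    eff=None,
    err=None,
    n_reads=1000,
    seed=0,
    scoring=None,
):
    """Simulate -> trim -> length filter -> map -> filter, in memory.

    Returns (sim_reads, retained_alignments, rejection_tally).
    """
    scoring = scoring or AlignmentScoring()
    sim = simulate_library(pool, panel, eff, err, n_reads=n_reads, seed=seed)
    records = [ReadRecord(r.read_id, r.sequence, r.qualities) for r in sim]
    trimmed = [trim_primers(r) for r in records]
    kept, _ = length_filter(trimmed, scoring.min_len)
    results = map_reads(((r.read_id, r.sequence, r.qualities) for r in kept), panel, scoring)
    retained, tally = filter_alignments(results, scoring)
    return sim, retained, tally


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
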