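import numpy as np
import pytest

from trapsplice.core import (
    GenomicInterval,
    JunctionCountTable,
    SampleMeta,
    SpliceJunction,
)
from trapsplice.simulate import SimulationConfig, simulate_study


def make_table(rows, samples=None):
    """Small count table from (chrom, start, end, strand, counts...) rows."""
    junctions = [
        SpliceJunction(GenomicInterval(c, s, e, st)) for c, s, e, st, *_ in rows
    ]
    counts = np.array([list(r[4:]) for r in rows], dtype=np.int64)
    if samples is None:
        samples = [
            SampleMeta(f"s{i}", tissue=f"t{i}", fraction="IP", replicate=1)
            for i in range(counts.shape[1])
        ]
    return JunctionCountTable(junctions, samples, counts)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study reused across tests (deterministic)."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=60,
        events_per_class={
            "cassette": 12,
            "alt5ss": 4,
            "alt3ss": 4,
            "mutually_exclusive": 4,
            "alt_start_terminal": 4,
            "intron_retention": 4,
            "complex": 2,
        },
        n_exclusive_genes=4,
    )
    return simulate_study(cfg)
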