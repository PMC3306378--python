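import numpy as np
import pandas as pd
import pytest

from pantx import BaseCountTable
from pantx import synthetic_data as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        n_lines=12,
        group_sizes={"SSS": 4, "NSS": 4, "Exotic": 4},
        n_genes=60,
        n_snps=400,
        n_invariant_sites=400,
        n_novel_transcripts=60,
        n_reference_like_transcripts=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return sim.simulate_study(small_config)


def random_basecount_table(rng, n_lines=5, n_positions=30, max_depth=25, p_covered=0.8):
    """A random small base-count table plus its dict form for oracles."""
    lines = [f"L{i + 1}" for i in range(n_lines)]
    rows = []
    records = {}
    for chrom in ("chr1", "chr2"):
        for pos in rng.choice(np.arange(1, 200), size=n_positions // 2, replace=False):
            pos = int(pos)
            for line in lines:
                if rng.random() > p_covered:
                    continue
                counts = rng.multinomial(
                    int(rng.integers(0, max_depth + 1)),
                    rng.dirichlet([0.4] * 4),
                )
                if counts.sum() == 0:
                    continue
                rows.append((line, chrom, pos, *counts))
                records[(line, chrom, pos)] = tuple(int(c) for c in counts)
    df = pd.DataFrame(
        rows,
        columns=["line_id", "chrom", "pos", "count_A", "count_C", "count_G", "count_T"],
    )
    return BaseCountTable(df), records, lines
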