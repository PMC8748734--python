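import numpy as np
import pandas as pd
import pytest

from subshelf import profiling as prof
from subshelf import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        n_genomes=60, n_reads_per_sample=20_000, n_samples=4, seed=11,
        group_assignment={"a1": "basal", "a2": "basal", "b1": "mid", "b2": "mid"},
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return sim.simulate_community(small_config)


@pytest.fixture()
def marker_catalog():
    """A catalog carrying one gene per marker family plus two metabolic genes."""
    rows = [
        (f"m_{fam}", fam, length, "gA", None, True)
        for fam, length in prof.MARKER_FAMILIES.items()
    ]
    rows += [
        ("gene_amoA", "AmoA", 750, "gA", "ammonia oxidation", False),
        ("gene_rho", "RHO", 900, "gB", "rhodopsin phototrophy", False),
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "family", "length_bp", "genome_id", "pathway",
                 "is_single_copy_marker"],
    ).set_index("gene_id")


def make_hits(rows):
    """Build a hit table from (read, gene, identity, coverage, bitscore, length)."""
    return pd.DataFrame(
        rows,
        columns=["read_id", "gene_id", "percent_identity", "query_coverage",
                 "bitscore", "read_length"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
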