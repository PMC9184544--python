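import numpy as np
import pytest

from islandrad import simulate as sim
from islandrad.qc import WindowedAlignment


def make_alignment(taxa, rows, coords=None):
    return WindowedAlignment.from_strings(taxa, rows, coords=coords)


def columns_alignment(columns, taxa=None):
    """Build an alignment from a list of column strings (one char per row)."""
    n = len(columns[0])
    taxa = taxa or [f"t{i}" for i in range(n)]
    rows = ["".join(col[i] for col in columns) for i in range(n)]
    return make_alignment(taxa, rows)


@pytest.fixture(scope="session")
def four_species_config():
    """Small 4-species radiation: 2 individuals each, theta 0.001,
    sister species 5x theta apart."""
    tree = sim.SpeciesTreeSpec(
        newick="((A:0.0025,B:0.0025):0.002,(C:0.0025,D:0.0025):0.002);",
        theta={s: 0.001 for s in "ABCD"},
        n_individuals={s: 2 for s in "ABCD"},
    )
    return sim.SimulationConfig(
        tree=tree,
        contig_lengths={"c1": 200_000},
        p_ils=0.2,
        ils_block_bp=20_000,
        missing_rate=0.02,
        missing_run_mean=100.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def four_species_data(four_species_config):
    genomes, truth = sim.simulate(four_species_config)
    return genomes, truth
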