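import numpy as np
import pytest

from rediplo.homeopair import call_ohnologs, pair_contigs, seed_and_chain
from rediplo.syngen import SimulationConfig, TEFamily, simulate

SMALL_FAMS = (
    TEFamily("TcMar-Tc1", "DNA", 1600, 26, 3.0e6),
    TEFamily("L2", "LINE", 2400, 18, 3.0e6),
)


def small_config(seed: int = 7, **kw) -> SimulationConfig:
    base = dict(
        seed=seed,
        n_contigs=2,
        contig_len=200_000,
        n_genes_per_contig=24,
        te_families=SMALL_FAMS,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One mid-sized synthetic dataset shared across the suite."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_pairings(small_sim):
    hsps = seed_and_chain(small_sim.sequences)
    return pair_contigs(hsps, small_sim.contig_lengths)


@pytest.fixture(scope="session")
def small_ohnologs(small_sim, small_pairings):
    pairs, singletons = call_ohnologs(small_pairings, small_sim.genes,
                                      small_sim.sequences)
    return pairs, singletons


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
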