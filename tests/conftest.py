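import pytest

from lcbkit.sim import EvolutionParams, simulate, worked_example_fixtures


@pytest.fixture(scope="session")
def examples():
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def small_sim():
    """Three 8 kbp genomes at default divergence, with ground truth."""
    return simulate(EvolutionParams(ancestor_len=8000, seed=3))


@pytest.fixture(scope="session")
def small_sim_blocks(small_sim):
    from lcbkit.finder import find_collinear_blocks
    from lcbkit.graph import build_compacted

    records, truth = small_sim
    graph = build_compacted(records, k=15, a=150)
    blocks = find_collinear_blocks(graph, b=200, m=50)
    return graph, blocks
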