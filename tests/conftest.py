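import pytest

from glia.classify import classify_loci
from glia.simulate import SimulationConfig, evolve_locus


@pytest.fixture(scope="session")
def sim47():
    """One full-size (47-gene, three-genome) simulated locus set."""
    return evolve_locus(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def classified47(sim47):
    """The same locus set after classification with pooled references."""
    return classify_loci(list(sim47.loci.values()), sim47.te_library)


@pytest.fixture(scope="session")
def small_sim():
    """A compact 9-gene simulation for alignment-heavy tests."""
    cfg = SimulationConfig(
        seed=5, n_genes={"A": 3, "B": 3, "D": 3}, n_shared_ancestral=0,
        expr_log_mean=2.5,
    )
    return cfg, evolve_locus(cfg)
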