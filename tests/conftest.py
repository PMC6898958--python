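import pytest

from breakscape import simkaryo


@pytest.fixture(scope="session")
def small_ancestor():
    """A 5 x ~2 Mb ancestor with sequence, genes and repeats."""
    return simkaryo.simulate_ancestor(
        5, mean_length=2_000_000, length_dispersion=0.1,
        gene_rate=20.0, gc_target=0.45, seed=11)


@pytest.fixture(scope="session")
def fissioned(small_ancestor):
    """The small ancestor after four fissions and one inversion."""
    plan = simkaryo.sample_plan(
        small_ancestor, 0, counts={"fission": 4, "inversion": 1}, seed=5,
        edge_margin=0.25)
    derived = simkaryo.apply_rearrangements(small_ancestor, plan, derived_id="der")
    return small_ancestor, derived
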