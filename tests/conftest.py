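import numpy as np
import pytest

from ratebound import (
    CodonAlignment,
    DualRateCodonModel,
    PhyloTree,
    SimulationSpec,
    simulate_alignment,
)
from ratebound.simulate import RateLaw


@pytest.fixture(scope="session")
def tree4():
    return PhyloTree.from_newick(
        "((a:0.12,b:0.08):0.05,(c:0.2,d:0.15):0.07);"
    )


@pytest.fixture(scope="session")
def tree5():
    return PhyloTree.from_newick(
        "((a:0.12,b:0.08):0.05,(c:0.2,(d:0.15,e:0.1):0.04):0.07);"
    )


@pytest.fixture(scope="session")
def aln4(tree4):
    """Small simulated 4-taxon alignment matched to tree4."""
    spec = SimulationSpec(
        n_sites=12, seed=901, newick=tree4.to_newick(),
        syn_law=RateLaw.gamma(1.0), nonsyn_law=RateLaw.gamma(0.5),
        nonsyn_scale=0.4,
    )
    aln, _tree, _truth = simulate_alignment(spec)
    return aln


@pytest.fixture(scope="session")
def sim_small():
    """Session-scoped 6-taxon, 150-codon dataset with dual gamma rates."""
    spec = SimulationSpec(
        n_sites=150, seed=5150, n_taxa=6, branch_length_mean=0.12,
        syn_law=RateLaw.gamma(1.0), nonsyn_law=RateLaw.gamma(0.3),
        nonsyn_scale=0.5,
    )
    return simulate_alignment(spec)


@pytest.fixture(scope="session")
def sim_constant():
    """Dataset with no rate variation at all."""
    spec = SimulationSpec(
        n_sites=200, seed=77, n_taxa=6, branch_length_mean=0.12,
        syn_law=RateLaw.constant(), nonsyn_law=RateLaw.constant(),
        nonsyn_scale=0.5,
    )
    return simulate_alignment(spec)


@pytest.fixture(scope="session")
def fit_small_dg(sim_small):
    """One shared discrete-gamma fit of the small dataset (K=3)."""
    aln, tree, _ = sim_small
    return DualRateCodonModel(aln, tree).fit("discrete_gamma", k_syn=3)
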