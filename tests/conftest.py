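import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from posel.alignment import CodonAlignment
from posel.simulate import (
    SimulationSpec,
    default_primate_tree,
    simulate_alignment,
)
from posel.sitemodels import m0_model
from posel.trees import PhyloTree


@pytest.fixture(scope="session")
def primate_tree() -> PhyloTree:
    return default_primate_tree()


@pytest.fixture(scope="session")
def small_tree() -> PhyloTree:
    """Four taxa, asymmetric branch lengths."""
    return PhyloTree.from_newick("((A:0.10,B:0.20):0.05,(C:0.15,D:0.30):0.07);")


@pytest.fixture(scope="session")
def clean_alignment(primate_tree) -> CodonAlignment:
    """A pristine 20-taxon, 200-codon simulated alignment (purifying, M0)."""
    aln, _ = simulate_alignment(
        SimulationSpec(
            tree=primate_tree, n_codons=200, site_model=m0_model(0.2), seed=7
        )
    )
    return aln


def make_alignment(rows: dict[str, str], reference: str = "Homo_sapiens") -> CodonAlignment:
    """Helper: build a CodonAlignment from name -> nucleotide string."""
    return CodonAlignment.from_sequences(list(rows.items()), reference_taxon=reference)
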