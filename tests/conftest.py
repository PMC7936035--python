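import pytest

from mitorearr.ancestral import reconstruct
from mitorearr.events import NOTOTHENIOID_MODEL
from mitorearr.fixtures import REFERENCE_TREE_NEWICK, tip_gene_orders
from mitorearr.pipeline import PipelineConfig, run_pipeline
from mitorearr.simulate import SimConfig, simulate_ancestor

RECONSTRUCTION_REGION = ("nad5", "M")


@pytest.fixture(scope="session")
def reference_assignment():
    """Sankoff reconstruction on the 28-taxon notothenioid scenario."""
    return reconstruct(REFERENCE_TREE_NEWICK, tip_gene_orders(),
                       model=NOTOTHENIOID_MODEL, region=RECONSTRUCTION_REGION)


@pytest.fixture(scope="session")
def synthetic_report():
    """One full synthetic_full pipeline run (seed 0)."""
    return run_pipeline(PipelineConfig(scenario="synthetic_full", seed=0))


@pytest.fixture(scope="session")
def ancestor_genome():
    """A VertGO ancestor without burn-in (fast, composition = base_freqs)."""
    _, genome = simulate_ancestor(SimConfig(seed=11, burn_in=0.0))
    return genome
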