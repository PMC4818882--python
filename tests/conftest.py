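import pandas as pd
import pytest

from blastodyn import (
    SimConfig,
    consensus_table,
    simulate_experiment,
    test_comparison,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The stated experimental world: 5 colonies x 3 phases, depth 1e6,
    2000 genes, 10% DE per transition, package-default seed."""
    return simulate_experiment(SimConfig())


@pytest.fixture(scope="session")
def default_consensus(default_dataset):
    """3-of-5 consensus calls over the three cyclic comparisons."""
    cfg = default_dataset.config
    calls = []
    for a, b in cfg.comparisons:
        calls.extend(test_comparison(default_dataset.counts, a, b, alpha=0.05))
    return consensus_table(calls, min_clues=3)


@pytest.fixture(scope="session")
def default_calls_truth(default_dataset, default_consensus):
    """Consensus calls joined with the generator's truth table."""
    frame = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in default_consensus],
            "comparison": [
                f"{c.comparison[0]}_vs_{c.comparison[1]}" for c in default_consensus
            ],
            "call": [c.status for c in default_consensus],
        }
    )
    return default_dataset.truth_de.merge(frame, on=["gene_id", "comparison"])


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap dataset for plumbing tests."""
    return simulate_experiment(
        SimConfig(n_genes=300, n_go_terms=40, library_size=2e5, seed=42)
    )
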