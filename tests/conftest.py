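import numpy as np
import pandas as pd
import pytest

import cactophil as cp
from cactophil.orthology import similarity_from_sequences
from cactophil.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_tree() -> cp.SpeciesTree:
    return cp.SpeciesTree.default()


@pytest.fixture(scope="session")
def small_world():
    """A simulated study system shared across orthology/branch-rate tests:
    families, sequences, similarity edges and the inferred orthology map."""
    cfg = SimulationConfig(n_families=120, codon_length=200, seed=3)
    rng = np.random.default_rng(3)
    tables, truth = cp.simulate_gene_families(cfg, rng)
    seqs = cp.simulate_codon_sequences(truth, cfg, rng)
    edges = pd.concat(
        [similarity_from_sequences(s) for s in seqs.values() if len(s) > 1],
        ignore_index=True,
    )
    tree = cfg.tree()
    omap = cp.classify_orthology(truth.genes, edges, tree)
    return {
        "config": cfg,
        "truth": truth,
        "sequences": seqs,
        "edges": edges,
        "tree": tree,
        "omap": omap,
    }
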