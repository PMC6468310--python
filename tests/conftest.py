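"""Shared fixtures: simulated plastomes of several sizes, with features.

Session-scoped because simulation and folding-profile computation dominate
suite runtime; tests must not mutate fixture objects.
"""

import numpy as np
import pandas as pd
import pytest

from plastoperon import (
    GeneModel,
    PlastomeAnnotation,
    SimConfig,
    enumerate_adjacent_pairs,
    feature_table,
    simulate_plastome,
)

# Operon-size mix giving roughly equal numbers of operon and non-operon
# pairs (mean operon size 2), used for the large balanced training genome.
BALANCED_SIZES = {1: 0.50, 2: 0.20, 3: 0.15, 4: 0.10, 5: 0.05}


@pytest.fixture(scope="session")
def sim_small():
    return simulate_plastome(SimConfig(n_genes=40, seed=11))


@pytest.fixture(scope="session")
def small_pairs(sim_small):
    return enumerate_adjacent_pairs(sim_small.annotation)


@pytest.fixture(scope="session")
def small_table(sim_small, small_pairs):
    return feature_table(sim_small.annotation, small_pairs)


@pytest.fixture(scope="session")
def small_labels(sim_small):
    return pd.Series(sim_small.label_dict())


@pytest.fixture(scope="session")
def sim_big():
    """~200 operon + ~200 non-operon pairs with strong planted effects."""
    cfg = SimConfig(
        n_genes=400, seed=101, operon_length_distribution=dict(BALANCED_SIZES)
    )
    return simulate_plastome(cfg)


@pytest.fixture(scope="session")
def big_table(sim_big):
    pairs = enumerate_adjacent_pairs(sim_big.annotation)
    return feature_table(sim_big.annotation, pairs)


@pytest.fixture(scope="session")
def big_labels(sim_big):
    return pd.Series(sim_big.label_dict())


@pytest.fixture(scope="session")
def sim_eval():
    """Independent genome (different seed) held out from all training."""
    cfg = SimConfig(
        n_genes=120, seed=202, operon_length_distribution=dict(BALANCED_SIZES)
    )
    return simulate_plastome(cfg)


@pytest.fixture(scope="session")
def eval_table(sim_eval):
    pairs = enumerate_adjacent_pairs(sim_eval.annotation)
    return feature_table(sim_eval.annotation, pairs)


@pytest.fixture(scope="session")
def eval_labels(sim_eval):
    return pd.Series(sim_eval.label_dict())


def toy_genes(spans, genome_id="toy", types=None, strands=None):
    types = types or ["CDS"] * len(spans)
    strands = strands or ["+"] * len(spans)
    return [
        GeneModel(
            gene_id=f"gene{chr(ord('A') + i)}",
            gene_type=types[i],
            strand=strands[i],
            start=s,
            end=e,
            genome_id=genome_id,
        )
        for i, (s, e) in enumerate(spans)
    ]


@pytest.fixture
def toy_annotation():
    """Hand-built circular 3-gene genome for conventions tests."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 1000))
    genes = toy_genes([(10, 100), (150, 300), (400, 700)])
    return PlastomeAnnotation(genome_id="toy", sequence=seq, circular=True, genes=genes)
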