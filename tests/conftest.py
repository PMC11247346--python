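"""Shared fixtures: small hand-built alignments and the synthetic
datasets used across the suite.

Session-scoped fixtures carry the expensive grid sweeps so that the
identity/ensemble checks can reuse one fitted ensemble.
"""

from __future__ import annotations

import numpy as np
import pytest

from cladesparse import (
    GeneAlignment,
    GridConfig,
    SimConfig,
    build_report,
    one_hot_encode,
    run_grid,
    simulate_dataset,
)
from cladesparse.phylogeny import balance_classes


@pytest.fixture
def tiny_genes() -> list[GeneAlignment]:
    """Two toy nucleotide genes over 4 taxa; geneB lacks taxon d."""
    g1 = GeneAlignment(
        gene_id="geneA",
        sequences={
            "a": "ACGTAC",
            "b": "ACGTAC",
            "c": "ATGTAC",
            "d": "ATGAAC",
        },
        length=6,
        alphabet="nucleotide",
    )
    g2 = GeneAlignment(
        gene_id="geneB",
        sequences={"a": "GGAA", "b": "GGAA", "c": "GCAA"},
        length=4,
        alphabet="nucleotide",
    )
    return [g1, g2]


def small_sim_config(**overrides) -> SimConfig:
    """A seconds-scale dataset for end-to-end tests."""
    kw = dict(
        n_in=8,
        n_out=8,
        n_genes=8,
        sites_per_gene=60,
        n_discordant_genes=1,
        seed=0,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_dataset():
    res = simulate_dataset(small_sim_config())
    bal = balance_classes(res.hypothesis, seed=0)
    data = one_hot_encode(res.genes, bal.selected_taxa, bal.y)
    return res, bal, data


@pytest.fixture(scope="session")
def small_ensemble(small_dataset):
    _, _, data = small_dataset
    return run_grid(data, GridConfig())


@pytest.fixture(scope="session")
def default_dataset():
    """The default study fixture: 20+20 taxa, 30 genes, 200 sites."""
    res = simulate_dataset(SimConfig())
    bal = balance_classes(res.hypothesis, seed=0)
    data = one_hot_encode(res.genes, bal.selected_taxa, bal.y)
    return res, bal, data


@pytest.fixture(scope="session")
def default_ensemble(default_dataset):
    _, _, data = default_dataset
    return run_grid(data, GridConfig())


@pytest.fixture(scope="session")
def default_report(default_dataset, default_ensemble):
    _, _, data = default_dataset
    return build_report(default_ensemble, data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
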