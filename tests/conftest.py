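"""Shared fixtures: trees, small synthetic databases, toy proteomes."""

from __future__ import annotations

import numpy as np
import pytest

from evonet.data_io import Phylogeny
from evonet.network_evolution import SENSU_STRICTO_NEWICK
from evonet.pipe_engine import PipeConfig
from evonet.synthetic_data import DEFAULT_TREE_NEWICK, SynthConfig, generate_database

SPECIES = ("Sbay", "Skud", "Smik", "Spar", "Scer")


@pytest.fixture(scope="session")
def ladder_tree() -> Phylogeny:
    """Rooted ladder topology of the five-species clade (no branch lengths)."""
    return Phylogeny.from_newick(SENSU_STRICTO_NEWICK)


@pytest.fixture(scope="session")
def sim_tree() -> Phylogeny:
    """Same topology with branch lengths in substitutions per codon."""
    return Phylogeny.from_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture(scope="session")
def small_db():
    """A small planted-motif database: quick to score, non-trivial signal."""
    config = SynthConfig(
        n_proteins=36, n_edges=36, mean_length=150, min_length=50, seed=5
    )
    return generate_database(config)


@pytest.fixture(scope="session")
def pipe_config() -> PipeConfig:
    return PipeConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
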