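import numpy as np
import pandas as pd
import pytest

import kerndep as kd


@pytest.fixture(scope="session")
def small_config() -> kd.SimulationConfig:
    """Desk-size bundle for fast unit tests (not the study-scale conditions)."""
    return kd.SimulationConfig(n_genes=60, n_cells=80, n_shell1=12, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> kd.SyntheticBundle:
    return kd.make_bundle(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    directory = tmp_path_factory.mktemp("bundle")
    kd.write_bundle(small_bundle, directory)
    return directory


@pytest.fixture(scope="session")
def small_network(small_bundle_dir) -> kd.InteractionNetwork:
    return kd.build_network(
        small_bundle_dir / "protein_links.txt",
        small_bundle_dir / "protein_aliases.txt",
        focal="KRAS",
    )


def edge_frame(pairs, weights=None) -> pd.DataFrame:
    """Gene-level edge list helper: pairs of symbols, optional weights."""
    if weights is None:
        weights = [1.0] * len(pairs)
    a = [min(p) for p in pairs]
    b = [max(p) for p in pairs]
    return pd.DataFrame({"gene_a": a, "gene_b": b, "weight": list(weights)})


def path_network(genes) -> kd.InteractionNetwork:
    """A simple path graph network centered on its middle gene."""
    pairs = list(zip(genes[:-1], genes[1:]))
    focal = genes[len(genes) // 2]
    return kd.shell_restrict(edge_frame(pairs), focal, shells=len(genes))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
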