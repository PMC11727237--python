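import numpy as np
import pytest

from gdop import SyntheticConfig, make_fixture
from gdop.pathways import Pathway, PathwayCollection
from gdop.ppi import GeneSpace


@pytest.fixture(scope="session")
def small_config():
    """Reduced generator regime for fast unit tests."""
    return SyntheticConfig(
        n_genes=24,
        n_pathways=6,
        pathway_size_range=(3, 5),
        n_compounds=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    return make_fixture(small_config, tmp_path_factory.mktemp("bundle"))


@pytest.fixture
def gene_space5():
    return GeneSpace(["GA", "GB", "GC", "GD", "GE"])


def make_collection(sizes, prefix="P"):
    """Collection of pathways with given gene-set sizes over a shared pool."""
    paths = []
    for k, size in enumerate(sizes):
        genes = frozenset(f"G{k}_{i}" for i in range(size))
        paths.append(Pathway(id=f"{prefix}{k}", description="d", genes=genes))
    return PathwayCollection(paths)


@pytest.fixture
def write_gmt_file(tmp_path):
    def _write(lines, name="sets.gmt"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
        return p

    return _write
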