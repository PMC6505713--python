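import numpy as np
import pytest

from tilescope import pipeline
from tilescope.types import IntensityMatrix


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small synthetic input bundle shared by I/O and pipeline tests."""
    outdir = tmp_path_factory.mktemp("fixture")
    config, truth = pipeline.make_fixture(
        outdir, seed=11, genome_length=30_000, n_genes=8, n_novel=4
    )
    return config, truth


def build_matrix(values, n_replicates=None):
    """IntensityMatrix from a (probes x samples) array, first half reference."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1] // 2 if n_replicates is None else n_replicates
    return IntensityMatrix(
        probe_ids=[f"p{i}" for i in range(values.shape[0])],
        values=values,
        conditions=["reference"] * n + ["treated"] * (values.shape[1] - n),
        replicates=list(range(1, n + 1))
        + list(range(1, values.shape[1] - n + 1)),
    )


@pytest.fixture
def matrix_builder():
    return build_matrix
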