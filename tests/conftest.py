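import numpy as np
import pytest

from citemo import CountMatrix, generate_cite_seq, run_pipeline
from citemo.synthetic import preset


@pytest.fixture
def small_rna():
    return CountMatrix(
        np.array([[0, 2], [1, 0], [5, 5]]), ["G1", "G2", "G3"], ["c1", "c2"], "rna"
    )


@pytest.fixture
def small_adt():
    rng = np.random.default_rng(7)
    return CountMatrix(
        rng.integers(1, 40, size=(4, 6)),
        ["CD3", "CD4", "CD8", "CD19"],
        [f"c{i}" for i in range(6)],
        "adt",
    )


@pytest.fixture(scope="session")
def mixed_five_data():
    """Five synthetic clusters: two RNA-only separable, two ADT-only, one both."""
    return generate_cite_seq(preset("mixed_five"))


@pytest.fixture(scope="session")
def mixed_five_bundle(mixed_five_data, tmp_path_factory):
    """Full pipeline run on mixed_five under the cord-blood analysis style
    (10 RNA PCs, ADT passthrough, 15 multimodal PCs); shared across tests."""
    rna, adt, labels = mixed_five_data
    out = tmp_path_factory.mktemp("mixed_five_out")
    cfg = {"preset": "cbmc_like", "qc.drop_adts": [], "output.dir": str(out)}
    bundle = run_pipeline(cfg, rna=rna, adt=adt)
    return bundle, labels, out
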