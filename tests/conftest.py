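import numpy as np
import pytest

from mammotv import SyntheticSpec, default_specs, extract_all, generate_patches
from mammotv.backbones import FeatureMatrix

TINY_COUNTS = {
    ("D", "normal"): 4, ("D", "benign"): 3, ("D", "malignant"): 3,
}

MULTI_TISSUE_COUNTS = {
    (t, c): n
    for t in ("D", "F", "G")
    for c, n in (("normal", 4), ("benign", 3), ("malignant", 3))
}


@pytest.fixture(scope="session")
def tiny_spec():
    """10 patches, one tissue, small side: enough for dimensional contracts."""
    return SyntheticSpec(counts=dict(TINY_COUNTS), patch_side=64, seed=7, separability=3.0)


@pytest.fixture(scope="session")
def tiny_patches(tiny_spec):
    return generate_patches(tiny_spec)


@pytest.fixture(scope="session")
def tiny_blocks(tiny_patches):
    """All three backbone blocks for the tiny fixture (extracted once)."""
    return extract_all(tiny_patches, default_specs())


@pytest.fixture(scope="session")
def multi_tissue_patches():
    """30 patches across D/F/G with >= 2 per class per tissue."""
    spec = SyntheticSpec(
        counts=dict(MULTI_TISSUE_COUNTS), patch_side=64, seed=11, separability=3.0
    )
    return generate_patches(spec)


@pytest.fixture(scope="session")
def multi_tissue_blocks(multi_tissue_patches):
    return extract_all(multi_tissue_patches, default_specs())


def make_matrix(values, backbone="test", row_prefix="r"):
    """FeatureMatrix from a plain array, with synthetic ids/provenance."""
    values = np.asarray(values, dtype=np.float32)
    return FeatureMatrix(
        values=values,
        row_ids=[f"{row_prefix}{i}" for i in range(values.shape[0])],
        column_provenance=[(backbone, j) for j in range(values.shape[1])],
    )
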