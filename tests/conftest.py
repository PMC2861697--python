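import numpy as np
import pytest

from reginfluence import (
    BindingSite,
    DataBundle,
    SyntheticSpec,
    TSSAnnotation,
    generate_dataset,
)


@pytest.fixture
def toy_genes():
    return [
        TSSAnnotation("gA", "chr1", 100_000, "+"),
        TSSAnnotation("gB", "chr1", 160_000, "-"),
        TSSAnnotation("gC", "chr2", 50_000, "+"),
    ]


@pytest.fixture
def toy_sites():
    return [
        BindingSite("s1", "chr1", 119_900, 120_100, "liver", frozenset({"p300"}), 8.0, 0.6),
        BindingSite("s2", "chr1", 99_400, 99_600, "liver", frozenset({"CEBPA"}), 2.0, 0.2),
        BindingSite("s3", "chr2", 48_900, 49_100, "liver", frozenset(), None, None),
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """A small two-tissue synthetic dataset shared across tests."""
    spec = SyntheticSpec(n_genes=400, seed=42)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_bundle(small_dataset):
    ds = small_dataset
    return DataBundle(ds.genome, ds.sites, ds.expression, *ds.spec.tissues)
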