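import numpy as np
import pytest

from degnet import synthetic_data as sd
from degnet.io_catalog import GeneHit, SampleAnnotation


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study shared by read-only tests."""
    return sd.generate_study(sd.StudyDesign(seed=11))


@pytest.fixture(scope="session")
def catalog():
    return sd.default_catalog()


def random_hits(rng, sample_id="S", n=100):
    """Hits straddling the screening thresholds on both axes."""
    return [
        GeneHit(
            sample_id=sample_id,
            gene_id=f"g{i}",
            family_id=rng.choice(["AlkB", "XylE", "CatA", "NahAc"]),
            bit_score=float(rng.uniform(10.0, 90.0)),
            e_value=float(10.0 ** rng.uniform(-8.0, 0.0)),
        )
        for i in range(n)
    ]


@pytest.fixture
def random_annotation():
    rng = np.random.default_rng(42)
    hits = random_hits(rng, n=500)
    return SampleAnnotation(sample_id="S", total_gene_count=10_000, hits=hits)
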