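import numpy as np
import pytest

from lrkin.composition import GenotypeMatrix
from lrkin.fixtures import make_fixture_cohort
from lrkin.pedigree import HweFounders, build_reference_set


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


@pytest.fixture(scope="session")
def fixture_cohort():
    """Tiny deterministic cohort with documented MZ/PO/FS pairs."""
    return make_fixture_cohort(seed=7)


@pytest.fixture(scope="session")
def small_reference():
    """A modest tracked reference set shared by several tests.

    30 pairs each of a close-to-remote panel at MAF 0.5, 5,000 SNPs.
    """
    founders = HweFounders(0.5, 5_000)
    return build_reference_set(
        ("FS", "3/4S-FS", "HS", "FC", "UN"), founders, 30, seed=501, track_ibd=True
    )


@pytest.fixture
def random_genotypes(rng):
    """10 individuals x 200 variants with some missing calls."""
    d = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
    mask = rng.random(d.shape) < 0.05
    d[mask] = -1
    return GenotypeMatrix(
        dosages=d,
        sample_ids=[f"I{i}" for i in range(10)],
        variant_ids=[f"v{j}" for j in range(200)],
    )
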