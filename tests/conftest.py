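import numpy as np
import pytest

from plurevert.config import PipelineConfig
from plurevert.synthetic_data import generate_genome, toy_pwm_set


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_genome():
    """A 2 x 200 kb genome with 4 CpG islands (session-cached)."""
    return generate_genome(
        seed=42, chrom_sizes={"chr1": 200_000, "chr2": 200_000},
        n_cpg_islands=4,
    )


@pytest.fixture(scope="session")
def peak_genome():
    """A 2 x 1 Mb genome: large enough that flat background coverage sits
    well below the unbound-occupancy RPKM target of the peak generator."""
    return generate_genome(
        seed=43, chrom_sizes={"chr1": 1_000_000, "chr2": 1_000_000},
        n_cpg_islands=4,
    )


@pytest.fixture(scope="session")
def pwms():
    return toy_pwm_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
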