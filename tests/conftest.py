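import numpy as np
import pandas as pd
import pytest

from cnascreen import Aberration, DriverGene, ProbeProfile, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One-driver cohort at the default study conditions (seed fixed)."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture
def step_profile():
    """100-probe profile with a +1.0 step at probe 50, noise SD 0.1."""
    rng = np.random.default_rng(7)
    x = rng.normal(0, 0.1, 100)
    x[50:] += 1.0
    df = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(100) * 1000,
         "end": np.arange(100) * 1000 + 60, "log2": x}
    )
    return ProbeProfile("s1", df, normalized=True)


def make_profile(values, chrom="chr1", sample="s", normalized=True):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        {"chrom": chrom, "start": np.arange(values.size) * 1000,
         "end": np.arange(values.size) * 1000 + 60, "log2": values}
    )
    return ProbeProfile(sample, df, normalized=normalized)
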