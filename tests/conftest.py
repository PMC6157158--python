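import numpy as np
import pytest
from hypothesis import settings

from groupscreen.design import Group, GroupedDesign

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Aligned synthetic cohort with CpGs, SNPs and one causal interaction."""
    from groupscreen.synth import simulate_dataset

    return simulate_dataset(
        n=150,
        m_cpg=60,
        m_snp=40,
        n_causal_cpg=2,
        n_causal_snp=1,
        n_interactions=1,
        chrom_length=150_000,
        colocation_fraction=0.05,
        noise_sd=0.5,
        seed=11,
    )


def make_design(X, y, sizes, weights=None, kinds=None):
    """GroupedDesign from a plain matrix and a list of group sizes."""
    groups = []
    s = 0
    for j, d in enumerate(sizes):
        w = np.sqrt(d) if weights is None else weights[j]
        kind = "cpg" if kinds is None else kinds[j]
        groups.append(Group(f"g{j}", s, s + d, w, kind, (j,), pos=j + 1))
        s += d
    assert s == X.shape[1]
    return GroupedDesign(X=np.asarray(X, float), y=np.asarray(y, float), groups=groups)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
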