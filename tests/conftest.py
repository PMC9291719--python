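import numpy as np
import pytest

from snpfs.config import AnalysisConfig
from snpfs import workflow as wf


@pytest.fixture(scope="session")
def planted_study():
    """A 2,000-sample cohort with 10 feature sets and one planted causal FS.

    The causal SNPs are private to the planted FS (not shared through the
    druggable gene), so feature-set recurrence can single it out.
    """
    cfg = AnalysisConfig(n_samples=2000, base_seed=7, n_runs=20, n_permutations=5,
                         population=8, generations=8)
    return cfg, wf.build_synthetic_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
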