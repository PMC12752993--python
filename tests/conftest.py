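import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polyclust.sumstats import HarmonizedZMatrix

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(absz: np.ndarray, snp_ids=None, phenotypes=None) -> HarmonizedZMatrix:
    """Build a harmonized |z| matrix from a raw array (test helper)."""
    absz = np.asarray(absz, dtype=float)
    n, p = absz.shape
    snp_ids = snp_ids or [f"s{i:04d}" for i in range(n)]
    phenotypes = phenotypes or [f"ph{j}" for j in range(p)]
    df = pd.DataFrame(absz, index=pd.Index(snp_ids, name="snp_id"), columns=phenotypes)
    return HarmonizedZMatrix(absz=df, signed_z=pd.DataFrame(index=df.index))


@pytest.fixture
def two_block_matrix():
    """60 SNPs in two well-separated profile blocks (plus distinct noise rows)."""
    rng = np.random.default_rng(7)
    a = np.array([4.0, 1.0, 0.5]) + rng.normal(0, 0.2, size=(30, 3))
    b = np.array([0.5, 1.0, 4.0]) + rng.normal(0, 0.2, size=(30, 3))
    return make_matrix(np.vstack([a, b]))
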