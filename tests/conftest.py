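import numpy as np
import pytest

from mrmediate import HarmonizedInstrumentSet


def make_hset(bx, by, se_by, se_bx=None, eaf=None, n_exp=100_000, n_out=100_000,
              snp_ids=None, exposure="exposure", outcome="outcome"):
    """Build a univariable harmonized set from raw effect vectors."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    se_by = np.broadcast_to(np.asarray(se_by, float), bx.shape).copy()
    se_bx = np.full_like(bx, 1e-6) if se_bx is None else np.broadcast_to(
        np.asarray(se_bx, float), bx.shape).copy()
    eaf = np.full_like(bx, 0.3) if eaf is None else np.asarray(eaf, float)
    k = len(bx)
    ids = snp_ids or [f"rs{i+1}" for i in range(k)]
    return HarmonizedInstrumentSet(
        snp_ids=ids, exposure_names=[exposure], outcome_name=outcome,
        beta_exposure=bx, se_exposure=se_bx, eaf_exposure=eaf,
        n_exposure=np.full(k, n_exp, float), beta_outcome=by,
        se_outcome=se_by, n_outcome=np.full(k, n_out, float),
    )


@pytest.fixture
def hset_2snp():
    """The two-SNP worked instance: weights 625/2500, IVW beta 0.16."""
    return make_hset([0.1, 0.2], [0.02, 0.03], [0.004, 0.004])


@pytest.fixture
def hset_3snp():
    """Equal-weight Egger instance: slope 0.2, intercept 0.01."""
    return make_hset([0.1, 0.2, 0.3], [0.03, 0.05, 0.07], [0.01, 0.01, 0.01])
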