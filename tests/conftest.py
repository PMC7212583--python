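import numpy as np
import pytest

from pwmbench import PFM, random_pfm, regularize


@pytest.fixture
def uniform_pfm():
    def make(L=2, matrix_id="uniform"):
        return PFM(matrix_id, np.full((L, 4), 0.25))
    return make


@pytest.fixture
def regular_random_pfm():
    """A regularized random PFM factory (strictly positive entries)."""
    def make(L=6, concentration=0.5, seed=0, matrix_id="rand"):
        return regularize(random_pfm(L, concentration, seed, matrix_id))
    return make


def brute_force_auc(pos, neg):
    """Independent AUC oracle: explicit pair counting with half-tie credit."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (pos.size * neg.size)
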