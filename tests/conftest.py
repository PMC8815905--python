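import numpy as np
import pytest
from hypothesis import settings

from synwalk.nmf import NmfSettings
from synwalk.synth import SynthConfig, synthesize_envelopes
from synwalk.templates import MUSCLES, make_canonical_modules

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def templates():
    return make_canonical_modules(MUSCLES)


@pytest.fixture(scope="session")
def fast_nmf():
    """Reduced restart count for desk-scale factorizations."""
    return NmfSettings(n_restarts=10, seed=0)


@pytest.fixture(scope="session")
def clean_four_module():
    """Noiseless 8-muscle envelopes from 4 canonical modules, 20 strides."""
    cfg = SynthConfig(n_strides=20, noise_sd=0.0, seed=1)
    V, gt = synthesize_envelopes(cfg)
    return V, gt


@pytest.fixture(scope="session")
def merged_34():
    """Noiseless 3-synergy envelopes with modules 3 and 4 merged."""
    cfg = SynthConfig(n_strides=20, noise_sd=0.0, merge_pair=(3, 4), seed=2)
    V, gt = synthesize_envelopes(cfg)
    return V, gt


def greedy_match_cosines(W_rec: np.ndarray, W_true: np.ndarray) -> np.ndarray:
    """Cosine of each true column to its best-matching recovered column,
    under a greedy one-to-one assignment (highest cosine first)."""
    cos = np.zeros((W_rec.shape[1], W_true.shape[1]))
    for i in range(W_rec.shape[1]):
        for j in range(W_true.shape[1]):
            a, b = W_rec[:, i], W_true[:, j]
            cos[i, j] = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
    matched = []
    used_i, used_j = set(), set()
    flat = sorted(
        ((cos[i, j], i, j) for i in range(cos.shape[0]) for j in range(cos.shape[1])),
        reverse=True,
    )
    for c, i, j in flat:
        if i not in used_i and j not in used_j:
            matched.append(c)
            used_i.add(i)
            used_j.add(j)
    return np.array(matched)
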