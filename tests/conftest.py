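import numpy as np
import pytest

from pscn.hmm import ASSIGNMENT, HmmHyperParams
from pscn.io import AlleleSignalTrack


def make_track(u, chrom="1"):
    """Wrap an (n, 2) intensity array as a track."""
    u = np.asarray(u, dtype=float)
    n = len(u)
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    return AlleleSignalTrack(ids, chrom, np.arange(1, n + 1),
                             u[:, 0], u[:, 1])


def emit(g, theta, rng=None, sigma=0.15):
    """Noisy emissions for genotype codes g at states theta."""
    g = np.asarray(g)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim == 1:
        theta = np.tile(theta, (len(g), 1))
    u = np.einsum("tij,tj->ti", ASSIGNMENT[g], theta)
    if rng is not None:
        u = u + sigma * rng.standard_normal(u.shape)
    return u


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def hp_loose():
    """Jump rates large enough for changepoints to matter at tiny n."""
    return HmmHyperParams(p=0.05, r=0.08, s=0.02)
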