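import numpy as np
import pytest

from drowsetune import MusicStyleProfile, gen_notes
from drowsetune.eeg import build_patterns


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_cluster_patterns(n_per_class=60, n=3, noise=0.03, seed=0):
    """Two RE-space clusters: drowsy with high alpha, alert with high beta.

    Cluster centres (per window) are RE = (0.05, 0.1, 0.8, 0.05) for drowsy
    and (0.05, 0.1, 0.2, 0.65) for alert, with small Gaussian jitter —
    linearly separable with a wide margin.
    """
    rng = np.random.default_rng(seed)
    drowsy_c = np.array([0.05, 0.10, 0.80, 0.05])
    alert_c = np.array([0.05, 0.10, 0.20, 0.65])
    X, y = [], []
    for centre, label in ((drowsy_c, 1), (alert_c, 0)):
        for _ in range(n_per_class):
            windows = centre + rng.normal(0, noise, size=(n, 4))
            windows = np.clip(windows, 1e-6, None)
            windows /= windows.sum(axis=1, keepdims=True)
            X.append(windows.ravel())
            y.append(label)
    X = np.array(X)
    y = np.array(y)
    order = rng.permutation(len(y))
    return X[order], y[order]


@pytest.fixture(scope="session")
def separable_patterns():
    return make_cluster_patterns()


@pytest.fixture(scope="session")
def melody():
    return gen_notes(MusicStyleProfile(), n_notes=30, seed=7)


def sliding_pattern_oracle(res, n):
    """Enumerate sliding windows by explicit loop (independent of stride tricks)."""
    return [np.concatenate([res[i + j] for j in range(n)]) for i in range(len(res) - n + 1)]


def dft_psd_oracle(x):
    """O(T^2) discrete-Fourier-sum power spectrum, bins 1..T/2."""
    T = len(x)
    out = []
    for k in range(1, T // 2 + 1):
        coeff = sum(x[t] * np.exp(-2j * np.pi * k * t / T) for t in range(T))
        out.append(abs(coeff) ** 2)
    return np.array(out)
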