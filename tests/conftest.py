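import numpy as np
import pytest

from mammofuse.preprocess import MammogramROI, PreprocessedROI


def as_proi(arr, parent=None) -> PreprocessedROI:
    """Wrap a raw float array as a fully-content PreprocessedROI (no padding)."""
    a = np.asarray(arr, dtype=np.float64)
    return PreprocessedROI(
        pixels=a, scale_factor=1.0, pad_offsets=(0, 0), content_shape=a.shape, parent=parent
    )


def sample_gmrf(theta, shape=(128, 128), sweeps=80, sigma=1.0, seed=0):
    """Gibbs sampler for a second-order symmetric Gaussian Markov random field.

    Independent of the package's estimator: four-color checkerboard updates of
    the conditional normal distributions on a torus.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(shape) * sigma
    th_h, th_v, th_d, th_ad = theta
    for _ in range(sweeps):
        for pr in (0, 1):
            for pc in (0, 1):
                mean = (
                    th_h * (np.roll(x, 1, 1) + np.roll(x, -1, 1))
                    + th_v * (np.roll(x, 1, 0) + np.roll(x, -1, 0))
                    + th_d * (np.roll(np.roll(x, 1, 0), 1, 1) + np.roll(np.roll(x, -1, 0), -1, 1))
                    + th_ad * (np.roll(np.roll(x, 1, 0), -1, 1) + np.roll(np.roll(x, -1, 0), 1, 1))
                )
                upd = rng.standard_normal(shape) * sigma + mean
                x[pr::2, pc::2] = upd[pr::2, pc::2]
    return x


def pair_count_auc(scores, y) -> float:
    """Tie-corrected Mann-Whitney AUC by brute-force pair counting."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    conc = (pos > neg).sum()
    ties = (pos == neg).sum()
    return (conc + 0.5 * ties) / (pos.size * neg.size)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gradient_roi():
    """A deterministic textured ROI: diagonal ramp plus sinusoidal modulation."""
    n = 64
    i, j = np.mgrid[0:n, 0:n]
    a = (i + j) / (2 * (n - 1)) * 0.7 + 0.1 * np.sin(i / 3.0) * np.cos(j / 5.0) + 0.1
    a = a + 0.08 * np.random.default_rng(7).random((n, n))
    return as_proi(np.clip(a, 0, 1))


@pytest.fixture
def raw_roi(rng):
    px = rng.integers(100, 40000, size=(50, 70))
    return MammogramROI(pixels=px, patient_id="P1", roi_id="r1", label="benign")
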