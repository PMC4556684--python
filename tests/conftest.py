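import numpy as np
import pytest

from afmse.preprocess import BeatSeries


def naive_sampen_counts(x, m, tol):
    """Naive O(N^2) template-match counter (independent oracle).

    Same conventions as the optimized kernel: both counts over the N-m
    templates that admit an (m+1)-length extension, pairs i<j, Chebyshev
    distance, strict < tol.
    """
    x = np.asarray(x, dtype=float)
    t = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    dm = np.max(np.abs(t[:, None, :m] - t[None, :, :m]), axis=-1)
    dm1 = np.max(np.abs(t[:, None, :] - t[None, :, :]), axis=-1)
    iu = np.triu_indices(len(t), k=1)
    return int(np.sum(dm1[iu] < tol)), int(np.sum(dm[iu] < tol))


def naive_sampen_counts_loops(x, m, tol):
    """Pure double-loop reference for tiny series."""
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < tol:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < tol:
                    a += 1
    return a, b


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_beats():
    """Three all-N beats 0.8 s apart."""
    return BeatSeries(np.array([0.0, 0.8, 1.6]), np.array(["N", "N", "N"]))
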