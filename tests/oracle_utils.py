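"""Naive double-loop oracles for weighted moments and correlations.

These share no code with the batched statistics engine: explicit Python
accumulation loops, circular shifts via np.roll on full maps, block-mean
downsampling by explicit 2x2 averaging.
"""

import numpy as np

from ttmlab.statistics import VAR_EPS


def naive_moments(w, x):
    """Weighted mean/var/skew/kurt by explicit accumulation."""
    w = w / w.sum()
    mu = 0.0
    for wi, xi in zip(w.ravel(), x.ravel()):
        mu += wi * xi
    m2 = m3 = m4 = 0.0
    for wi, xi in zip(w.ravel(), x.ravel()):
        d = xi - mu
        m2 += wi * d**2
        m3 += wi * d**3
        m4 += wi * d**4
    if m2 < VAR_EPS:
        return mu, m2, 0.0, 0.0
    return mu, m2, m3 / m2**1.5, m4 / m2**2


def naive_wcorr(w, a, b):
    """Weighted Pearson correlation with the degenerate-variance rule."""
    w = w / w.sum()
    ma = sum(wi * ai for wi, ai in zip(w.ravel(), a.ravel()))
    mb = sum(wi * bi for wi, bi in zip(w.ravel(), b.ravel()))
    va = vb = cov = 0.0
    for wi, ai, bi in zip(w.ravel(), a.ravel(), b.ravel()):
        va += wi * (ai - ma) ** 2
        vb += wi * (bi - mb) ** 2
        cov += wi * (ai - ma) * (bi - mb)
    if va < VAR_EPS or vb < VAR_EPS:
        return 0.0
    return cov / np.sqrt(va * vb)


def naive_downsample(w):
    """2x block mean by explicit loops."""
    h, wd = w.shape
    out = np.zeros((h // 2, wd // 2))
    for i in range(h // 2):
        for j in range(wd // 2):
            out[i, j] = w[2 * i:2 * i + 2, 2 * j:2 * j + 2].mean()
    return out
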