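"""Independent brute-force oracles used to validate the thresholding code.

Everything here is deliberately written as plain-Python loops over the
histogram, independent of the vectorized implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


def otsu_brute_force(hist) -> int:
    """Exhaustive between-class-variance scan over all 255 cut points."""
    h = [float(c) for c in hist]
    total = sum(h)
    best_level, best_var = 0, -1.0
    for t in range(255):
        w0 = sum(h[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(i * h[i] for i in range(t + 1)) / w0
        mu1 = sum(i * h[i] for i in range(t + 1, 256)) / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_level = var, t
    return best_level


def tsai_moments_cleanroom(hist) -> int:
    """Direct transcription of Tsai's moment-preserving closed form.

    Computes m1..m3, the auxiliary c0/c1, the representative levels
    z0/z1 and the dark-class fraction p0, then picks the p0-percentile
    of the cumulative histogram.
    """
    h = [float(c) for c in hist]
    total = sum(h)
    p = [c / total for c in h]
    m1 = sum(i * p[i] for i in range(256))
    m2 = sum(i * i * p[i] for i in range(256))
    m3 = sum(i * i * i * p[i] for i in range(256))
    cd = m2 - m1 * m1
    if cd <= 1e-12:
        return max(range(256), key=lambda i: h[i])
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return max(range(256), key=lambda i: h[i])
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    if z1 == z0:
        return max(range(256), key=lambda i: h[i])
    p0 = (z1 - m1) / (z1 - z0)
    cum = 0.0
    for t in range(256):
        cum += p[t]
        if cum >= p0 - 1e-12:
            return t
    return 255


def cross_entropy(hist, t: int) -> float:
    """Li cross-entropy objective of cut level ``t`` (+1 gray shift)."""
    h = [float(c) for c in hist]
    wb = sum(h[: t + 1])
    wf = sum(h[t + 1:])
    if wb == 0 or wf == 0:
        return float("inf")
    sb = sum((i + 1.0) * h[i] for i in range(t + 1))
    sf = sum((i + 1.0) * h[i] for i in range(t + 1, 256))
    return -sb * math.log(sb / wb) - sf * math.log(sf / wf)


def cross_entropy_scan(hist) -> int:
    """Exhaustive minimum cross-entropy scan (Li criterion).

    Uses the same +1 gray-value shift as the implementation so the two
    optimize the identical objective; the search itself is independent.
    """
    h = [float(c) for c in hist]
    best_level, best_ce = 0, float("inf")
    for t in range(255):
        wb = sum(h[: t + 1])
        wf = sum(h[t + 1:])
        if wb == 0 or wf == 0:
            continue
        sb = sum((i + 1.0) * h[i] for i in range(t + 1))
        sf = sum((i + 1.0) * h[i] for i in range(t + 1, 256))
        mu_b, mu_f = sb / wb, sf / wf
        ce = -sb * math.log(mu_b) - sf * math.log(mu_f)
        if ce < best_ce:
            best_ce, best_level = ce, t
    return best_level


def random_histograms(n: int, seed: int) -> list[np.ndarray]:
    """Assorted random 256-bin histograms: mixtures, uniforms, sparse."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        kind = rng.integers(0, 3)
        if kind == 0:  # two-Gaussian mixture
            m1, m2 = sorted(rng.uniform(10, 245, size=2))
            sd1, sd2 = rng.uniform(3, 25, size=2)
            n1, n2 = rng.integers(200, 5000, size=2)
            vals = np.concatenate([
                rng.normal(m1, sd1, int(n1)), rng.normal(m2, sd2, int(n2))])
            hist = np.bincount(np.clip(np.round(vals), 0, 255).astype(int),
                               minlength=256)
        elif kind == 1:  # rough uniform counts
            hist = rng.integers(0, 50, size=256)
            if hist.sum() == 0:
                hist[rng.integers(0, 256)] = 1
        else:  # sparse spikes
            hist = np.zeros(256, dtype=int)
            spikes = rng.integers(2, 8)
            pos = rng.choice(256, size=spikes, replace=False)
            hist[pos] = rng.integers(1, 2000, size=spikes)
        out.append(np.asarray(hist, dtype=np.int64))
    return out
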