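"""Independent brute-force / textbook reference implementations used to
cross-check the package's statistics. Everything here is written from the
defining formulas, never by calling the code paths under test."""

from __future__ import annotations

import numpy as np
from scipy.stats import t as t_dist


def kappa_oracle(pred, truth) -> float:
    """Cohen's Kappa from the raw contingency counts."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    n = len(pred)
    classes = sorted(set(pred) | set(truth))
    p_o = sum(p == t for p, t in zip(pred, truth)) / n
    p_e = 0.0
    for c in classes:
        p_e += (np.sum(pred == c) / n) * (np.sum(truth == c) / n)
    if p_e >= 1 - 1e-15:
        return 1.0 if p_o >= 1 - 1e-15 else 0.0
    return (p_o - p_e) / (1 - p_e)


def mmcc_oracle(pred, truth) -> float:
    """Multi-class Matthews correlation (R_K) from the confusion matrix:
    (c*s - sum_k p_k t_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))."""
    pred, truth = np.asarray(pred), np.asarray(truth)
    classes = sorted(set(pred) | set(truth))
    k = len(classes)
    C = np.zeros((k, k))
    index = {c: i for i, c in enumerate(classes)}
    for p, t in zip(pred, truth):
        C[index[t], index[p]] += 1
    s = C.sum()
    c = np.trace(C)
    p_k = C.sum(axis=0)  # predicted-as-k totals
    t_k = C.sum(axis=1)  # truly-k totals
    num = c * s - (p_k * t_k).sum()
    den = np.sqrt(s**2 - (p_k**2).sum()) * np.sqrt(s**2 - (t_k**2).sum())
    if den == 0:
        return 0.0
    return num / den


def binary_mcc_oracle(pred, truth, positive) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    tp = np.sum((pred == positive) & (truth == positive))
    tn = np.sum((pred != positive) & (truth != positive))
    fp = np.sum((pred == positive) & (truth != positive))
    fn = np.sum((pred != positive) & (truth == positive))
    den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    if den == 0:
        return 0.0
    return (tp * tn - fp * fn) / den


def pearson_oracle(x, y):
    """Textbook Pearson r with the exact t-based two-tailed p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    r = (xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum())
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * t_dist.sf(abs(t), df=n - 2)
    return r, p


def one_sample_t_oracle(x, popmean=0.0):
    """t = (mean - mu) / (s / sqrt(n)), two-tailed p from the t CDF."""
    x = np.asarray(x, float)
    n = len(x)
    sd = np.sqrt(((x - x.mean())**2).sum() / (n - 1))
    t = (x.mean() - popmean) / (sd / np.sqrt(n))
    p = 2 * t_dist.sf(abs(t), df=n - 1)
    return t, p


def ad_ksample_oracle(samples) -> float:
    """Scholz–Stephens k-sample Anderson–Darling statistic, tie-corrected
    (midrank) A2akN form, returned on the normalized scale
    (A2akN - (k-1)) / sigma_N."""
    samples = [np.sort(np.asarray(s, float)) for s in samples]
    k = len(samples)
    n = np.array([len(s) for s in samples])
    pooled = np.sort(np.concatenate(samples))
    N = len(pooled)
    z, counts = np.unique(pooled, return_counts=True)
    L = len(z)

    a2 = 0.0
    for i in range(k):
        inner = 0.0
        for j in range(L):
            lj = counts[j]
            # midrank counts: observations strictly below z_j plus half ties
            maij = np.searchsorted(samples[i], z[j], side="left") \
                + 0.5 * (np.searchsorted(samples[i], z[j], side="right")
                         - np.searchsorted(samples[i], z[j], side="left"))
            baj = np.searchsorted(pooled, z[j], side="left") \
                + 0.5 * (np.searchsorted(pooled, z[j], side="right")
                         - np.searchsorted(pooled, z[j], side="left"))
            denom = baj * (N - baj) - N * lj / 4.0
            if denom > 0:
                inner += (lj / N) * (N * maij - n[i] * baj)**2 / denom
        a2 += inner / n[i]
    a2 *= (N - 1.0) / N

    # variance of A2akN under H0 (Scholz & Stephens 1987)
    H = (1.0 / n).sum()
    h = (1.0 / np.arange(1, N)).sum()
    g = 0.0
    for i in range(1, N - 1):
        g += (1.0 / ((N - i) * np.arange(i + 1, N))).sum()
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h \
        + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k \
        + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return (a2 - (k - 1)) / np.sqrt(var)


def stationary_oracle(matrix, tol=1e-13, max_iter=100000) -> np.ndarray:
    """Stationary distribution by fixed-point iteration pi <- pi T."""
    matrix = np.asarray(matrix, float)
    pi = np.full(matrix.shape[0], 1.0 / matrix.shape[0])
    for _ in range(max_iter):
        nxt = pi @ matrix
        if np.abs(nxt - pi).max() < tol:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()
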