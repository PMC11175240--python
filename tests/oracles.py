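"""Independent brute-force oracles used to validate the implementations.

Every function here is written from the defining formula, deliberately
avoiding the package's own code paths (direct double loops, exhaustive
enumeration, tangent-space integration), so agreement is a real check.
"""

from __future__ import annotations

import numpy as np


def brute_fourier_amplitudes(segment: np.ndarray, n_harm: int) -> np.ndarray:
    """Harmonic amplitudes by direct projection onto sin/cos at each harmonic."""
    n = len(segment)
    t = np.arange(n) / n
    amps = np.empty(n_harm)
    for h in range(1, n_harm + 1):
        c = (2.0 / n) * np.sum(segment * np.cos(2 * np.pi * h * t))
        s = (2.0 / n) * np.sum(segment * np.sin(2 * np.pi * h * t))
        amps[h - 1] = np.hypot(c, s)
    return amps


def brute_ami(series: np.ndarray, lag: int, bins: int = 16) -> float:
    """Average mutual information by an explicit double-loop histogram."""
    x = np.asarray(series, dtype=float)
    lo, hi = x.min(), x.max()
    edges = np.linspace(lo, hi, bins + 1)
    edges[-1] += 1e-12
    a = x[: len(x) - lag] if lag else x
    b = x[lag:]
    joint = np.zeros((bins, bins))
    for u, v in zip(a, b):
        i = int(np.searchsorted(edges, u, side="right") - 1)
        j = int(np.searchsorted(edges, v, side="right") - 1)
        joint[min(i, bins - 1), min(j, bins - 1)] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
    return mi


def brute_rqa(series: np.ndarray, m: int, tau: int, radius: float,
              theiler: int, l_min: int = 2, literal: bool = False):
    """%recurrence and %determinism by an O(N^2) matrix and explicit line scan."""
    x = np.asarray(series, dtype=float)
    N = len(x) - (m - 1) * tau
    emb = np.array([[x[i + k * tau] for k in range(m)] for i in range(N)])
    R = np.zeros((N, N), dtype=int)
    for i in range(N):
        for j in range(N):
            if not literal and abs(i - j) <= theiler:
                continue
            if np.sqrt(np.sum((emb[i] - emb[j]) ** 2)) <= radius:
                R[i, j] = 1
    rec = 100.0 * R.sum() / (N * N)
    # scan every diagonal for maximal runs
    num = 0.0
    den = 0.0
    offsets = range(-(N - 1), N)
    for off in offsets:
        if not literal and abs(off) <= theiler:
            continue
        if off >= 0:
            cells = [(i, i + off) for i in range(N - off)]
        else:
            cells = [(i - off, i) for i in range(N + off)]
        run = 0
        for (i, j) in cells:
            if R[i, j]:
                run += 1
            else:
                if run:
                    den += run
                    if run >= l_min:
                        num += run
                run = 0
        if run:
            den += run
            if run >= l_min:
                num += run
    det = 0.0 if den == 0 else 100.0 * num / den
    return rec, det


def benettin_lle(n_steps: int = 30000, dt: float = 0.002, seed: int = 0) -> float:
    """Largest Lyapunov exponent of the Lorenz system by tangent-space
    integration with repeated renormalisation (Benettin's method)."""
    sigma, rho, beta = 10.0, 28.0, 8.0 / 3.0
    rng = np.random.default_rng(seed)

    def f(s):
        x, y, z = s
        return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])

    def jac(s):
        x, y, z = s
        return np.array([[-sigma, sigma, 0.0],
                         [rho - z, -1.0, -x],
                         [y, x, -beta]])

    s = np.array([1.0, 1.0, 20.0]) + 0.1 * rng.standard_normal(3)
    for _ in range(10000):
        k1 = f(s); k2 = f(s + dt / 2 * k1)
        k3 = f(s + dt / 2 * k2); k4 = f(s + dt * k3)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    acc = 0.0
    for _ in range(n_steps):
        k1 = f(s); k2 = f(s + dt / 2 * k1)
        k3 = f(s + dt / 2 * k2); k4 = f(s + dt * k3)
        v = v + dt * (jac(s) @ v)
        s = s + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        nv = np.linalg.norm(v)
        acc += np.log(nv)
        v /= nv
    return acc / (n_steps * dt)


def brute_ks(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic by sweeping the empirical CDFs over all values."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    d = 0.0
    for x in grid:
        fa = np.sum(a <= x) / len(a)
        fb = np.sum(b <= x) / len(b)
        d = max(d, abs(fa - fb))
    return d


def brute_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the concordant-pair fraction with ties counted as 1/2."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_smote_sample(X: np.ndarray, k: int, n_new: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Reference SMOTE: explicit neighbour search and interpolation."""
    out = np.empty((n_new, X.shape[1]))
    for s in range(n_new):
        i = rng.integers(len(X))
        d = np.sqrt(((X - X[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        nn = np.argsort(d, kind="stable")[:k]
        j = nn[rng.integers(k)]
        u = rng.random()
        out[s] = X[i] + u * (X[j] - X[i])
    return out


def mc_power(n: int, delta: float, alpha: float = 0.05,
             n_reps: int = 100000, seed: int = 0) -> float:
    """Monte-Carlo power of the two-sided two-sample t-test (vectorised)."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_reps, n)) + delta
    b = rng.standard_normal((n_reps, n))
    t, p = stats.ttest_ind(a, b, axis=1)
    return float(np.mean(p < alpha))
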