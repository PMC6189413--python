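"""Independent reference implementations used to pin the package's semantics.

Everything here is deliberately written by a different route than the package:
closed-form weight matrices instead of recursions, explicit sort/split loops
instead of groupby pipelines, projection matrices instead of mean tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ewma_matrix(n: int, eta: float) -> np.ndarray:
    """Exact weight matrix of the forward pass y[t] = eta x[t] + (1-eta) y[t-1].

    Unrolling the recursion with y[0] = x[0] gives
    y[t] = a^t x[0] + eta * sum_{j=1..t} a^(t-j) x[j],  a = 1 - eta.
    """
    a = 1.0 - eta
    F = np.zeros((n, n))
    for t in range(n):
        F[t, 0] = a**t
        for j in range(1, t + 1):
            F[t, j] = eta * a ** (t - j)
    return F


def smooth_matrix(n: int, eta: float) -> np.ndarray:
    """Weight matrix of the forward-backward (zero-phase) smoother."""
    F = ewma_matrix(n, eta)
    R = np.eye(n)[::-1]
    return R @ F @ R @ F


def two_sided_exponential_kernel(eta: float, half_width: int) -> np.ndarray:
    """Normalized kernel w[d] ~ (1-eta)^|d|, the smoother's asymptotic response."""
    d = np.arange(-half_width, half_width + 1)
    w = (1.0 - eta) ** np.abs(d)
    return w / w.sum()


def weighted_pearson_local(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray, t: int
) -> float:
    """Local Pearson r at index t from an explicit centered weight vector."""
    half = (len(weights) - 1) // 2
    lo, hi = t - half, t + half + 1
    assert lo >= 0 and hi <= len(x), "oracle is only valid away from the edges"
    w = weights / weights.sum()
    xs, ys = x[lo:hi], y[lo:hi]
    mx, my = w @ xs, w @ ys
    cov = w @ (xs * ys) - mx * my
    vx = w @ (xs * xs) - mx * mx
    vy = w @ (ys * ys) - my * my
    return cov / np.sqrt(vx * vy)


def local_corr_from_matrix(a: np.ndarray, b: np.ndarray, eta: float) -> np.ndarray:
    """Instantaneous correlation of two aligned segments via the exact kernel matrix."""
    W = smooth_matrix(len(a), eta)
    ma, mb = W @ a, W @ b
    va = W @ (a * a) - ma * ma
    vb = W @ (b * b) - mb * mb
    cov = W @ (a * b) - ma * mb
    return np.clip(cov / np.sqrt(va * vb), -1.0, 1.0)


def two_stage_cell_means(
    trials: pd.DataFrame, cells: list[str], value: str = "rt_ms"
) -> dict[tuple, float]:
    """Brute-force participant-then-group averaging, loops only."""
    per: dict[tuple, dict[str, float]] = {}
    for _, row in trials.iterrows():
        key = tuple(row[c] for c in cells)
        per.setdefault(key, {}).setdefault(row["agent_id"], []).append(row[value])  # type: ignore[arg-type]
    out = {}
    for key, by_part in per.items():
        means = [float(np.mean(v)) for v in by_part.values()]
        out[key] = float(np.mean(means))
    return out


def quartile_bins_bruteforce(rts: list[float], n_bins: int = 4) -> list[float]:
    """Sort ascending, split into n_bins equal-count bins, extras to early bins."""
    srt = sorted(rts)
    n = len(srt)
    base, rem = divmod(n, n_bins)
    out, pos = [], 0
    for b in range(n_bins):
        size = base + (1 if b < rem else 0)
        out.append(float(np.mean(srt[pos : pos + size])))
        pos += size
    return out


def rm_anova_projection(Y: np.ndarray, levels: list[int]) -> dict[str, tuple]:
    """Within-subject ANOVA via explicit projection matrices.

    Y has shape (subjects, prod(levels)), cells in row-major level order.
    Returns {effect_name: (F, df1, df2)} with effects named by 1-based factor
    indices like "1", "1x2".
    """
    from itertools import combinations

    S, m = Y.shape
    assert m == int(np.prod(levels))
    ones = [np.ones((l, l)) / l for l in levels]
    centers = [np.eye(l) - o for l, o in zip(levels, ones)]
    JS = np.ones((S, S)) / S
    CS = np.eye(S) - JS
    results = {}
    k = len(levels)
    for r in range(1, k + 1):
        for subset in combinations(range(k), r):
            M = np.eye(1)
            for f in range(k):
                M = np.kron(M, centers[f] if f in subset else ones[f])
            P_eff = np.kron(JS, M)
            P_err = np.kron(CS, M)
            v = Y.reshape(-1)  # row-major: subject-major then cells
            ss_eff = float(v @ P_eff @ v)
            ss_err = float(v @ P_err @ v)
            df1 = int(np.prod([levels[f] - 1 for f in subset]))
            df2 = df1 * (S - 1)
            F = (ss_eff / df1) / (ss_err / df2)
            name = "x".join(str(f + 1) for f in subset)
            results[name] = (F, df1, df2)
    return results
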