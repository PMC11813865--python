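"""Independent brute-force oracles used to validate the implementation.

Everything here recomputes a quantity from its definition by enumeration or
direct optimization, sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def average_ranks(x: np.ndarray) -> np.ndarray:
    """1-based average ranks by pairwise counting (O(n^2), ties averaged)."""
    x = np.asarray(x, dtype=float)
    ranks = np.empty(x.size)
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def tmm_log_ratio_bruteforce(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> float:
    """Doubly trimmed precision-weighted mean log ratio, enumerated directly."""
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    M = np.log2((o / n_obs) / (r / n_ref))
    A = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = M.size
    rM, rA = average_ranks(M), average_ranks(A)
    loM, hiM = np.floor(n * trim_M) + 1, n - np.floor(n * trim_M)
    loA, hiA = np.floor(n * trim_A) + 1, n - np.floor(n * trim_A)
    kept = [
        i
        for i in range(n)
        if loM <= rM[i] <= hiM and loA <= rA[i] <= hiA
    ]
    if not kept:
        return 0.0
    num = sum(M[i] / w[i] for i in kept)
    den = sum(1.0 / w[i] for i in kept)
    f = num / den
    return 0.0 if abs(f) < 1e-10 else float(f)


def tmm_factors_bruteforce(counts: np.ndarray, trim_M=0.30, trim_A=0.05) -> np.ndarray:
    """Full TMM factor vector: reference by 75th-percentile rule, then
    per-sample trimmed ratios, rescaled to geometric mean 1."""
    lib = counts.sum(axis=0).astype(float)
    q75 = np.quantile(counts.astype(float), 0.75, axis=0) / lib
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    n = counts.shape[1]
    f = np.ones(n)
    for j in range(n):
        if j == ref:
            continue
        f[j] = 2.0 ** tmm_log_ratio_bruteforce(
            counts[:, j], counts[:, ref], lib[j], lib[ref], trim_M, trim_A
        )
    return f / np.exp(np.mean(np.log(f)))


def bh_stepup_bruteforce(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg from the definition: sort, step up, restore order."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adj_sorted[rank - 1] = running_min
    out = np.empty(n)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def auc_allpairs_bruteforce(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC = (#concordant + 0.5 #tied) / (#pos * #neg), over every pair."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (pos.size * neg.size)


def youden_bruteforce(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Max of sens + spec - 1 by exhausting every threshold (rule: score >= t
    predicts positive); ties go to higher sensitivity."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    best = (-np.inf, -np.inf, np.nan)  # (J, sens, threshold)
    for t in np.concatenate(([np.inf], np.unique(s))):
        pred = s >= t
        sens = np.mean(pred[y == 1]) if (y == 1).any() else 0.0
        spec = np.mean(~pred[y == 0]) if (y == 0).any() else 0.0
        cand = (sens + spec - 1.0, sens, t)
        if cand[:2] > best[:2]:
            best = cand
    j, sens, t = best
    pred = s >= t
    spec = np.mean(~pred[y == 0])
    return float(j), float(sens), float(spec)


def hinge_objective(
    w: np.ndarray, b: float, X: np.ndarray, y_pm: np.ndarray, C: float, weights: np.ndarray
) -> float:
    """0.5 ||w||^2 + C sum_i c_i max(0, 1 - y_i (w.x_i + b))."""
    margins = y_pm * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.sum(weights * np.maximum(0.0, 1.0 - margins)))


def hinge_minimize_bruteforce(
    X: np.ndarray, y_pm: np.ndarray, C: float, weights: np.ndarray, n_starts: int = 12
) -> tuple[np.ndarray, float]:
    """Direct minimization of the weighted hinge objective from many starts."""
    from scipy.optimize import minimize

    d = X.shape[1]
    rng = np.random.default_rng(0)
    best = None
    for s in range(n_starts):
        x0 = rng.normal(0, 1.0, d + 1) if s else np.zeros(d + 1)
        res = minimize(
            lambda z: hinge_objective(z[:d], z[d], X, y_pm, C, weights),
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x[:d], float(best.x[d])
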