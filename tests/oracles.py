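"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle is written directly from first principles and shares no code
with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_has_run(day_flags: dict[int, bool], min_len: int, min_start: int | None = None) -> bool:
    """Scan every possible window of min_len consecutive days.

    day_flags maps day -> True when all required flags are recorded true;
    absent days count as false.  With min_start, additionally require that
    the day before the window is not flagged (the run must *commence* at a
    day >= min_start); runs longer than min_len qualify through any
    contained window whose start is a run start.
    """
    if not day_flags:
        return False
    max_day = max(day_flags)
    for start in range(1, max_day + 1):
        if min_start is not None and start < min_start:
            continue
        if min_start is not None and day_flags.get(start - 1, False):
            continue  # window does not commence here
        if all(day_flags.get(start + k, False) for k in range(min_len)):
            return True
    return False


def newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> np.ndarray:
    """Hand-rolled Newton-Raphson maximum-likelihood logistic regression."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y - mu)
        W = mu * (1 - mu)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def sort_split_deciles(scores: np.ndarray) -> np.ndarray:
    """Decile labels by explicit sort-and-split with type-7 quantile edges."""
    scores = np.asarray(scores, float)
    srt = np.sort(scores)
    n = len(srt)
    edges = []
    for q in [k / 10 for k in range(1, 10)]:
        h = (n - 1) * q
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        edges.append(srt[lo] + (h - lo) * (srt[hi] - srt[lo]))
    edges = sorted(set(edges))
    labels = np.empty(len(scores), dtype=int)
    for i, s in enumerate(scores):
        b = 1
        for e in edges:
            if s > e:
                b += 1
        labels[i] = b
    return labels


def census_pair_count(fed_cells: dict, unfed_cells: dict) -> int:
    """Sum over cells of min(#fed, #unfed)."""
    total = 0
    for key in set(fed_cells) | set(unfed_cells):
        total += min(fed_cells.get(key, 0), unfed_cells.get(key, 0))
    return total


def log_scale_or(a, b, c, d):
    """Odds ratio, SE of the log OR and 95% CI by direct arithmetic."""
    log_or = math.log(a) + math.log(d) - math.log(b) - math.log(c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = 1.959963984540054
    return math.exp(log_or), se, (math.exp(log_or - z * se), math.exp(log_or + z * se))


def direct_risk_difference(a, b, c, d):
    p1 = a / (a + b)
    p2 = c / (c + d)
    se = math.sqrt(p1 * (1 - p1) / (a + b) + p2 * (1 - p2) / (c + d))
    return p1 - p2, se


def random_day_table(rng: np.random.Generator, n_days_max: int = 14):
    """A random per-baby day record for the run-definition property tests."""
    n_days = int(rng.integers(1, n_days_max + 1))
    days = sorted(rng.choice(np.arange(1, n_days_max + 3), size=n_days, replace=False).tolist())
    rows = []
    for d in days:
        abx = rng.choice([1.0, 0.0, np.nan], p=[0.5, 0.3, 0.2])
        nbm = rng.choice([1.0, 0.0, np.nan], p=[0.5, 0.3, 0.2])
        rows.append((int(d), abx, nbm))
    return rows
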