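"""Independent brute-force oracles used to pin down expected values.

Everything here is deliberately naive and separate from the package's own
code paths: a from-scratch coordinate-descent elastic net, an exact
rational-arithmetic hypergeometric tail, and a brute-force membership
tally for overlap cells.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from itertools import combinations

import numpy as np


def enet_objective(X: np.ndarray, y: np.ndarray, b0: float, b: np.ndarray,
                   lam: float, alpha: float) -> float:
    """(1/2n)||y - b0 - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||_2^2)."""
    n = len(y)
    resid = y - b0 - X @ b
    return float(
        0.5 / n * resid @ resid
        + lam * (alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * b @ b)
    )


def _soft(x: float, t: float) -> float:
    return np.sign(x) * max(abs(x) - t, 0.0)


def enet_coordinate_descent(X: np.ndarray, y: np.ndarray, lam: float, alpha: float,
                            tol: float = 1e-12, max_iter: int = 200_000) -> tuple[float, np.ndarray]:
    """Cyclic coordinate descent on the elastic-net objective, run to convergence.

    The intercept is profiled out exactly: b0 = mean(y - Xb) at every step
    (equivalently, work with centered y when X has centered columns).
    Returns (b0, b).
    """
    n, p = X.shape
    xm = X.mean(axis=0)
    Xc = X - xm
    ym = y.mean()
    yc = y - ym
    col_sq = (Xc ** 2).sum(axis=0) / n
    b = np.zeros(p)
    resid = yc.copy()
    prev_obj = np.inf
    for _ in range(max_iter):
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = (Xc[:, j] @ resid) / n + col_sq[j] * b[j]
            new_bj = _soft(rho, lam * alpha) / (col_sq[j] + lam * (1 - alpha))
            if new_bj != b[j]:
                resid -= Xc[:, j] * (new_bj - b[j])
                b[j] = new_bj
        obj = enet_objective(Xc, yc, 0.0, b, lam, alpha)
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    b0 = ym - float(b @ xm)
    return b0, b


def hypergeom_upper_tail_exact(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by exact rational summation over the support."""
    if k <= 0:
        return 1.0
    total = comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(n, K) + 1):
        if n - i > N - K:
            continue
        acc += Fraction(comb(K, i) * comb(N - K, n - i), total)
    return float(acc)


def hypergeom_upper_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by complete enumeration of all C(N, n) draws (tiny N only)."""
    if k <= 0:
        return 1.0
    successes = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(successes.intersection(draw)) >= k)
    return hits / comb(N, n)


def brute_force_upset(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive-intersection cell counts by per-element membership lookup."""
    labels = sorted(sets)
    cells: dict[tuple[str, ...], int] = {}
    for element in set().union(*sets.values()):
        pattern = tuple(lbl for lbl in labels if element in sets[lbl])
        cells[pattern] = cells.get(pattern, 0) + 1
    return cells
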