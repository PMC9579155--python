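"""Independent oracles used by the test suite.

Each oracle is a deliberately naive implementation (plain loops, generic
solvers) kept separate from the library code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize


def kapur_bruteforce(image: np.ndarray) -> int:
    """Exhaustive max-entropy threshold: plain loops over all 256 splits.

    Sides are ``< T`` and ``>= T``; a split with an empty side is invalid;
    ties go to the smallest T.
    """
    counts = [0] * 256
    for v in np.asarray(image).ravel():
        counts[int(v)] += 1

    def side_entropy(sub):
        tot = sum(sub)
        if tot == 0:
            return None
        h = 0.0
        for c in sub:
            if c > 0:
                p = c / tot
                h -= p * math.log(p)
        return h

    best_t, best_score = None, -math.inf
    for t in range(256):
        lo = side_entropy(counts[:t])
        hi = side_entropy(counts[t:])
        if lo is None or hi is None:
            continue
        score = lo + hi
        if score > best_score + 1e-12:
            best_score, best_t = score, t
    return best_t


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by BFS, in raster order of first pixel."""
    mask = np.asarray(mask).astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not seen[r0, c0]:
                comp, queue = set(), [(r0, c0)]
                seen[r0, c0] = True
                while queue:
                    r, c = queue.pop()
                    comp.add((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < rows and 0 <= cc < cols and \
                                    mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                queue.append((rr, cc))
                comps.append(comp)
    return comps


def pairwise_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC by O(n^2) comparison; ties count 1/2."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def solve_dual_qp(k: np.ndarray, y: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    """Soft-margin SVM dual via a generic SLSQP solver.

    maximize  sum(a) - 1/2 (a*y)' K (a*y)
    s.t.      0 <= a <= C,  a . y = 0
    """
    n = k.shape[0]
    yf = y.astype(float)
    q = (yf[:, None] * yf[None, :]) * k

    def fun(a):
        return -(a.sum() - 0.5 * a @ q @ a)

    def jac(a):
        return -(np.ones(n) - q @ a)

    res = minimize(fun, np.zeros(n), jac=jac, bounds=[(0.0, c)] * n,
                   constraints=[{"type": "eq", "fun": lambda a: a @ yf,
                                 "jac": lambda a: yf}],
                   method="SLSQP", options={"maxiter": 3000, "ftol": 1e-14})
    return res.x, float(-res.fun)
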