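"""Independent brute-force oracles used to cross-check the solver paths.

These deliberately avoid the package's LP assembly: the flux polytope
vertex enumerator works from raw (A, b, bounds) by basis enumeration, the
iMAT oracle enumerates every binary assignment and checks feasibility of
the induced box, and the hypergeometric tail is an exact combinatorial sum.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog


def enumerate_vertices(A: np.ndarray, b: np.ndarray, lb: np.ndarray,
                       ub: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """All vertices of {x : A x = b, lb <= x <= ub} by enumerating choices
    of nonbasic variables fixed at a bound.  Exponential; for tiny n only."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    m, n = A.shape
    r = np.linalg.matrix_rank(A) if A.size else 0
    free = n - r
    verts = []
    for nonbasic in itertools.combinations(range(n), free):
        basic = [j for j in range(n) if j not in nonbasic]
        for corner in itertools.product(*[(lb[j], ub[j]) for j in nonbasic]):
            x = np.empty(n)
            for j, val in zip(nonbasic, corner):
                x[j] = val
            rhs = b - (A[:, list(nonbasic)] @ np.array(corner) if free else 0.0)
            if basic:
                sol, res, rank, _ = np.linalg.lstsq(A[:, basic], rhs, rcond=None)
                if rank < len(basic):
                    continue
                x[basic] = sol
            if np.max(np.abs(A @ x - b), initial=0.0) > 1e-7:
                continue
            if np.all(x >= lb - tol) and np.all(x <= ub + tol):
                verts.append(np.clip(x, lb, ub))
    if not verts:
        return np.empty((0, n))
    uniq = []
    for v in verts:
        if not any(np.allclose(v, u, atol=1e-7) for u in uniq):
            uniq.append(v)
    return np.array(uniq)


def lp_optimum_by_vertices(c, A, b, lb, ub, sense: str = "max"):
    """Optimal objective of the LP by brute vertex enumeration (None if the
    polytope is empty)."""
    verts = enumerate_vertices(A, b, np.asarray(lb, float), np.asarray(ub, float))
    if verts.shape[0] == 0:
        return None
    vals = verts @ np.asarray(c, float)
    return float(vals.max() if sense == "max" else vals.min())


def fva_by_vertices(A, b, lb, ub, c, floor):
    """Per-variable min/max over {A x = b, bounds, c.x >= floor}, by adding
    a slack variable and enumerating the augmented polytope's vertices."""
    A = np.atleast_2d(np.asarray(A, float))
    m, n = A.shape
    c = np.asarray(c, float)
    big = float(np.abs(c) @ np.maximum(np.abs(lb), np.abs(ub)) + abs(floor) + 1)
    A2 = np.hstack([np.vstack([A, c[None, :]]),
                    np.concatenate([np.zeros(m), [-1.0]])[:, None]])
    b2 = np.concatenate([b, [floor]])
    lb2 = np.concatenate([lb, [0.0]])
    ub2 = np.concatenate([ub, [big]])
    verts = enumerate_vertices(A2, b2, lb2, ub2)
    if verts.shape[0] == 0:
        return None
    return [(float(verts[:, j].min()), float(verts[:, j].max())) for j in range(n)]


def imat_by_enumeration(S, lb, ub, rh_idx, rl_idx, epsilon) -> int:
    """Optimal iMAT agreement score by exhaustive enumeration of the binary
    activity states (3 states per core-active reaction, 2 per core-inactive
    reaction), each checked with a feasibility LP."""
    S = np.atleast_2d(np.asarray(S, float))
    n = S.shape[1]
    best = 0
    states_h = [(0, 0), (1, 0), (0, 1)]  # (y+, y-)
    for combo_h in itertools.product(states_h, repeat=len(rh_idx)):
        score_h = sum(yp + ym for yp, ym in combo_h)
        for combo_l in itertools.product((0, 1), repeat=len(rl_idx)):
            score = score_h + sum(combo_l)
            if score <= best:
                continue
            lo, hi = np.array(lb, float), np.array(ub, float)
            ok = True
            for (yp, ym), j in zip(combo_h, rh_idx):
                if yp:
                    lo[j] = max(lo[j], epsilon)
                if ym:
                    hi[j] = min(hi[j], -epsilon)
                if lo[j] > hi[j]:
                    ok = False
            for z, j in zip(combo_l, rl_idx):
                if z:
                    lo[j] = max(lo[j], 0.0)
                    hi[j] = min(hi[j], 0.0)
                    if lo[j] > hi[j]:
                        ok = False
            if not ok:
                continue
            res = linprog(np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lo, hi]), method="highs")
            if res.status == 0:
                best = score
    return best


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    total = math.comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            acc += math.comb(K, j) * math.comb(N - K, n - j)
    return acc / total
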