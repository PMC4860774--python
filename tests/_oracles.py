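"""Independent brute-force oracles used only by the tests.

These are deliberately written with plain Python loops and exact integer
arithmetic, sharing no code with the package implementation.
"""

from __future__ import annotations

import math
from statistics import median


def polish_oracle_3d(values, mask, max_iter=20, tol=1e-6):
    """Plain-loop three-way median polish.

    ``values``: nested list (or array) indexed [r][c][p]; ``mask``: same
    shape, True where the cell is observed.  Returns (overall, row_eff,
    col_eff, plate_eff, residuals) following the sweep schedule rows ->
    columns -> plates with effect-vector medians re-absorbed into the
    overall term after each full iteration.
    """
    R = len(values)
    C = len(values[0])
    P = len(values[0][0])
    resid = [[[float(values[r][c][p]) for p in range(P)] for c in range(C)]
             for r in range(R)]
    obs = [[[bool(mask[r][c][p]) for p in range(P)] for c in range(C)]
           for r in range(R)]
    overall = 0.0
    row_eff = [0.0] * R
    col_eff = [0.0] * C
    plate_eff = [0.0] * P

    total_abs = sum(
        abs(resid[r][c][p])
        for r in range(R) for c in range(C) for p in range(P)
        if obs[r][c][p]
    )
    threshold = tol * (total_abs if total_abs > 0 else 1.0)

    for _ in range(max_iter):
        adjustment = 0.0
        # row sweep
        for r in range(R):
            vals = [resid[r][c][p] for c in range(C) for p in range(P)
                    if obs[r][c][p]]
            m = median(vals) if vals else 0.0
            for c in range(C):
                for p in range(P):
                    resid[r][c][p] -= m
            row_eff[r] += m
            adjustment += abs(m)
        # column sweep
        for c in range(C):
            vals = [resid[r][c][p] for r in range(R) for p in range(P)
                    if obs[r][c][p]]
            m = median(vals) if vals else 0.0
            for r in range(R):
                for p in range(P):
                    resid[r][c][p] -= m
            col_eff[c] += m
            adjustment += abs(m)
        # plate sweep
        for p in range(P):
            vals = [resid[r][c][p] for r in range(R) for c in range(C)
                    if obs[r][c][p]]
            m = median(vals) if vals else 0.0
            for r in range(R):
                for c in range(C):
                    resid[r][c][p] -= m
            plate_eff[p] += m
            adjustment += abs(m)
        # re-absorb effect medians
        for eff in (row_eff, col_eff, plate_eff):
            m = median(eff)
            for i in range(len(eff)):
                eff[i] -= m
            overall += m
            adjustment += abs(m)
        if adjustment <= threshold:
            break
    return overall, row_eff, col_eff, plate_eff, resid


def polish_oracle_2d(values, max_iter=20, tol=1e-6):
    """Classical two-way (single-plate) median polish via the 3D oracle."""
    R, C = len(values), len(values[0])
    cube = [[[values[r][c]] for c in range(C)] for r in range(R)]
    mask = [[[True] for _ in range(C)] for _ in range(R)]
    overall, row_eff, col_eff, plate_eff, resid = polish_oracle_3d(
        cube, mask, max_iter=max_iter, tol=tol
    )
    resid2d = [[resid[r][c][0] + plate_eff[0] * 0 for c in range(C)]
               for r in range(R)]
    return overall + plate_eff[0], row_eff, col_eff, resid2d


def hypergeom_upper_tail_exact(N, K, n, k):
    """P(X >= k) by exact summation of binomial-coefficient ratios."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    from fractions import Fraction

    return float(Fraction(total, denom))
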