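"""Independent linear-programming oracle for Hartigan's dip statistic.

Minimises the sup-band half-width d such that a unimodal CDF G (convex to
the left of a mode, concave to the right, with an atom allowed only at the
mode) fits within d of the ECDF, by solving one LP per candidate mode
position.  The CDF is modelled piecewise-linearly with knots at the data
points (plus the candidate mode), with separate variables for left limits
and values so the modal atom is representable.  Intended for small n only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _lp_for_mode(knots, f_left, f_right, mode_idx):
    """Min band width d for mode at knots[mode_idx].

    f_left[k], f_right[k]: ECDF left limit / value at each knot.
    Variables: u_k = G(knot_k-), w_k = G(knot_k), d.  G linear between
    knots, continuous except at the mode, convex before / concave after.
    """
    m = len(knots)
    nv = 2 * m + 1
    iu = lambda k: k
    iw = lambda k: m + k
    i_d = 2 * m
    A_ub, b_ub = [], []
    A_eq, b_eq = [], []

    def ub(coeffs, rhs):
        row = np.zeros(nv)
        for i, c in coeffs:
            row[i] += c
        A_ub.append(row)
        b_ub.append(rhs)

    def eq(coeffs, rhs):
        row = np.zeros(nv)
        for i, c in coeffs:
            row[i] += c
        A_eq.append(row)
        b_eq.append(rhs)

    # band constraints: |u_k - f_left[k]| <= d, |w_k - f_right[k]| <= d
    for k in range(m):
        ub([(iu(k), 1.0), (i_d, -1.0)], f_left[k])
        ub([(iu(k), -1.0), (i_d, -1.0)], -f_left[k])
        ub([(iw(k), 1.0), (i_d, -1.0)], f_right[k])
        ub([(iw(k), -1.0), (i_d, -1.0)], -f_right[k])
    # tails: G <= d left of first knot, G >= 1-d right of last knot
    ub([(iu(0), 1.0), (i_d, -1.0)], 0.0)
    ub([(iw(m - 1), -1.0), (i_d, -1.0)], -1.0)
    # continuity except at the mode; atom (u <= w) at the mode
    for k in range(m):
        if k == mode_idx:
            ub([(iu(k), 1.0), (iw(k), -1.0)], 0.0)
        else:
            eq([(iu(k), 1.0), (iw(k), -1.0)], 0.0)
    # monotone segments
    for k in range(m - 1):
        ub([(iw(k), 1.0), (iu(k + 1), -1.0)], 0.0)
    # slopes: s_k = (u_{k+1} - w_k) / dx_k ; convex (nondecreasing) before
    # the mode, concave (nonincreasing) after
    dx = np.diff(knots)
    for k in range(m - 2):
        sk = [(iu(k + 1), 1.0 / dx[k]), (iw(k), -1.0 / dx[k])]
        sk1 = [(iu(k + 2), 1.0 / dx[k + 1]), (iw(k + 1), -1.0 / dx[k + 1])]
        if k + 1 <= mode_idx:        # both segments on the convex side
            ub([*sk, *[(i, -c) for i, c in sk1]], 0.0)
        if k >= mode_idx:            # both segments on the concave side
            ub([*[(i, -c) for i, c in sk], *sk1], 0.0)

    c = np.zeros(nv)
    c[i_d] = 1.0
    bounds = [(None, None)] * (2 * m) + [(0.0, None)]
    res = linprog(c, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=bounds, method="highs")
    assert res.success, res.message
    return float(res.fun)


def dip_lp(values) -> float:
    """Dip of a small sample by LP over all candidate mode positions."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0
    v, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / n
    # knots: data points plus gap midpoints (candidate modes between points)
    knots, f_left, f_right = [], [], []
    prev = 0.0
    for k in range(len(v)):
        knots.append(v[k])
        f_left.append(prev)
        f_right.append(cum[k])
        prev = cum[k]
        if k + 1 < len(v):
            mid = (v[k] + v[k + 1]) / 2.0
            knots.append(mid)
            f_left.append(prev)
            f_right.append(prev)
    knots = np.array(knots)
    f_left = np.array(f_left)
    f_right = np.array(f_right)
    return min(_lp_for_mode(knots, f_left, f_right, j)
               for j in range(len(knots)))
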