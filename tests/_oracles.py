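"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's LP path: the 1-input/1-output
closed form is plain arithmetic, and the general envelopment oracle
enumerates basic solutions (vertices) of the LP polyhedron with
numpy.linalg only.
"""

from itertools import combinations

import numpy as np


def ccr_ratio_oracle(x, y):
    """CCR input-oriented efficiency for 1-input/1-output data:
    each unit's output/input ratio divided by the best ratio."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ratio = y / x
    return ratio / ratio.max()


def envelopment_vertex_oracle(x0, y0, X, Y, vrs, tol=1e-8):
    """Radial input-oriented efficiency by vertex enumeration.

    Variables v = (theta, lam).  Constraints:
      inputs:   X lam - theta x0 <= 0
      outputs:  y0 - Y lam <= 0
      bounds:   theta >= 0, lam >= 0
      vrs:      sum(lam) = 1
    The optimum of a bounded LP over a pointed polyhedron lies at a
    vertex, i.e. a feasible basic solution with d linearly independent
    active constraints (d = number of variables).  Enumerate all
    candidate active sets and take the feasible minimum of theta.
    """
    x0 = np.asarray(x0, float).ravel()
    y0 = np.asarray(y0, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    m, n = X.shape
    s = Y.shape[0]
    d = 1 + n

    # rows a, rhs b with meaning a @ v <= b
    rows = []
    rhs = []
    for i in range(m):
        a = np.zeros(d)
        a[0] = -x0[i]
        a[1:] = X[i]
        rows.append(a)
        rhs.append(0.0)
    for r in range(s):
        a = np.zeros(d)
        a[1:] = -Y[r]
        rows.append(a)
        rhs.append(-y0[r])
    for k in range(d):  # -v_k <= 0
        a = np.zeros(d)
        a[k] = -1.0
        rows.append(a)
        rhs.append(0.0)
    rows = np.array(rows)
    rhs = np.array(rhs)

    eq_rows = []
    eq_rhs = []
    if vrs:
        a = np.zeros(d)
        a[1:] = 1.0
        eq_rows.append(a)
        eq_rhs.append(1.0)

    n_eq = len(eq_rows)
    best = np.inf
    for active in combinations(range(len(rows)), d - n_eq):
        A = np.vstack([rows[list(active)]] + ([np.array(eq_rows)] if n_eq else []))
        b = np.concatenate([rhs[list(active)], np.array(eq_rhs)]) if n_eq else rhs[
            list(active)
        ]
        if np.linalg.matrix_rank(A) < d:
            continue
        try:
            v = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        scale = 1.0 + np.abs(v).max()
        if (rows @ v - rhs > tol * scale).any():
            continue
        if n_eq and abs(np.array(eq_rows) @ v - eq_rhs).max() > tol * scale:
            continue
        best = min(best, v[0])
    return best
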