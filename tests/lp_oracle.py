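"""Exhaustive vertex-enumeration oracle for small bounded LPs.

Independent of the package's LP path: enumerates candidate vertices of
{v : S v = 0, lb <= v <= ub} by fixing subsets of variables at their
bounds and solving the remaining square-ish system by least squares. Valid
whenever all bounds are finite (polytope bounded), which the random test
models guarantee.
"""

import itertools

import numpy as np


def enumerate_vertices(S, lb, ub, atol=1e-9):
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    r = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - r
    points = []
    for fixed in itertools.combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        for sides in itertools.product((0, 1), repeat=n_fixed):
            v = np.zeros(n)
            for j, s in zip(fixed, sides):
                v[j] = ub[j] if s else lb[j]
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ v[list(fixed)]
                x, *_ = np.linalg.lstsq(A, b, rcond=None)
                if np.linalg.norm(A @ x - b) > atol:
                    continue  # inconsistent: not a feasible face
                v[free] = x
            if np.any(S @ v > atol) or np.any(S @ v < -atol):
                continue
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                points.append(v)
    return points


def brute_force_fba(model):
    """Max objective over enumerated vertices; returns (optimum, argmax)."""
    from glycferm.model import build_stoichiometric_matrix

    S = build_stoichiometric_matrix(model)
    lb = [r.lower_bound for r in model.reactions]
    ub = [r.upper_bound for r in model.reactions]
    idx = model.reaction_index()
    c = np.zeros(len(model.reactions))
    for rid, w in model.objective.items():
        c[idx[rid]] = w
    best, best_v = None, None
    for v in enumerate_vertices(S, lb, ub):
        val = float(c @ v)
        if best is None or val > best:
            best, best_v = val, v
    return best, best_v
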