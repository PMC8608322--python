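"""Minimum-norm quadratic subproblem for the L2-minimal flux-difference step.

:func:`min_norm_box_eq` computes the minimum-Euclidean-norm point of
``{x : A_eq x = b, lo <= A_row x <= hi, l <= x <= u}``.  The point is found
by Dykstra's alternating projections (the projection of the origin onto an
intersection of convex sets converges to the constrained least-norm point),
then polished exactly: bounds and rows active at the iterate are pinned and
the remaining equality-constrained least-norm problem is solved in closed
form through the pseudoinverse, with a feasibility check before acceptance.
Deterministic throughout — repeated solves return bit-identical answers.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

_ACTIVE_TOL = 1e-7


def _dykstra(A_eq, b_eq, l, u, slabs, iters=20000, tol=1e-13):
    """Project the origin onto {A_eq x = b_eq} ∩ [l, u] ∩ slabs.

    ``slabs`` is a list of (a, lo, hi) single-row two-sided constraints.
    Returns the final iterate (box projection applied last, so bounds hold
    exactly; the equality residual is driven below tol * scale).
    """
    n = len(l)
    pinv = np.linalg.pinv(A_eq, rcond=1e-12)
    x_part = pinv @ b_eq  # particular solution; affine proj: x - pinv(Ax - b)
    sets = ["eq", "box"] + list(range(len(slabs)))
    incr = {s: np.zeros(n) for s in sets}
    x = np.zeros(n)
    for _ in range(iters):
        x_prev = x
        for s in sets:
            y = x + incr[s]
            if s == "eq":
                p = y - pinv @ (A_eq @ y) + x_part
            elif s == "box":
                p = np.clip(y, l, u)
            else:
                a, lo, hi = slabs[s]
                val = a @ y
                nn = a @ a
                if val > hi:
                    p = y - (val - hi) / nn * a
                elif val < lo:
                    p = y - (val - lo) / nn * a
                else:
                    p = y
            incr[s] = y - p
            x = p
        if np.max(np.abs(x - x_prev)) < tol * max(1.0, np.max(np.abs(x))):
            break
    return x


def min_norm_box_eq(
    A_eq: np.ndarray | sp.spmatrix,
    b_eq: np.ndarray,
    l: np.ndarray,
    u: np.ndarray,
    x0: np.ndarray | None = None,
    A_rng: np.ndarray | None = None,
    lo_rng: np.ndarray | None = None,
    hi_rng: np.ndarray | None = None,
) -> np.ndarray:
    """Minimize ``||x||_2^2`` subject to ``A_eq x = b_eq``, optional two-sided
    rows ``lo_rng <= A_rng x <= hi_rng`` and box bounds ``l <= x <= u``.

    ``x0`` (any feasible point) is the fallback if polishing fails on an
    ill-identified active set; it does not influence the optimum.
    """
    A_eq = np.asarray(A_eq.todense() if sp.issparse(A_eq) else A_eq, dtype=float)
    b_eq = np.asarray(b_eq, dtype=float)
    slabs = []
    if A_rng is not None and len(A_rng):
        A_rng = np.asarray(A_rng, dtype=float)
        lo_rng = np.asarray(lo_rng, dtype=float)
        hi_rng = np.asarray(hi_rng, dtype=float)
        slabs = [(A_rng[r], lo_rng[r], hi_rng[r]) for r in range(len(A_rng))]

    x = _dykstra(A_eq, b_eq, l, u, slabs)

    polished = _polish(x, A_eq, b_eq, l, u, A_rng, lo_rng, hi_rng)
    if polished is not None:
        return polished
    # accept the iterate if it is essentially feasible, else fall back
    scale = max(1.0, float(np.max(np.abs(x))))
    if np.max(np.abs(A_eq @ x - b_eq), initial=0.0) <= 1e-7 * scale:
        return x
    return x if x0 is None else np.asarray(x0, dtype=float)


def _polish(x, A_eq, b_eq, l, u, A_rng, lo_rng, hi_rng):
    """Pin bounds/rows active at x, solve the equality-constrained least-norm
    problem in closed form, and accept if feasible and no worse."""
    n = len(x)
    scale = max(1.0, float(np.max(np.abs(x))))
    act_lo = x <= l + _ACTIVE_TOL * scale
    act_hi = x >= u - _ACTIVE_TOL * scale
    fixed_val = np.where(act_lo, l, np.where(act_hi, u, 0.0))
    fixed = act_lo | act_hi
    free = ~fixed

    eq_rows = [A_eq]
    eq_rhs = [b_eq]
    if A_rng is not None and len(A_rng):
        r = A_rng @ x
        on_lo = r <= lo_rng + _ACTIVE_TOL * scale
        on_hi = r >= hi_rng - _ACTIVE_TOL * scale
        on = on_lo | on_hi
        if on.any():
            eq_rows.append(A_rng[on])
            eq_rhs.append(np.where(on_lo[on], lo_rng[on], hi_rng[on]))
    A = np.vstack(eq_rows)
    b = np.concatenate(eq_rhs)

    # min ||x_free||^2  s.t.  A_free x_free = b - A_fixed x_fixed
    rhs = b - A[:, fixed] @ fixed_val[fixed]
    A_free = A[:, free]
    try:
        x_free = np.linalg.pinv(A_free, rcond=1e-12) @ rhs
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    cand = np.empty(n)
    cand[fixed] = fixed_val[fixed]
    cand[free] = x_free

    ftol = 1e-8 * max(1.0, float(np.max(np.abs(cand))))
    if np.any(cand < l - ftol) or np.any(cand > u + ftol):
        return None
    if np.max(np.abs(A_eq @ cand - b_eq), initial=0.0) > ftol:
        return None
    if A_rng is not None and len(A_rng):
        r = A_rng @ cand
        if np.any(r < lo_rng - ftol) or np.any(r > hi_rng + ftol):
            return None
    if float(cand @ cand) > float(x @ x) + max(ftol, 1e-6 * float(x @ x)):
        return None
    return np.clip(cand, l, u)
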