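"""Independent brute-force oracle for the consistency optimum.

Enumerates, per split reaction that matters (regulated, half of a reversible
pair, or forced to zero), its indicator state:

    UP    zU=1            dv in [max(dv_min, mu),  dv_max]
    DOWN  zD=1            dv in [dv_min,           min(dv_max, -eta)]
    NONE  all z zero      dv in [max(dv_min,-eta), min(dv_max, mu)]
    ZERO  z0=1            dv = 0

Every feasible binary assignment of the MILP maps to exactly one such state
vector (zU=zD=1 and z0=1 with a nonzero flag are infeasible whenever the
thresholds are positive), so maximizing the consistency score over state
vectors — each checked for continuous feasibility by an LP on the balance
equation and the state intervals — is an exhaustive enumeration of the
binaries.  Assignments are visited in descending score order with early
exit.  This code shares nothing with the package's MILP builder.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

UP, DOWN, NONE, ZERO = "U", "D", "N", "Z"


def oracle_phi_star(
    S_split: np.ndarray,
    dv_min: np.ndarray,
    dv_max: np.ndarray,
    mu: np.ndarray,
    eta: np.ndarray,
    r_up: dict[int, float],
    r_down: dict[int, float],
    pair_map: list[tuple[int, int]],
    forced_zero: set[int] = frozenset(),
    pair_coupling: str = "symmetric",
    z0_free: bool = True,
) -> float:
    S = np.asarray(S_split, dtype=float)
    n = S.shape[1]
    assert np.all(mu > 0) and np.all(eta > 0), "oracle requires positive thresholds"

    enum = sorted(set(r_up) | set(r_down) | {k for p in pair_map for k in p})
    enum = [i for i in enum if i not in forced_zero]
    states = [UP, DOWN, NONE, ZERO] if z0_free else [UP, DOWN, NONE]

    def phi(assign: dict[int, str]) -> float:
        total = 0.0
        for i, w in r_up.items():
            s = assign.get(i, NONE)
            total += w * (1 if s == UP else -1 if s == DOWN else 0)
        for j, w in r_down.items():
            s = assign.get(j, NONE)
            total += w * (1 if s == DOWN else -1 if s == UP else 0)
        return total

    ordered_pairs = list(pair_map)
    if pair_coupling == "symmetric":
        ordered_pairs += [(kp, k) for k, kp in pair_map]

    def pairs_ok(assign: dict[int, str]) -> bool:
        # z0_k + zU_k >= zD_k' ; z0_k + zD_k >= zU_k'
        for k, kp in ordered_pairs:
            sk = assign.get(k, ZERO if k in forced_zero else NONE)
            skp = assign.get(kp, ZERO if kp in forced_zero else NONE)
            if skp == DOWN and sk not in (UP, ZERO):
                return False
            if skp == UP and sk not in (DOWN, ZERO):
                return False
        return True

    def feasible(assign: dict[int, str]) -> bool:
        lo = dv_min.copy()
        hi = dv_max.copy()
        for i in range(n):
            s = assign.get(i, ZERO if i in forced_zero else None)
            if s is None:
                continue
            if s == UP:
                lo[i] = max(lo[i], mu[i])
            elif s == DOWN:
                hi[i] = min(hi[i], -eta[i])
            elif s == NONE:
                lo[i] = max(lo[i], -eta[i])
                hi[i] = min(hi[i], mu[i])
            else:  # ZERO
                lo[i] = max(lo[i], 0.0)
                hi[i] = min(hi[i], 0.0)
        if np.any(lo > hi):
            return False
        res = linprog(c=np.zeros(n), A_eq=S, b_eq=np.zeros(S.shape[0]),
                      bounds=np.column_stack([lo, hi]), method="highs")
        return res.status == 0

    candidates = [dict(zip(enum, combo))
                  for combo in itertools.product(states, repeat=len(enum))]
    candidates.sort(key=phi, reverse=True)
    for assign in candidates:
        if pairs_ok(assign) and feasible(assign):
            return phi(assign)
    raise AssertionError("no feasible assignment found (dv = 0 should always work)")
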