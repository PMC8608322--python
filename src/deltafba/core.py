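"""The flux-difference optimization: consistency MILP and norm-minimal step.

The method predicts ``dv = v_P - v_C`` directly.  Because both conditions are
at steady state, the difference is itself balanced, ``S dv = 0``.  Among all
balanced difference vectors within bounds, step 1 maximizes a weighted
consistency score between the *sign* of each regulated reaction's flux
difference and the direction of its expression change:

    Phi = sum_{i in R_up} w_i (zU_i - zD_i) + sum_{j in R_down} w_j (zD_j - zU_j)

where the binaries are tied to the continuous dv through big-M indicator
constraints: ``zU_i = 1`` forces ``dv_i >= mu_i`` (a genuine increase) and
``zU_i = 0`` forces ``dv_i <= mu_i``; symmetrically ``zD_i = 1`` forces
``dv_i <= -eta_i``.  A third binary family ``z0`` pins selected reactions to
zero change, and for every forward/backward half-pair (k, k') of a split
reversible reaction the couplings ``z0_k + zU_k >= zD_k'`` and
``z0_k + zD_k >= zU_k'`` prevent both directions from carrying flux change
simultaneously, which reduces solution degeneracy.

Because many difference vectors attain the optimal score Phi*, step 2 picks
the parsimonious one: minimize ``||dv||_2^2`` (or ``||dv||_1``) subject to
the same constraints plus ``Phi = Phi*``.  With binaries free this is a
mixed-integer quadratic (or linear) program; a fast mode freezes the step-1
binaries, leaving a continuous QP/LP.

Solvers: HiGHS through scipy for all LPs/MILPs; an active-set-polished QP
(see ``_qp``) for the continuous L2 problem and an own branch-and-bound for
the mixed-integer L2 mode.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from ._qp import min_norm_box_eq
from .model_io import DeltaBounds, SplitNetwork
from .regulation import RegulationInput

__all__ = ["MILPSpec", "DeltaSolution", "build_milp", "solve_consistency",
           "minimize_norm", "net_delta", "solve_two_step"]

DEFAULT_M = 1e5
DEFAULT_BOUND_CAP = 1e4
PHI_RELAX = 1e-9


@dataclass
class MILPSpec:
    """Assembled constraint system for one flux-difference problem.

    Variables are laid out as ``[dv (n), zU (n), zD (n), z0 (n)]`` with n the
    number of split reactions.  ``z0_mode`` is "free" (solver may zero any
    reaction, forced members fixed to 1) or "strict" (z0 fixed to 0 outside
    the forced set).
    """

    split: SplitNetwork
    dv_min: np.ndarray
    dv_max: np.ndarray
    mu: np.ndarray
    eta: np.ndarray
    M: float
    r_up: dict[int, float]
    r_down: dict[int, float]
    forced_zero: set[int]
    net_overrides: dict[int, tuple[float, float]] = field(default_factory=dict)
    z0_mode: str = "free"
    pair_coupling: str = "symmetric"

    @property
    def n(self) -> int:
        return self.split.n_split

    @property
    def phi_upper_bound(self) -> float:
        return sum(self.r_up.values()) + sum(self.r_down.values())

    def objective_z(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients of Phi on (zU, zD)."""
        n = self.n
        c_u, c_d = np.zeros(n), np.zeros(n)
        for i, w in self.r_up.items():
            c_u[i] += w
            c_d[i] -= w
        for j, w in self.r_down.items():
            c_d[j] += w
            c_u[j] -= w
        return c_u, c_d

    def phi_of(self, z_up: np.ndarray, z_down: np.ndarray) -> float:
        c_u, c_d = self.objective_z()
        return float(c_u @ z_up + c_d @ z_down)

    # -- constraint assembly ------------------------------------------------

    def constraint_system(self):
        """All linear rows as (A, lo, hi) over [dv, zU, zD, z0]."""
        n, M = self.n, self.M
        I = sp.identity(n, format="csr")
        Z = sp.csr_matrix((n, n))
        S = sp.csr_matrix(self.split.S_split)
        m = S.shape[0]
        rows, lo, hi = [], [], []

        # flux-difference balance  S dv = 0
        rows.append(sp.hstack([S, sp.csr_matrix((m, 3 * n))]))
        lo.append(np.zeros(m))
        hi.append(np.zeros(m))

        # Indicator rows use the smallest valid big-M per row (never larger
        # than the validated global M is required to be): the integer-feasible
        # set is identical, but the LP relaxation is tighter and — crucially —
        # the solver's integrality tolerance is not amplified by an oversized
        # constant into indicator-semantics violations.
        floor = 1e-6
        m_u4 = np.maximum(self.mu - self.dv_min, floor)   # zU=0 side of Eq "dv >= mu - M"
        m_u5 = np.maximum(self.dv_max - self.mu, floor)   # zU=1 side of "dv <= mu + M"
        m_d6 = np.maximum(self.dv_max + self.eta, floor)
        m_d7 = np.maximum(-self.eta - self.dv_min, floor)
        m_z8 = np.maximum(self.dv_max, floor)
        m_z9 = np.maximum(-self.dv_min, floor)

        # up indicator:  zU=1 => dv >= mu ;  zU=0 => dv <= mu
        rows.append(sp.hstack([I, -sp.diags(m_u4), Z, Z]))
        lo.append(self.mu - m_u4)
        hi.append(np.full(n, np.inf))
        rows.append(sp.hstack([I, -sp.diags(m_u5), Z, Z]))
        lo.append(np.full(n, -np.inf))
        hi.append(self.mu)

        # down indicator:  zD=1 => dv <= -eta ;  zD=0 => dv >= -eta
        rows.append(sp.hstack([I, Z, sp.diags(m_d6), Z]))
        lo.append(np.full(n, -np.inf))
        hi.append(-self.eta + m_d6)
        rows.append(sp.hstack([I, Z, sp.diags(m_d7), Z]))
        lo.append(-self.eta)
        hi.append(np.full(n, np.inf))

        # zero indicator:  z0=1 => dv = 0
        rows.append(sp.hstack([I, Z, Z, sp.diags(m_z8)]))
        lo.append(np.full(n, -np.inf))
        hi.append(m_z8)
        rows.append(sp.hstack([I, Z, Z, -sp.diags(m_z9)]))
        lo.append(-m_z9)
        hi.append(np.full(n, np.inf))

        # zU + zD <= 1
        rows.append(sp.hstack([Z, I, I, Z]))
        lo.append(np.zeros(n))
        hi.append(np.ones(n))

        # pair couplings: z0_k + zU_k - zD_k' >= 0 ; z0_k + zD_k - zU_k' >= 0.
        # "symmetric" (default) applies them to both orders of each half pair,
        # which is what actually prevents the two halves from carrying flux
        # change simultaneously; "printed" constrains only the forward half.
        if self.split.pair_map:
            ordered = list(self.split.pair_map)
            if self.pair_coupling == "symmetric":
                ordered += [(kp, k) for k, kp in self.split.pair_map]
            p = len(ordered)
            d1 = sp.lil_matrix((p, 4 * n))
            d2 = sp.lil_matrix((p, 4 * n))
            for r, (k, kp) in enumerate(ordered):
                d1[r, 3 * n + k] = 1; d1[r, n + k] = 1; d1[r, 2 * n + kp] = -1
                d2[r, 3 * n + k] = 1; d2[r, 2 * n + k] = 1; d2[r, n + kp] = -1
            for d in (d1, d2):
                rows.append(sp.csr_matrix(d))
                lo.append(np.zeros(p))
                hi.append(np.full(p, np.inf))

        # measured net-difference overrides on reversible reactions
        if self.net_overrides:
            p = len(self.net_overrides)
            dd = sp.lil_matrix((p, 4 * n))
            olo, ohi = np.empty(p), np.empty(p)
            for r, (oi, (a, b)) in enumerate(sorted(self.net_overrides.items())):
                dd[r, self.split.forward_of[oi]] = 1
                dd[r, self.split.backward_of[oi]] = -1
                olo[r], ohi[r] = a, b
            rows.append(sp.csr_matrix(dd))
            lo.append(olo)
            hi.append(ohi)

        return sp.vstack(rows, format="csr"), np.concatenate(lo), np.concatenate(hi)

    def variable_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        n = self.n
        l = np.concatenate([self.dv_min, np.zeros(3 * n)])
        u = np.concatenate([self.dv_max, np.ones(3 * n)])
        for i in self.forced_zero:
            l[3 * n + i] = 1.0
        if self.z0_mode == "strict":
            for i in range(n):
                if i not in self.forced_zero:
                    u[3 * n + i] = 0.0
        return l, u


@dataclass
class DeltaSolution:
    """A solved flux-difference vector with its indicator assignment."""

    dv_split: np.ndarray
    dv_net: np.ndarray
    z_up: np.ndarray
    z_down: np.ndarray
    z_zero: np.ndarray
    phi_star: float
    step2_norm: float | None
    solver_status: str
    gap: float
    norm: str | None = None
    binaries_mode: str | None = None

    @property
    def balance_residual(self) -> float:
        return self._residual

    def attach_residual(self, split: SplitNetwork) -> "DeltaSolution":
        r = np.abs(split.S_split @ self.dv_split)
        self._residual = float(r.max(initial=0.0))
        return self


class InfeasibleProblem(RuntimeError):
    """Raised when the constraint system admits no solution; the message
    names the constraint groups most likely responsible."""


def build_milp(
    split: SplitNetwork,
    bounds: DeltaBounds,
    reg: RegulationInput,
    M: float | None = None,
    bound_cap: float = DEFAULT_BOUND_CAP,
    z0_mode: str = "free",
    pair_coupling: str = "symmetric",
) -> MILPSpec:
    """Validate inputs and assemble the consistency MILP.

    ``M`` defaults to 1e5 and is auto-raised (with a warning) if the bound
    magnitudes require it; an explicitly passed M that is too small is an
    error.  Infinite flux-difference bounds are capped at ``bound_cap``.
    """
    reg.validate_disjoint(split)
    n = split.n_split
    dv_min = np.clip(bounds.dv_min, -bound_cap, bound_cap)
    dv_max = np.clip(bounds.dv_max, -bound_cap, bound_cap)
    if np.any(dv_min > dv_max):
        raise InfeasibleProblem("dv_min exceeds dv_max after capping")
    mu = np.asarray(reg.mu if reg.mu is not None else np.zeros(n), dtype=float)
    eta = np.asarray(reg.eta if reg.eta is not None else np.zeros(n), dtype=float)
    if mu.size == 1:
        mu = np.full(n, float(mu))
    if eta.size == 1:
        eta = np.full(n, float(eta))

    need = float(np.max(np.concatenate([np.abs(dv_min), np.abs(dv_max), mu, eta])))
    if M is None:
        M = DEFAULT_M
        if M <= need:
            M = 10.0 * need
            warnings.warn(f"default big-M too small for bound magnitudes; raised to {M:g}")
    elif M <= need:
        raise ValueError(f"big-M {M:g} must exceed the largest bound/threshold magnitude {need:g}")

    return MILPSpec(
        split=split, dv_min=dv_min, dv_max=dv_max, mu=mu, eta=eta, M=float(M),
        r_up=dict(reg.r_up), r_down=dict(reg.r_down),
        forced_zero=set(reg.forced_zero),
        net_overrides=dict(bounds.net_overrides), z0_mode=z0_mode,
        pair_coupling=pair_coupling,
    )


def _round_binaries(x: np.ndarray, n: int):
    zb = np.rint(x[n:]).astype(int)
    return zb[:n], zb[n:2 * n], zb[2 * n:]


def _milp_solve(c, A, lo, hi, l, u, integrality, time_limit=None):
    options = {"mip_rel_gap": 0.0}
    if time_limit:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=c,
        constraints=LinearConstraint(A, lo, hi),
        integrality=integrality,
        bounds=Bounds(l, u),
        options=options,
    )
    return res


def _feasible_dv(spec: MILPSpec, z_up, z_down, z_zero,
                 c: np.ndarray | None = None) -> np.ndarray | None:
    """A dv consistent with a fixed binary assignment (optionally minimizing
    ``c @ dv``), or None if that assignment admits no flux difference.

    Needed because the MILP backend's integrality tolerance, amplified by
    big-M, can return continuous values that violate the indicator semantics
    of the *rounded* binaries by up to M x tol; re-solving the continuous
    problem with the binaries pinned restores exact consistency.
    """
    from scipy.optimize import linprog

    lo, hi = _binary_intervals(spec, z_up, z_down, z_zero)
    if np.any(lo > hi + 1e-9):
        return None
    hi = np.maximum(hi, lo)
    A_ov, olo, ohi = _override_rows(spec, spec.n)
    A_ub = b_ub = None
    if A_ov is not None:
        A_ub = np.vstack([A_ov, -A_ov])
        b_ub = np.concatenate([ohi, -olo])
    S = sp.csr_matrix(spec.split.S_split)
    res = linprog(
        c=np.zeros(spec.n) if c is None else c,
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub, b_ub=b_ub,
        bounds=np.column_stack([lo, hi]), method="highs",
    )
    return res.x if res.status == 0 else None


def solve_consistency(
    spec: MILPSpec, time_limit: float | None = None
) -> tuple[float, DeltaSolution]:
    """Step 1: maximize the consistency score Phi.

    Returns (Phi*, incumbent).  Phi* is recomputed from the rounded binary
    assignment, so it is exact in binary arithmetic and always bounded by
    the total regulation weight; the incumbent's dv is re-solved with the
    binaries pinned so indicators and continuous values agree exactly.
    """
    n = spec.n
    A, lo, hi = spec.constraint_system()
    l, u = spec.variable_bounds()
    c_u, c_d = spec.objective_z()
    c = np.concatenate([np.zeros(n), -c_u, -c_d, np.zeros(n)])  # milp minimizes
    integrality = np.concatenate([np.zeros(n), np.ones(3 * n)])
    res = _milp_solve(c, A, lo, hi, l, u, integrality, time_limit)
    if res.status == 2 or res.x is None:
        raise InfeasibleProblem(
            "consistency MILP infeasible: check flux-difference bound overrides, "
            "forced-zero set and net-difference constraints for contradictions"
        )
    z_up, z_down, z_zero = _round_binaries(res.x, n)
    phi_star = spec.phi_of(z_up, z_down)
    status = "optimal" if res.status == 0 else "time_limit"
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    dv = _feasible_dv(spec, z_up, z_down, z_zero)
    if dv is None:
        raise InfeasibleProblem(
            "rounded step-1 binary assignment admits no flux difference "
            "(big-M/integrality tolerance artifact); rescale bounds or lower M"
        )
    sol = DeltaSolution(
        dv_split=dv,
        dv_net=spec.split.net_vector(dv),
        z_up=z_up, z_down=z_down, z_zero=z_zero,
        phi_star=phi_star, step2_norm=None,
        solver_status=status, gap=gap,
    ).attach_residual(spec.split)
    return phi_star, sol


def _phi_row(spec: MILPSpec, n_var: int):
    n = spec.n
    c_u, c_d = spec.objective_z()
    row = np.zeros(n_var)
    row[n:2 * n] = c_u
    row[2 * n:3 * n] = c_d
    return row


def _binary_intervals(spec: MILPSpec, z_up, z_down, z_zero):
    """Per-reaction dv interval implied by a fixed binary assignment."""
    lo = spec.dv_min.copy()
    hi = spec.dv_max.copy()
    up = z_up.astype(bool)
    dn = z_down.astype(bool)
    zz = z_zero.astype(bool)
    lo[up] = np.maximum(lo[up], spec.mu[up])
    hi[~up] = np.minimum(hi[~up], spec.mu[~up])
    hi[dn] = np.minimum(hi[dn], -spec.eta[dn])
    lo[~dn] = np.maximum(lo[~dn], -spec.eta[~dn])
    lo[zz] = np.maximum(lo[zz], 0.0)
    hi[zz] = np.minimum(hi[zz], 0.0)
    return lo, hi


def _override_rows(spec: MILPSpec, n_var: int):
    if not spec.net_overrides:
        return None, None, None
    p = len(spec.net_overrides)
    A = np.zeros((p, n_var))
    lo, hi = np.empty(p), np.empty(p)
    for r, (oi, (a, b)) in enumerate(sorted(spec.net_overrides.items())):
        A[r, spec.split.forward_of[oi]] = 1.0
        A[r, spec.split.backward_of[oi]] = -1.0
        lo[r], hi[r] = a, b
    return A, lo, hi


def _l2_fixed(spec: MILPSpec, incumbent: DeltaSolution) -> np.ndarray:
    lo, hi = _binary_intervals(spec, incumbent.z_up, incumbent.z_down, incumbent.z_zero)
    if np.any(lo > hi + 1e-9):
        raise InfeasibleProblem("incumbent binary assignment admits no flux difference")
    hi = np.maximum(hi, lo)
    A_ov, olo, ohi = _override_rows(spec, spec.n)
    S = spec.split.S_split
    return min_norm_box_eq(
        S, np.zeros(S.shape[0]), lo, hi, incumbent.dv_split,
        A_rng=A_ov, lo_rng=olo, hi_rng=ohi,
    )


def _l1_fixed_lp(spec: MILPSpec, z_up, z_down, z_zero) -> np.ndarray | None:
    """L1-minimal dv for a fixed binary assignment (LP on |dv| epigraph)."""
    from scipy.optimize import linprog

    lo, hi = _binary_intervals(spec, z_up, z_down, z_zero)
    if np.any(lo > hi + 1e-9):
        return None
    hi = np.maximum(hi, lo)
    n = spec.n
    S = sp.csr_matrix(spec.split.S_split)
    A_eq = sp.hstack([S, sp.csr_matrix((S.shape[0], n))], format="csr")
    I = sp.identity(n, format="csr")
    ub_rows = [sp.hstack([I, -I]), sp.hstack([-I, -I])]
    b_ub = [np.zeros(2 * n)]
    A_ov, olo, ohi = _override_rows(spec, n)
    if A_ov is not None:
        A_ov = sp.hstack([sp.csr_matrix(A_ov), sp.csr_matrix((len(olo), n))])
        ub_rows += [A_ov, -A_ov]
        b_ub += [ohi, -olo]
    res = linprog(
        c=np.concatenate([np.zeros(n), np.ones(n)]),
        A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
        A_ub=sp.vstack(ub_rows, format="csr"), b_ub=np.concatenate(b_ub),
        bounds=np.column_stack([
            np.concatenate([lo, np.zeros(n)]),
            np.concatenate([hi, np.full(n, np.inf)]),
        ]),
        method="highs",
    )
    return res.x[:n] if res.status == 0 else None


def _l1_milp(spec: MILPSpec, phi_star: float, fixed: DeltaSolution | None,
             time_limit=None):
    """L1 minimization as a MILP (or LP when binaries are fixed)."""
    n = spec.n
    A, lo, hi = spec.constraint_system()
    l, u = spec.variable_bounds()
    n_base = 4 * n
    # append t variables: t >= dv, t >= -dv
    A = sp.hstack([A, sp.csr_matrix((A.shape[0], n))], format="csr")
    I = sp.identity(n, format="csr")
    Zp = sp.csr_matrix((n, 3 * n))
    t_rows = sp.vstack([
        sp.hstack([I, Zp, -I]),   # dv - t <= 0
        sp.hstack([-I, Zp, -I]),  # -dv - t <= 0
    ], format="csr")
    A = sp.vstack([A, t_rows], format="csr")
    lo = np.concatenate([lo, np.full(2 * n, -np.inf)])
    hi = np.concatenate([hi, np.zeros(2 * n)])
    # Phi = Phi*
    phi_row = _phi_row(spec, n_base + n)
    A = sp.vstack([A, sp.csr_matrix(phi_row)], format="csr")

    l = np.concatenate([l, np.zeros(n)])
    u = np.concatenate([u, np.maximum(np.abs(spec.dv_min), np.abs(spec.dv_max))])
    integrality = np.concatenate([np.zeros(n), np.ones(3 * n), np.zeros(n)])
    if fixed is not None:
        zb = np.concatenate([fixed.z_up, fixed.z_down, fixed.z_zero]).astype(float)
        l[n:n_base] = zb
        u[n:n_base] = zb
    c = np.concatenate([np.zeros(n_base), np.ones(n)])

    for phi_lo, phi_hi in ((phi_star, phi_star), (phi_star - PHI_RELAX, np.inf)):
        res = _milp_solve(
            c, A, np.concatenate([lo, [phi_lo]]), np.concatenate([hi, [phi_hi]]),
            l, u, integrality, time_limit,
        )
        if res.status in (0, 1) and res.x is not None:
            return res
    raise InfeasibleProblem("L1 step infeasible even with relaxed consistency equality")


def _z_feasible(spec: MILPSpec, z_up, z_down, z_zero) -> bool:
    """Check the pure-binary constraints of an assignment: no simultaneous
    up/down flag, forced zeros honored, pair couplings satisfied."""
    if np.any(z_up + z_down > 1):
        return False
    for i in spec.forced_zero:
        if z_zero[i] != 1:
            return False
    if spec.z0_mode == "strict":
        for i in range(spec.n):
            if z_zero[i] == 1 and i not in spec.forced_zero:
                return False
    ordered = list(spec.split.pair_map)
    if spec.pair_coupling == "symmetric":
        ordered += [(kp, k) for k, kp in spec.split.pair_map]
    for k, kp in ordered:
        if z_zero[k] + z_up[k] < z_down[kp] or z_zero[k] + z_down[k] < z_up[kp]:
            return False
    return True


def _l2_branch_and_bound(spec: MILPSpec, phi_star: float, incumbent: DeltaSolution,
                         node_limit: int = 2000):
    """Mixed-integer L2 step via best-first branch-and-bound over the binaries.

    The incumbent starts at the fixed-binaries QP solution, so the search can
    only improve on it.  Node bounds come from a rigorous valid inequality:
    any integer solution with ``zU_i = 1`` has ``dv_i^2 >= mu_i^2`` (and
    ``zD_i = 1`` gives ``eta_i^2``), so the LP minimum of
    ``sum(mu^2 zU + eta^2 zD)`` under the node's constraints lower-bounds the
    achievable squared norm.  Integral LP solutions are evaluated exactly by
    the continuous QP with the binaries pinned.  Returns (dv, z, status),
    status "node_limit" when the search was truncated (the incumbent is then
    still feasible and no worse than the fixed-binaries answer).
    """
    from scipy.optimize import linprog as _linprog

    n = spec.n
    A, lo, hi = spec.constraint_system()
    phi_row = _phi_row(spec, 4 * n)
    A = sp.vstack([A, sp.csr_matrix(phi_row)], format="csr")
    lo = np.concatenate([lo, [phi_star]])
    hi = np.concatenate([hi, [phi_star]])
    l0, u0 = spec.variable_bounds()

    best_dv = _l2_fixed(spec, incumbent)
    best_obj = float(best_dv @ best_dv)
    best_z = (incumbent.z_up, incumbent.z_down, incumbent.z_zero)

    cut = np.concatenate([np.zeros(n), spec.mu ** 2, spec.eta ** 2, np.zeros(n)])
    fin_hi = np.isfinite(hi)
    fin_lo = np.isfinite(lo)
    A_ub_cut = sp.vstack([A[fin_hi], -A[fin_lo]], format="csr")
    b_ub_cut = np.concatenate([hi[fin_hi], -lo[fin_lo]])

    def node_lp(l, u):
        res = _linprog(c=cut, A_ub=A_ub_cut, b_ub=b_ub_cut,
                       bounds=np.column_stack([l, u]), method="highs")
        if res.status != 0:
            return None
        return float(res.fun), res.x

    tol = 1e-6
    counter = 0
    heap: list = []
    seen: set[bytes] = set()

    def push(bound, l, u):
        nonlocal counter
        heapq.heappush(heap, (bound, counter, l, u))
        counter += 1

    def try_incumbent(z_up, z_down, z_zero) -> None:
        nonlocal best_obj, best_dv, best_z
        key = np.concatenate([z_up, z_down, z_zero]).astype(np.int8).tobytes()
        if key in seen:
            return
        seen.add(key)
        if abs(spec.phi_of(z_up, z_down) - phi_star) > 1e-9:
            return
        if not _z_feasible(spec, z_up, z_down, z_zero):
            return
        cand = DeltaSolution(
            dv_split=best_dv, dv_net=spec.split.net_vector(best_dv),
            z_up=z_up, z_down=z_down, z_zero=z_zero,
            phi_star=phi_star, step2_norm=None, solver_status="", gap=0.0)
        try:
            dv = _l2_fixed(spec, cand)
        except InfeasibleProblem:
            return
        obj = float(dv @ dv)
        if obj < best_obj - 1e-15:
            best_obj, best_dv, best_z = obj, dv, (z_up, z_down, z_zero)

    push(0.0, l0, u0)
    nodes = 0
    status = "optimal"
    while heap:
        bound, _, l, u = heapq.heappop(heap)
        if bound >= best_obj - 1e-12:
            continue
        nodes += 1
        if nodes > node_limit:
            status = "node_limit"
            break
        out = node_lp(l, u)
        if out is None:
            continue
        lb_ind, x = out
        if lb_ind >= best_obj - 1e-12:
            continue
        zpart = x[n:]
        frac = np.abs(zpart - np.rint(zpart))
        j = int(np.argmax(frac))
        z_up, z_down, z_zero = _round_binaries(x, n)
        try_incumbent(z_up, z_down, z_zero)
        if frac[j] <= tol:
            continue  # integral node: fully evaluated above
        jv = n + j
        for fix in (0.0, 1.0):
            ll, uu = l.copy(), u.copy()
            ll[jv] = uu[jv] = fix
            push(lb_ind, ll, uu)
    return best_dv, best_z, status


def minimize_norm(
    spec: MILPSpec,
    phi_star: float,
    incumbent: DeltaSolution,
    norm: str = "L2",
    binaries: str = "free",
    time_limit: float | None = None,
    node_limit: int = 2000,
) -> DeltaSolution:
    """Step 2: the norm-minimal flux difference at consistency level Phi*.

    norm="L2" minimizes ``||dv||_2^2`` (unique dv for a fixed binary
    assignment), norm="L1" minimizes ``||dv||_1``.  binaries="free" searches
    over all binary assignments achieving Phi* (faithful, mixed-integer);
    binaries="fixed" freezes the step-1 incumbent's assignment (continuous,
    fast).  The achieved Phi equals Phi* exactly in both modes.
    """
    n = spec.n
    norm = norm.upper()
    if norm == "L1":
        if binaries == "fixed":
            z_up, z_down, z_zero = incumbent.z_up, incumbent.z_down, incumbent.z_zero
            status = "optimal"
        else:
            res = _l1_milp(spec, phi_star, None, time_limit)
            z_up, z_down, z_zero = _round_binaries(res.x[:4 * n], n)
            status = "optimal" if res.status == 0 else "time_limit"
        # continuous re-solve with pinned binaries for exact consistency
        dv = _l1_fixed_lp(spec, z_up, z_down, z_zero)
        if dv is None:
            raise InfeasibleProblem("L1 binary assignment admits no flux difference")
    elif norm == "L2":
        if binaries == "fixed":
            dv = _l2_fixed(spec, incumbent)
            z_up, z_down, z_zero = incumbent.z_up, incumbent.z_down, incumbent.z_zero
            status = "optimal"
        else:
            dv, (z_up, z_down, z_zero), status = _l2_branch_and_bound(
                spec, phi_star, incumbent, node_limit)
    else:
        raise ValueError(f"norm must be 'L1' or 'L2', got {norm!r}")

    achieved = spec.phi_of(z_up, z_down)
    if abs(achieved - phi_star) > 1e-9:
        raise InfeasibleProblem(
            f"step-2 consistency {achieved} does not match Phi* = {phi_star}")
    step2_norm = float(np.abs(dv).sum()) if norm == "L1" else float(dv @ dv)
    return DeltaSolution(
        dv_split=dv,
        dv_net=spec.split.net_vector(dv),
        z_up=z_up, z_down=z_down, z_zero=z_zero,
        phi_star=phi_star,
        step2_norm=step2_norm,
        solver_status=status, gap=0.0,
        norm=norm, binaries_mode=binaries,
    ).attach_residual(spec.split)


def net_delta(sol: DeltaSolution, split: SplitNetwork) -> np.ndarray:
    """Per-original-reaction flux difference: forward minus backward half."""
    return split.net_vector(sol.dv_split)


def solve_two_step(
    spec: MILPSpec,
    norm: str = "L2",
    binaries: str = "free",
    time_limit: float | None = None,
    node_limit: int = 2000,
) -> DeltaSolution:
    """Run step 1 (consistency) then step 2 (norm minimization)."""
    phi_star, incumbent = solve_consistency(spec, time_limit)
    return minimize_norm(spec, phi_star, incumbent, norm=norm,
                         binaries=binaries, time_limit=time_limit,
                         node_limit=node_limit)
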