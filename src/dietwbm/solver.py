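"""Flux balance analysis and L2-parsimonious FBA.

The simulation protocol: pin the whole-body maintenance reaction flux to one
(lower bound = upper bound = maintenance value), then minimize the Euclidean
norm of the flux vector — sum of squared fluxes over *all* reactions,
exchanges and maintenance included — subject to steady-state mass balance
``S v = 0`` and the flux bounds.  The objective is strictly convex, so the
optimum is the unique projection of the origin onto the feasible
affine-and-box set.

Implementation: variables pinned by equal bounds are eliminated exactly;
the reduced convex QP is solved by scipy's trust-constr and then polished to
machine precision with a primal-dual active-set iteration on the KKT system.
``qp_oracle`` solves the same QP by exhaustive active-set enumeration and is
intended purely as an independent test oracle for tiny models.
"""

from __future__ import annotations

import enum
import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize, sparse

from .model_core import INF_BOUND, ReactionKind, WholeBodyModel


class SolverStatus(str, enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    NUMERIC_FAILURE = "numeric_failure"


class FluxNorm(str, enum.Enum):
    L2 = "L2"
    L1 = "L1"


@dataclass(frozen=True)
class SolverSettings:
    norm: FluxNorm = FluxNorm.L2
    feasibility_tol: float = 1e-8
    optimality_tol: float = 1e-8
    mass_balance_tol: float = 1e-6
    maintenance_value: float = 1.0

    def __post_init__(self) -> None:
        for name in ("feasibility_tol", "optimality_tol", "mass_balance_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isfinite(self.maintenance_value):
            raise ValueError("maintenance_value must be finite")


@dataclass
class FluxSolution:
    fluxes: dict[str, float]
    objective: float
    status: SolverStatus
    max_mass_balance_residual: float = math.nan
    max_bound_violation: float = math.nan

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["reaction_id\tflux"]
        lines += [f"{r}\t{v:.12g}" for r, v in self.fluxes.items()]
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "status": self.status.value,
            "objective": self.objective,
            "max_mass_balance_residual": self.max_mass_balance_residual,
            "max_bound_violation": self.max_bound_violation,
            "fluxes": self.fluxes,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")


class OracleSizeError(ValueError):
    """qp_oracle refuses models above its exhaustive-enumeration cap."""


# ---------------------------------------------------------------------------
# shared pieces
# ---------------------------------------------------------------------------

def _problem_arrays(model: WholeBodyModel, settings: SolverSettings | None,
                    pin_maintenance: bool):
    S = model.stoichiometric_matrix().tocsc()
    lb, ub = model.bounds()
    if pin_maintenance:
        j = model.reaction_ids.index(model.maintenance_reaction_id)
        lb = lb.copy()
        ub = ub.copy()
        lb[j] = ub[j] = settings.maintenance_value
    return S, lb, ub


def _residuals(S, v, lb, ub) -> tuple[float, float]:
    mass = float(np.max(np.abs(S @ v))) if S.shape[0] else 0.0
    bound = float(np.max(np.maximum(lb - v, 0) + np.maximum(v - ub, 0)))
    return mass, bound


def _solution(model: WholeBodyModel, v: np.ndarray, S, lb, ub,
              objective: float, status: SolverStatus) -> FluxSolution:
    mass, bound = _residuals(S, v, lb, ub)
    return FluxSolution(
        fluxes={r: float(x) for r, x in zip(model.reaction_ids, v)},
        objective=float(objective), status=status,
        max_mass_balance_residual=mass, max_bound_violation=bound,
    )


def _feasible_point(S, lb, ub) -> np.ndarray | None:
    """A feasible flux vector via LP, or None if the polytope is empty."""
    res = optimize.linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
                           bounds=list(zip(lb, ub)), method="highs")
    return res.x if res.status == 0 else None


def _reduce_equalities(A: np.ndarray, d: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Project ``A x = d`` onto an independent row basis (consistency assumed,
    which holds whenever a feasible point exists)."""
    if A.shape[0] == 0:
        return A, d
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    tol = max(A.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    r = int(np.sum(s > tol))
    Ur = U[:, :r]
    return Ur.T @ A, Ur.T @ d


# ---------------------------------------------------------------------------
# exact equality-constrained sub-solves (used by polish and oracle)
# ---------------------------------------------------------------------------

def _min_norm_on_active_set(A: np.ndarray, d: np.ndarray, lb: np.ndarray,
                            ub: np.ndarray, state: np.ndarray,
                            feas_tol: float):
    """Solve min ||x||^2 s.t. A x = d with variables clamped per ``state``.

    ``state``: 0 free, -1 at lower bound, +1 at upper bound.  Returns
    (x, mu, consistent) where mu are the equality multipliers and
    ``consistent`` flags whether the clamped system admits a solution.
    """
    n = A.shape[1]
    x = np.zeros(n)
    x[state == -1] = lb[state == -1]
    x[state == +1] = ub[state == +1]
    free = state == 0
    rhs = d - A[:, ~free] @ x[~free]
    A_f = A[:, free]
    if free.any():
        x_f, *_ = np.linalg.lstsq(A_f, rhs, rcond=None)
        if np.linalg.norm(A_f @ x_f - rhs, ord=np.inf) > feas_tol * max(
                1.0, float(np.linalg.norm(rhs, ord=np.inf))):
            return x, None, False
        x[free] = x_f
        mu, *_ = np.linalg.lstsq(A_f.T, -2.0 * x_f, rcond=None)
    else:
        if rhs.size and np.linalg.norm(rhs, ord=np.inf) > feas_tol:
            return x, None, False
        mu, *_ = np.linalg.lstsq(A.T, -2.0 * x, rcond=None)
    return x, mu, True


def _kkt_ok(A, x, mu, lb, ub, state, clampable, tol) -> bool:
    """Primal feasibility of free vars + dual sign conditions on active ones."""
    free = state == 0
    if np.any(x[free] < lb[free] - tol) or np.any(x[free] > ub[free] + tol):
        return False
    lam = 2.0 * x + A.T @ mu  # -lambda_lb + lambda_ub = -lam
    at_lb = (state == -1) & clampable
    at_ub = (state == +1) & clampable
    # at lower bound: lambda_lb = lam >= 0 ; at upper: lambda_ub = -lam >= 0
    if np.any(lam[at_lb] < -tol) or np.any(lam[at_ub] > tol):
        return False
    return True


def _active_set_polish(A, d, lb, ub, x0, feas_tol=1e-10, dual_tol=1e-9,
                       max_iter=300):
    """Refine an approximate box-constrained min-norm point to a KKT point.

    Primal active-set method for ``min ||x||^2 s.t. A x = d, lb <= x <= ub``
    started from a (near-)feasible ``x0``: the working set only ever holds
    bounds active at the current iterate, so the clamped subproblem always
    contains the iterate and stays consistent; steps are line-searched to
    the first blocking bound, and wrong-sign multipliers release their
    constraint.  Returns None if it fails to settle within ``max_iter``.
    """
    n = A.shape[1]
    fixed = lb == ub
    x = np.clip(np.asarray(x0, dtype=float), lb, ub)
    state = np.zeros(n, dtype=int)
    state[fixed] = -1
    prox = 1e-9 * np.maximum(1.0, np.abs(x))
    state[(~fixed) & (x <= lb + prox)] = -1
    state[(~fixed) & (x >= ub - prox)] = +1
    clampable = ~fixed

    for _ in range(max_iter):
        z, mu, ok = _min_norm_on_active_set(A, d, lb, ub, state, feas_tol)
        if not ok:
            # cannot happen once the iterate is feasible; bail out
            return None
        p = z - x
        if np.max(np.abs(p)) <= 1e-13 * max(1.0, float(np.max(np.abs(x)))):
            lam = 2.0 * z + A.T @ mu
            bad_lb = np.where((state == -1) & clampable, -lam, -np.inf)
            bad_ub = np.where((state == +1) & clampable, lam, -np.inf)
            worst = max(bad_lb.max(initial=-np.inf), bad_ub.max(initial=-np.inf))
            if worst <= dual_tol:
                return np.clip(z, lb, ub)
            if bad_lb.max(initial=-np.inf) >= bad_ub.max(initial=-np.inf):
                state[int(np.argmax(bad_lb))] = 0
            else:
                state[int(np.argmax(bad_ub))] = 0
            x = z
            continue
        # line search to the first blocking bound among free variables
        alpha = 1.0
        block = -1
        block_side = 0
        freem = state == 0
        for j in np.flatnonzero(freem):
            if p[j] > feas_tol:
                a = (ub[j] - x[j]) / p[j]
                side = +1
            elif p[j] < -feas_tol:
                a = (lb[j] - x[j]) / p[j]
                side = -1
            else:
                continue
            if a < alpha:
                alpha, block, block_side = a, j, side
        alpha = max(alpha, 0.0)
        x = x + alpha * p
        if block >= 0 and alpha < 1.0:
            x[block] = ub[block] if block_side > 0 else lb[block]
            state[block] = block_side
        # alpha == 1: x == z; the next round checks optimality via duals
    return None


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

def pfba(model: WholeBodyModel, settings: SolverSettings | None = None) -> FluxSolution:
    """Parsimonious FBA: minimize the sum of squared fluxes at maintenance = 1.

    The maintenance reaction's bounds are overridden to the pinned value
    before solving.  L2 is the protocol norm; L1 (minimal total flux) is
    available as a fallback but is a different parsimony criterion.
    """
    settings = settings or SolverSettings()
    S, lb, ub = _problem_arrays(model, settings, pin_maintenance=True)
    if np.any(lb > ub):
        return FluxSolution({}, math.nan, SolverStatus.INFEASIBLE)
    if settings.norm is FluxNorm.L1:
        return _pfba_l1(model, S, lb, ub)

    x_feas = _feasible_point(S, lb, ub)
    if x_feas is None:
        return FluxSolution({}, math.nan, SolverStatus.INFEASIBLE)

    n = S.shape[1]
    fixed = lb == ub
    free = ~fixed
    Sd = np.asarray(S.todense())
    d_full = np.zeros(S.shape[0])
    v = np.empty(n)
    v[fixed] = lb[fixed]

    if free.any():
        A = Sd[:, free]
        d = d_full - Sd[:, fixed] @ lb[fixed]
        A, d = _reduce_equalities(A, d)
        lb_f, ub_f, x0 = lb[free], ub[free], x_feas[free]
        res = optimize.minimize(
            lambda x: float(x @ x), x0, jac=lambda x: 2.0 * x,
            hess=lambda x: 2.0 * sparse.identity(x.size, format="csr"),
            method="trust-constr",
            constraints=[optimize.LinearConstraint(A, d, d)],
            bounds=optimize.Bounds(lb_f, ub_f),
            options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 3000, "verbose": 0},
        )
        x = _active_set_polish(A, d, lb_f, ub_f, res.x)
        if x is None:
            x = res.x
            if not res.success and res.status not in (1, 2):
                sol = _solution(model, _assemble(v, x, free), S, lb, ub,
                                float(np.sum(v**2)), SolverStatus.NUMERIC_FAILURE)
                return sol
        v[free] = x

    objective = float(v @ v)
    sol = _solution(model, v, S, lb, ub, objective, SolverStatus.OPTIMAL)
    if (sol.max_mass_balance_residual
            > settings.mass_balance_tol * max(1.0, float(np.max(np.abs(v))))
            or sol.max_bound_violation > settings.feasibility_tol * 10):
        sol.status = SolverStatus.NUMERIC_FAILURE
    return sol


def _assemble(v, x, free):
    v = v.copy()
    v[free] = x
    return v


def _pfba_l1(model: WholeBodyModel, S, lb, ub) -> FluxSolution:
    """Minimal total flux via positive/negative splitting (LP)."""
    n = S.shape[1]
    # variables [v, t], minimize sum t, with -t <= v <= t
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = sparse.hstack([S, sparse.csr_matrix(S.shape)])
    I = sparse.identity(n, format="csr")
    A_ub = sparse.vstack([sparse.hstack([I, -I]), sparse.hstack([-I, -I])])
    b_ub = np.zeros(2 * n)
    bounds = list(zip(lb, ub)) + [(0, None)] * n
    res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                           b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status == 2:
        return FluxSolution({}, math.nan, SolverStatus.INFEASIBLE)
    if res.status != 0:
        return FluxSolution({}, math.nan, SolverStatus.NUMERIC_FAILURE)
    v = res.x[:n]
    return _solution(model, v, S, lb, ub, float(np.sum(np.abs(v))),
                     SolverStatus.OPTIMAL)


# ---------------------------------------------------------------------------
# FBA (LP)
# ---------------------------------------------------------------------------

def fba(model: WholeBodyModel, objective_reaction: str,
        sense: str = "max") -> FluxSolution:
    """Linear FBA: optimize one reaction's flux subject to S v = 0 and bounds."""
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    ids = model.reaction_ids
    if objective_reaction not in ids:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    S, lb, ub = _problem_arrays(model, None, pin_maintenance=False)
    c = np.zeros(len(ids))
    c[ids.index(objective_reaction)] = -1.0 if sense == "max" else 1.0
    res = optimize.linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                           bounds=list(zip(lb, ub)), method="highs")
    if res.status == 2:
        return FluxSolution({}, math.nan, SolverStatus.INFEASIBLE)
    if res.status == 3:
        return FluxSolution({}, math.nan, SolverStatus.UNBOUNDED)
    if res.status != 0:
        return FluxSolution({}, math.nan, SolverStatus.NUMERIC_FAILURE)
    v = res.x
    obj = float(v[ids.index(objective_reaction)])
    return _solution(model, v, S, lb, ub, obj, SolverStatus.OPTIMAL)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

ORACLE_MAX_REACTIONS = 12


def qp_oracle(model: WholeBodyModel,
              settings: SolverSettings | None = None) -> FluxSolution:
    """Solve the pFBA QP by dense KKT with exhaustive active-set enumeration.

    Test oracle only: every assignment of {free, at-lb, at-ub} to each
    reaction's bound constraints is tried (smallest active sets first) and
    the first KKT-consistent point is returned — for a strictly convex QP a
    KKT point is the unique global optimum.  Refuses models with more than
    12 reactions.
    """
    settings = settings or SolverSettings()
    n = len(model.reactions)
    if n > ORACLE_MAX_REACTIONS:
        raise OracleSizeError(
            f"qp_oracle caps at {ORACLE_MAX_REACTIONS} reactions, got {n}")
    S, lb, ub = _problem_arrays(model, settings, pin_maintenance=True)
    if np.any(lb > ub):
        return FluxSolution({}, math.nan, SolverStatus.INFEASIBLE)
    A = np.asarray(S.todense())
    d = np.zeros(A.shape[0])
    fixed = lb == ub
    clampable = ~fixed
    candidates = []
    for j in range(n):
        if fixed[j]:
            candidates.append((-1,))
            continue
        states = [0]
        if lb[j] > -INF_BOUND * 0.999:
            states.append(-1)
        if ub[j] < INF_BOUND * 0.999:
            states.append(+1)
        candidates.append(tuple(states))

    tol = 1e-9
    assignments = sorted(itertools.product(*candidates),
                         key=lambda s: sum(1 for j, st in enumerate(s)
                                           if st != 0 and not fixed[j]))
    for assignment in assignments:
        state = np.array(assignment, dtype=int)
        x, mu, ok = _min_norm_on_active_set(A, d, lb, ub, state, feas_tol=1e-9)
        if not ok or mu is None:
            continue
        if _kkt_ok(A, x, mu, lb, ub, state, clampable, tol):
            x = np.clip(x, lb, ub)
            return _solution(model, x, S, lb, ub, float(x @ x),
                             SolverStatus.OPTIMAL)
    if _feasible_point(S, lb, ub) is None:
        return FluxSolution({}, math.nan, SolverStatus.INFEASIBLE)
    return FluxSolution({}, math.nan, SolverStatus.NUMERIC_FAILURE)


# ---------------------------------------------------------------------------
# infeasibility diagnosis
# ---------------------------------------------------------------------------

def diagnose_infeasibility(model: WholeBodyModel,
                           settings: SolverSettings | None = None
                           ) -> list[dict[str, float | str]]:
    """Minimal bound relaxations (diet exchanges + maintenance) restoring feasibility.

    Solves an LP minimizing the total slack added to the relaxable bounds;
    returns entries {reaction_id, relaxation} with nonzero slack, sorted
    descending.  An empty list means the model is already feasible.
    Maintenance slack is charged ten times the diet slack so the diagnosis
    localizes to missing nutrients rather than to giving up the
    physiological demand; maintenance relaxation is reported only when no
    diet can supply it.
    """
    settings = settings or SolverSettings()
    S, lb, ub = _problem_arrays(model, settings, pin_maintenance=True)
    n = S.shape[1]
    relaxable = np.array([
        r.kind in (ReactionKind.DIET_EXCHANGE, ReactionKind.MAINTENANCE)
        for r in model.reactions
    ])
    k = int(relaxable.sum())
    if k == 0:
        raise ValueError("model has no relaxable (diet/maintenance) reactions")
    R = sparse.csr_matrix(
        (np.ones(k), (np.flatnonzero(relaxable), np.arange(k))), shape=(n, k))
    # variables [v, s_lo, s_hi]; relaxed bounds lb - s_lo <= v <= ub + s_hi
    weights = np.array([
        10.0 if model.reactions[j].kind is ReactionKind.MAINTENANCE else 1.0
        for j in np.flatnonzero(relaxable)])
    c = np.concatenate([np.zeros(n), weights, weights])
    Z = sparse.csr_matrix((n, k))
    I = sparse.identity(n, format="csr")
    A_ub = sparse.vstack([
        sparse.hstack([I, Z, -R]),    # v - s_hi <= ub (on relaxable cols)
        sparse.hstack([-I, -R, Z]),   # -v - s_lo <= -lb
    ])
    b_ub = np.concatenate([ub, -lb])
    A_eq = sparse.hstack([S, sparse.csr_matrix((S.shape[0], 2 * k))])
    bounds = [(None, None)] * n + [(0, None)] * (2 * k)
    res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                           b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError("slack LP failed; model is structurally inconsistent")
    s_lo = res.x[n:n + k]
    s_hi = res.x[n + k:]
    relax_ids = [model.reactions[j].id for j in np.flatnonzero(relaxable)]
    out = []
    for rid, a, b in zip(relax_ids, s_lo, s_hi):
        total = float(a + b)
        if total > 1e-9:
            out.append({"reaction_id": rid, "relaxation": total})
    out.sort(key=lambda e: (-e["relaxation"], e["reaction_id"]))
    return out
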