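"""Optimization engines over metabolic models: FBA, FVA, minimum-norm flux
distributions, blocked-reaction and dead-end detection, and sanity checks.

All linear programs are assembled from the model's stoichiometric matrix plus
any ``extra_constraints`` rows (community coupling constraints) and handed to
a single solver contract, :func:`solve_lp`, backed by HiGHS through
``scipy.optimize.linprog`` with deterministic single-threaded settings.  The
minimum-euclidean-norm problem is the one quadratic program in the package
and is solved with a trust-region constrained optimizer; a pure-LP 1-norm
variant is available.

Tolerances: feasibility ``1e-6`` (max |S v|), blocked-flux threshold
``1e-6``; both are module constants, overridable per call, and recorded in
every report that uses them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .model_core import MetabolicModel, Reaction, stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "FvaResult",
    "SanityReport",
    "SolverError",
    "FEASIBILITY_TOL",
    "BLOCKED_TOL",
    "solve_lp",
    "fba",
    "fva",
    "min_norm_solution",
    "find_blocked_reactions",
    "find_dead_end_metabolites",
    "run_sanity_checks",
]

FEASIBILITY_TOL = 1e-6
BLOCKED_TOL = 1e-6

#: HiGHS options fixed for reproducibility
_LP_OPTIONS = {"presolve": True}


class SolverError(RuntimeError):
    """Raised when the backend fails in a way that is not a clean
    infeasible/unbounded status."""


@dataclass
class FluxSolution:
    """Outcome of one flux optimization.

    ``objective`` is the optimal value ``Z*`` (in the requested sense) when
    ``status == 'optimal'``.  ``shadow_prices`` are the duals of the
    steady-state rows (sensitivity of ``Z*`` to metabolite accumulation) and
    ``reduced_costs`` the duals of the flux bounds, both reported in the
    *maximization* sign convention.
    """

    status: str
    objective: float = math.nan
    fluxes: dict[str, float] = field(default_factory=dict)
    shadow_prices: dict[str, float] = field(default_factory=dict)
    reduced_costs: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FvaResult:
    """Per-reaction flux ranges at an optimality fraction ``gamma``."""

    ranges: dict[str, tuple[float, float]]
    gamma: float
    objective_floor: float
    failures: dict[str, str] = field(default_factory=dict)

    def span(self, rid: str) -> float:
        vmin, vmax = self.ranges[rid]
        return vmax - vmin

    def spans(self) -> dict[str, float]:
        return {rid: vmax - vmin for rid, (vmin, vmax) in self.ranges.items()}


@dataclass
class SanityReport:
    """COBRA-style structural health report for a model."""

    leaking_metabolites: list[str] = field(default_factory=list)
    blocked_reactions: list[str] = field(default_factory=list)
    dead_end_metabolites: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.leaking_metabolites or self.blocked_reactions
                    or self.dead_end_metabolites)


# ---------------------------------------------------------------------------
# solver contract
# ---------------------------------------------------------------------------

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(c, A_eq=None, b_eq=None, A_ub=None, b_ub=None, bounds=None):
    """Minimize ``c @ x`` subject to ``A_eq x = b_eq``, ``A_ub x <= b_ub``
    and box bounds.  Returns the scipy result with a normalised ``.status``
    string attached as ``.status_str``.  Deterministic HiGHS dual simplex.
    """
    res = linprog(
        c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds,
        method="highs-ds", options=_LP_OPTIONS,
    )
    if res.status not in _STATUS:
        raise SolverError(f"LP solver failure: {res.message}")
    res.status_str = _STATUS[res.status]
    return res


def _assemble(model: MetabolicModel):
    """(reaction ids, S, lb, ub, c, A_ub, b_ub) for the model's LP."""
    rids = model.reaction_ids
    ridx = {rid: j for j, rid in enumerate(rids)}
    S = stoichiometric_matrix(model)
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    c = np.zeros(len(rids))
    for rid, w in model.objective.items():
        c[ridx[rid]] = w
    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    n = len(rids)
    for coeffs, sense, rhs in model.extra_constraints:
        row = np.zeros(n)
        for rid, coef in coeffs.items():
            row[ridx[rid]] = coef
        if sense == "==":
            eq_rows.append(row)
            eq_rhs.append(rhs)
        elif sense == "<=":
            ub_rows.append(row)
            ub_rhs.append(rhs)
        elif sense == ">=":
            ub_rows.append(-row)
            ub_rhs.append(-rhs)
        else:
            raise ValueError(f"unknown constraint sense {sense!r}")
    A_eq = sparse.vstack([S] + [sparse.csr_matrix(r) for r in eq_rows]) if eq_rows else S
    b_eq = np.concatenate([np.zeros(S.shape[0]), np.array(eq_rhs)]) if eq_rows else np.zeros(S.shape[0])
    A_ub = sparse.vstack([sparse.csr_matrix(r) for r in ub_rows]) if ub_rows else None
    b_ub = np.array(ub_rhs) if ub_rows else None
    return rids, S, lb, ub, c, A_eq, b_eq, A_ub, b_ub


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def fba(model: MetabolicModel, sense: str = "max") -> FluxSolution:
    """Flux balance analysis: optimize ``c . v`` s.t. ``S v = 0``,
    ``lb <= v <= ub`` (plus any coupling rows).

    Infeasible/unbounded outcomes are encoded in ``status``, never raised.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    if not model.objective:
        raise ValueError("model objective is empty")
    rids, S, lb, ub, c, A_eq, b_eq, A_ub, b_ub = _assemble(model)
    sgn = -1.0 if sense == "max" else 1.0
    res = solve_lp(sgn * c, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub,
                   bounds=np.column_stack([lb, ub]))
    if res.status_str != "optimal":
        return FluxSolution(status=res.status_str)
    v = res.x
    n_met = S.shape[0]
    # scipy reports duals for the minimization; flip into max convention
    shadow = dict(zip(model.metabolite_ids, -sgn * np.asarray(res.eqlin.marginals)[:n_met]))
    reduced = dict(zip(
        rids, -sgn * (np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals))
    ))
    return FluxSolution(
        status="optimal",
        objective=float(c @ v),
        fluxes=dict(zip(rids, map(float, v))),
        shadow_prices=shadow,
        reduced_costs=reduced,
    )


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

def _objective_floor(zstar: float, gamma: float) -> float:
    # relaxed slightly so floating-point optima do not empty the feasible set
    return gamma * zstar - FEASIBILITY_TOL * max(1.0, abs(zstar))


def fva(
    model: MetabolicModel,
    gamma: float = 1.0,
    reactions: list[str] | None = None,
    sense: str = "max",
) -> FvaResult:
    """Flux variability analysis at optimality fraction ``gamma``.

    For each requested reaction, minimize and maximize its flux subject to
    the steady-state system and ``c . v >= gamma * Z*`` (for maximization;
    the floor is skipped when the model has no objective or ``gamma`` is 0).
    Per-reaction solver failures are collected in ``failures`` rather than
    aborting the sweep.
    """
    rids, S, lb, ub, c, A_eq, b_eq, A_ub, b_ub = _assemble(model)
    ridx = {rid: j for j, rid in enumerate(rids)}
    targets = reactions if reactions is not None else rids
    missing = [rid for rid in targets if rid not in ridx]
    if missing:
        raise KeyError(f"FVA targets not in model: {missing}")

    floor = -math.inf
    use_floor = bool(model.objective) and gamma > 0
    if use_floor:
        base = fba(model, sense=sense)
        if not base.optimal:
            raise SolverError(f"FVA requires an optimal base FBA, got {base.status}")
        floor = _objective_floor(base.objective, gamma)
        floor_row = sparse.csr_matrix(-c if sense == "max" else c)
        floor_rhs = np.array([-floor if sense == "max" else floor])
        A_ub = sparse.vstack([A_ub, floor_row]) if A_ub is not None else floor_row
        b_ub = np.concatenate([b_ub, floor_rhs]) if b_ub is not None else floor_rhs

    bounds = np.column_stack([lb, ub])
    ranges: dict[str, tuple[float, float]] = {}
    failures: dict[str, str] = {}
    n = len(rids)
    for rid in targets:
        j = ridx[rid]
        obj = np.zeros(n)
        obj[j] = 1.0
        lo = solve_lp(obj, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
        hi = solve_lp(-obj, A_eq=A_eq, b_eq=b_eq, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
        if lo.status_str != "optimal" or hi.status_str != "optimal":
            failures[rid] = f"min: {lo.status_str}, max: {hi.status_str}"
            continue
        vmin, vmax = float(lo.x[j]), float(hi.x[j])
        if vmin > vmax:  # numerical jitter on forced fluxes
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FvaResult(ranges=ranges, gamma=gamma,
                     objective_floor=floor if use_floor else -math.inf,
                     failures=failures)


# ---------------------------------------------------------------------------
# minimum-norm flux distribution
# ---------------------------------------------------------------------------

def min_norm_solution(model: MetabolicModel, norm: str = "euclidean") -> FluxSolution:
    """Among alternate FBA optima, the flux vector of minimal norm.

    ``euclidean`` solves the strictly convex QP
    ``min ||v||^2  s.t.  S v = 0, bounds, c . v = Z*`` (unique solution;
    spurious internal cycles drop to zero).  ``one`` solves the equivalent
    LP with flux-splitting — cheaper but possibly non-unique.
    """
    base = fba(model, sense="max")
    if not base.optimal:
        return FluxSolution(status=base.status)
    zstar = base.objective
    rids, S, lb, ub, c, A_eq, b_eq, A_ub, b_ub = _assemble(model)
    n = len(rids)

    if norm == "one":
        # v = p - q with p, q >= 0; minimize sum(p + q)
        I = sparse.eye(n, format="csr")
        A_eq2 = sparse.hstack([A_eq @ I, -(A_eq @ I)], format="csr")
        A_eq2 = sparse.vstack([A_eq2, sparse.csr_matrix(np.concatenate([c, -c]))])
        b_eq2 = np.concatenate([b_eq, [zstar]])
        A_ub2 = None
        b_ub2 = None
        if A_ub is not None:
            A_ub2 = sparse.hstack([A_ub, -A_ub], format="csr")
            b_ub2 = b_ub
        # p - q must respect the original box: lb <= p - q <= ub
        box = sparse.hstack([I, -I], format="csr")
        rows = sparse.vstack([box, -box])
        rhs = np.concatenate([ub, -lb])
        A_ub2 = sparse.vstack([A_ub2, rows]) if A_ub2 is not None else rows
        b_ub2 = np.concatenate([b_ub2, rhs]) if b_ub2 is not None else rhs
        cost = np.ones(2 * n)
        big = max(1e4, float(np.max(np.abs(np.concatenate([lb, ub])))))
        res = solve_lp(cost, A_eq=A_eq2, b_eq=b_eq2, A_ub=A_ub2, b_ub=b_ub2,
                       bounds=[(0, big)] * (2 * n))
        if res.status_str != "optimal":
            return FluxSolution(status=res.status_str)
        v = res.x[:n] - res.x[n:]
        return FluxSolution(status="optimal", objective=float(c @ v),
                            fluxes=dict(zip(rids, map(float, v))))

    if norm != "euclidean":
        raise ValueError("norm must be 'euclidean' or 'one'")

    A_dense = A_eq.toarray() if sparse.issparse(A_eq) else np.asarray(A_eq)
    cons = [
        LinearConstraint(A_dense, b_eq, b_eq),
        LinearConstraint(c, zstar, zstar),
    ]
    if A_ub is not None:
        cons.append(LinearConstraint(A_ub.toarray(), -np.inf, b_ub))
    x0 = np.array([base.fluxes[rid] for rid in rids])
    res = minimize(
        lambda v: 0.5 * float(v @ v),
        x0,
        jac=lambda v: v,
        hess=lambda v: np.eye(n),
        bounds=Bounds(lb, ub),
        constraints=cons,
        method="trust-constr",
        options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000, "verbose": 0},
    )
    if not res.success and res.constr_violation > 1e-6:
        warnings.warn(
            f"euclidean minNorm QP did not converge ({res.message}); "
            "falling back to 1-norm LP"
        )
        return min_norm_solution(model, norm="one")
    v = res.x
    return FluxSolution(status="optimal", objective=float(c @ v),
                        fluxes=dict(zip(rids, map(float, v))))


# ---------------------------------------------------------------------------
# blocked reactions, dead ends, sanity checks
# ---------------------------------------------------------------------------

def find_blocked_reactions(
    model: MetabolicModel,
    reactions: list[str] | None = None,
    tol: float = BLOCKED_TOL,
) -> list[str]:
    """Reactions unable to carry flux above ``tol`` in any steady state.

    Runs FVA with no objective floor (gamma = 0) and flags reactions whose
    whole range lies within ``[-tol, tol]``.
    """
    res = fva(model, gamma=0.0, reactions=reactions)
    blocked = [
        rid for rid, (vmin, vmax) in res.ranges.items()
        if abs(vmin) < tol and abs(vmax) < tol
    ]
    blocked += list(res.failures)
    return sorted(blocked)


def find_dead_end_metabolites(model: MetabolicModel) -> list[str]:
    """Metabolites that are only produced or only consumed.

    Purely topological: a reversible reaction (lb < 0) counts as both a
    producer and a consumer of everything it touches.  Boundary reactions
    count like any other (a metabolite with an exchange is never a dead
    end unless the exchange is its only link and is irreversible inward).
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    touched: set[str] = set()
    for r in model.reactions:
        fwd = r.ub > 0
        rev = r.lb < 0
        for mid, coef in r.stoichiometry.items():
            touched.add(mid)
            is_product = coef > 0
            if (is_product and fwd) or (not is_product and rev):
                produced.add(mid)
            if (not is_product and fwd) or (is_product and rev):
                consumed.add(mid)
    return sorted(
        mid for mid in touched
        if (mid in produced) != (mid in consumed)
    )


def run_sanity_checks(model: MetabolicModel, tol: float = BLOCKED_TOL) -> SanityReport:
    """COBRA-toolbox-style sanity checks.

    Leak test: with every boundary reaction closed to uptake (lb raised to
    0), each metabolite gets a temporary demand that is maximized; producible
    flux above ``tol`` means mass is created from nothing.  Also reports
    blocked reactions (on the open model) and topological dead ends.
    """
    closed = model.copy()
    for r in closed.reactions:
        if r.kind in ("exchange", "sink", "demand"):
            r.lb = max(r.lb, 0.0)
    rep = SanityReport(notes=[f"tolerances: feasibility={FEASIBILITY_TOL}, blocked={tol}"])
    for met in closed.metabolites:
        probe = closed.copy()
        dm = Reaction(id="__leak_probe__", stoichiometry={met.id: -1.0},
                      lb=0.0, ub=1e4, kind="demand")
        probe.add_reaction(dm)
        probe.objective = {"__leak_probe__": 1.0}
        sol = fba(probe, sense="max")
        if sol.optimal and sol.objective > tol:
            rep.leaking_metabolites.append(met.id)
    rep.blocked_reactions = find_blocked_reactions(model, tol=tol)
    rep.dead_end_metabolites = find_dead_end_metabolites(model)
    return rep
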