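"""FBA, FVA and production-envelope computation.

The linear program is  max cᵀv  s.t.  S·v = 0, lb ≤ v ≤ ub, plus any
coupling constraints. The backend contract (equality/inequality rows,
variable bounds, optimal/infeasible/unbounded status) is implemented on
scipy's HiGHS interior-point/simplex driver; alternative backends can
subclass :class:`LPBackend`.

Degenerate alternate optima are the norm in FBA: ``solve_fba`` returns one
arbitrary optimal vertex, and all biological claims in this package are
asserted through FVA ranges, never through a particular vertex.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .model import (
    CouplingConstraint,
    MetabolicModel,
    Relation,
    build_stoichiometric_matrix,
)


class SolverStatus(str, enum.Enum):
    OPTIMAL = "OPTIMAL"
    INFEASIBLE = "INFEASIBLE"
    UNBOUNDED = "UNBOUNDED"


class LPError(RuntimeError):
    pass


@dataclass
class FluxSolution:
    status: SolverStatus
    objective_value: float = float("nan")
    fluxes: dict[str, float] = field(default_factory=dict)

    def flux(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FvaResult:
    fraction_of_optimum: float
    ranges: dict[str, tuple[float, float]]

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            [(rid, lo, hi) for rid, (lo, hi) in self.ranges.items()],
            columns=["reaction_id", "min", "max"],
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class Envelope:
    product_id: str
    points: list[tuple[float, float, float]]  # (growth, product_min, product_max)

    def to_tsv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.points, columns=["growth", "product_min", "product_max"])
        df.to_csv(path, sep="\t", index=False)


class LPBackend:
    """Minimal LP contract: minimize cᵀx s.t. A_eq x = b_eq, A_ub x ≤ b_ub,
    bounds. Subclass and override :meth:`solve` to swap solvers."""

    def __init__(self, tolerance: float = 1e-9):
        self.tolerance = tolerance

    def solve(self, c, A_eq, b_eq, A_ub, b_ub, bounds):
        options = {"primal_feasibility_tolerance": self.tolerance,
                   "dual_feasibility_tolerance": self.tolerance}
        res = linprog(
            c,
            A_eq=A_eq if A_eq is not None and len(A_eq) else None,
            b_eq=b_eq if b_eq is not None and len(b_eq) else None,
            A_ub=A_ub if A_ub is not None and len(A_ub) else None,
            b_ub=b_ub if b_ub is not None and len(b_ub) else None,
            bounds=bounds,
            method="highs",
            options=options,
        )
        if res.status == 0:
            return SolverStatus.OPTIMAL, res.fun, res.x
        if res.status == 2:
            return SolverStatus.INFEASIBLE, float("nan"), None
        if res.status == 3:
            return SolverStatus.UNBOUNDED, float("nan"), None
        raise LPError(f"LP backend failure: {res.message}")


@dataclass
class _Program:
    """Matrices of a model's LP, built once and reused across FVA subproblems."""

    rxn_ids: list[str]
    A_eq: np.ndarray
    b_eq: np.ndarray
    A_ub: Optional[np.ndarray]
    b_ub: Optional[np.ndarray]
    bounds: list[tuple[float, float]]
    index: dict[str, int]


def _build_program(model: MetabolicModel) -> _Program:
    S = build_stoichiometric_matrix(model)
    rxn_ids = [r.id for r in model.reactions]
    index = {rid: j for j, rid in enumerate(rxn_ids)}
    n = len(rxn_ids)

    eq_rows = [S]
    eq_rhs = list(np.zeros(S.shape[0]))
    ub_rows: list[np.ndarray] = []
    ub_rhs: list[float] = []
    for c in model.couplings:
        row = np.zeros(n)
        for rid, coeff in c.terms.items():
            row[index[rid]] += coeff
        if c.relation is Relation.EQ:
            eq_rows.append(row[None, :])
            eq_rhs.append(c.rhs)
        elif c.relation is Relation.LE:
            ub_rows.append(row)
            ub_rhs.append(c.rhs)
        else:  # GE → negate
            ub_rows.append(-row)
            ub_rhs.append(-c.rhs)

    A_eq = np.vstack(eq_rows)
    b_eq = np.array(eq_rhs)
    A_ub = np.vstack(ub_rows) if ub_rows else None
    b_ub = np.array(ub_rhs) if ub_rhs else None
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return _Program(rxn_ids, A_eq, b_eq, A_ub, b_ub, bounds, index)


def _objective_vector(model: MetabolicModel, prog: _Program) -> np.ndarray:
    if not model.objective:
        raise LPError("model objective is empty")
    c = np.zeros(len(prog.rxn_ids))
    for rid, w in model.objective.items():
        c[prog.index[rid]] = w
    return c


def solve_fba(model: MetabolicModel, backend: Optional[LPBackend] = None) -> FluxSolution:
    """Maximize the model objective; returns status and, when optimal, the
    objective value and one flux vector. UNBOUNDED is reported distinctly
    (usually a missing exchange cap or an unremoved internal cycle)."""
    backend = backend or LPBackend()
    prog = _build_program(model)
    c = _objective_vector(model, prog)
    status, fun, x = backend.solve(-c, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
    if status is not SolverStatus.OPTIMAL:
        return FluxSolution(status=status)
    return FluxSolution(
        status=SolverStatus.OPTIMAL,
        objective_value=-fun,
        fluxes=dict(zip(prog.rxn_ids, (float(v) for v in x))),
    )


def _with_objective_floor(prog: _Program, c: np.ndarray, floor: float) -> _Program:
    """Add the FVA constraint  cᵀv ≥ floor  (as −cᵀv ≤ −floor)."""
    row = -c[None, :]
    A_ub = row if prog.A_ub is None else np.vstack([prog.A_ub, row])
    b_ub = np.array([-floor]) if prog.b_ub is None else np.append(prog.b_ub, -floor)
    return _Program(prog.rxn_ids, prog.A_eq, prog.b_eq, A_ub, b_ub, prog.bounds, prog.index)


def solve_fva(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    reaction_ids: Optional[Sequence[str]] = None,
    backend: Optional[LPBackend] = None,
) -> FvaResult:
    """Min/max flux of each requested reaction subject to the objective
    being at least ``fraction_of_optimum`` of its FBA optimum.

    The objective floor is an inequality, not an equality: standard FVA,
    and numerically far better behaved.
    """
    if not (0 < fraction_of_optimum <= 1):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    backend = backend or LPBackend()
    base = solve_fba(model, backend)
    if base.status is not SolverStatus.OPTIMAL:
        raise LPError(
            f"FVA requires an optimal base solution, got {base.status.value}; "
            "check scenario constraints"
        )
    prog = _build_program(model)
    c = _objective_vector(model, prog)
    floor = fraction_of_optimum * base.objective_value
    prog = _with_objective_floor(prog, c, floor)

    ids = list(reaction_ids) if reaction_ids is not None else list(prog.rxn_ids)
    ranges: dict[str, tuple[float, float]] = {}
    n = len(prog.rxn_ids)
    for rid in ids:
        j = prog.index[rid]
        e = np.zeros(n)
        e[j] = 1.0
        lo_status, lo, _ = backend.solve(e, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
        hi_status, hi, _ = backend.solve(-e, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
        if lo_status is not SolverStatus.OPTIMAL or hi_status is not SolverStatus.OPTIMAL:
            raise LPError(f"FVA subproblem for {rid!r} returned {lo_status}/{hi_status}")
        lo, hi = float(lo), float(-hi)
        if lo > hi:  # numerical jitter on a pinned flux
            lo = hi = 0.5 * (lo + hi)
        ranges[rid] = (lo, hi)
    return FvaResult(fraction_of_optimum=fraction_of_optimum, ranges=ranges)


def compute_envelope(
    model: MetabolicModel,
    product_id: str,
    n_points: int = 20,
    backend: Optional[LPBackend] = None,
) -> Envelope:
    """Product solution space: min/max feasible product flux on an even grid
    of growth levels from 0 to μ_max (the wedge plots of production envelopes)."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    backend = backend or LPBackend()
    base = solve_fba(model, backend)
    if base.status is not SolverStatus.OPTIMAL:
        raise LPError(f"envelope base FBA is {base.status.value}")
    mu_max = base.objective_value
    prog0 = _build_program(model)
    c = _objective_vector(model, prog0)
    j = prog0.index[product_id]
    n = len(prog0.rxn_ids)
    e = np.zeros(n)
    e[j] = 1.0

    points: list[tuple[float, float, float]] = []
    for g in np.linspace(0.0, mu_max, n_points):
        prog = _with_objective_floor(prog0, c, float(g))
        lo_status, lo, _ = backend.solve(e, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
        hi_status, hi, _ = backend.solve(-e, prog.A_eq, prog.b_eq, prog.A_ub, prog.b_ub, prog.bounds)
        if lo_status is not SolverStatus.OPTIMAL or hi_status is not SolverStatus.OPTIMAL:
            raise LPError(f"envelope subproblem at growth {g} returned {lo_status}/{hi_status}")
        points.append((float(g), float(lo), float(-hi)))
    return Envelope(product_id=product_id, points=points)


def is_growth_coupled(
    model: MetabolicModel,
    product_id: str,
    tolerance: float = 1e-6,
    backend: Optional[LPBackend] = None,
) -> bool:
    """True iff every maximum-growth solution carries product flux: the FVA
    minimum of the product at fraction 1.0 exceeds ``tolerance``."""
    fva = solve_fva(model, 1.0, [product_id], backend=backend)
    return fva.ranges[product_id][0] > tolerance


def check_solution(
    model: MetabolicModel, solution: FluxSolution, tolerance: float = 1e-6
) -> float:
    """Max violation of S·v = 0, bounds and couplings for a flux vector
    (used by tests to audit feasibility)."""
    S = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    worst = float(np.max(np.abs(S @ v))) if len(v) else 0.0
    for r, flux in zip(model.reactions, v):
        worst = max(worst, r.lower_bound - flux, flux - r.upper_bound)
    for c in model.couplings:
        val = sum(coeff * solution.fluxes[rid] for rid, coeff in c.terms.items())
        if c.relation is Relation.EQ:
            worst = max(worst, abs(val - c.rhs))
        elif c.relation is Relation.LE:
            worst = max(worst, val - c.rhs)
        else:
            worst = max(worst, c.rhs - val)
    return worst
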