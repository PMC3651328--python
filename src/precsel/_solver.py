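"""Thin mixed-integer linear programming layer.

All selection models (feature ILP, protein-based LP, iterative IPS_LP) are
assembled through :class:`MilpBuilder` and solved with HiGHS via
``scipy.optimize.milp``.  Keeping the build -> solve -> extract cycle behind
this small surface keeps the formulations readable and the backend
swappable.

Maximization is expressed by negating the objective; HiGHS proves
optimality (zero MIP gap within integer tolerance) for every model built
here, so a returned solution is a global optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

__all__ = ["MilpBuilder", "MilpSolution", "SolverError"]


class SolverError(RuntimeError):
    """The backend failed to return a proven-optimal solution."""


@dataclass
class MilpSolution:
    values: np.ndarray
    objective: float

    def value(self, index: int) -> float:
        return float(self.values[index])


class MilpBuilder:
    """Incrementally assemble a (mixed-integer) linear program.

    Variables are added one at a time and identified by integer index;
    constraints are sparse rows over those indices.  The objective sense is
    maximization.
    """

    def __init__(self) -> None:
        self._obj: list[float] = []
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integrality: list[int] = []
        self._rows: list[dict[int, float]] = []
        self._row_lb: list[float] = []
        self._row_ub: list[float] = []

    # -- variables ---------------------------------------------------------
    def add_binary(self, objective: float = 0.0) -> int:
        return self._add_var(objective, 0.0, 1.0, 1)

    def add_continuous(
        self, objective: float = 0.0, lb: float = 0.0, ub: float = np.inf
    ) -> int:
        return self._add_var(objective, lb, ub, 0)

    def _add_var(self, obj: float, lb: float, ub: float, integrality: int) -> int:
        self._obj.append(obj)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integrality.append(integrality)
        return len(self._obj) - 1

    def fix(self, index: int, value: float) -> None:
        """Pin a variable to a value (equality bounds)."""
        self._lb[index] = value
        self._ub[index] = value

    def set_objective(self, index: int, coefficient: float) -> None:
        self._obj[index] = coefficient

    def add_to_objective(self, index: int, coefficient: float) -> None:
        self._obj[index] += coefficient

    @property
    def n_variables(self) -> int:
        return len(self._obj)

    @property
    def objective(self) -> list[float]:
        """Copy of the current objective coefficient vector."""
        return list(self._obj)

    # -- constraints -------------------------------------------------------
    def add_constraint(
        self,
        coefficients: dict[int, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> None:
        if not coefficients:
            return
        self._rows.append(dict(coefficients))
        self._row_lb.append(lb)
        self._row_ub.append(ub)

    def add_le(self, coefficients: dict[int, float], rhs: float) -> None:
        self.add_constraint(coefficients, ub=rhs)

    def add_eq(self, coefficients: dict[int, float], rhs: float) -> None:
        self.add_constraint(coefficients, lb=rhs, ub=rhs)

    # -- solve -------------------------------------------------------------
    def solve(self) -> MilpSolution:
        n = self.n_variables
        if n == 0:
            return MilpSolution(values=np.zeros(0), objective=0.0)
        c = -np.asarray(self._obj, dtype=float)  # milp minimizes
        constraints = []
        if self._rows:
            data, ri, ci = [], [], []
            for r, row in enumerate(self._rows):
                for col, v in row.items():
                    ri.append(r)
                    ci.append(col)
                    data.append(v)
            a = sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), n))
            constraints.append(
                LinearConstraint(a, np.asarray(self._row_lb), np.asarray(self._row_ub))
            )
        from scipy.optimize import Bounds

        res = milp(
            c,
            constraints=constraints,
            integrality=np.asarray(self._integrality),
            bounds=Bounds(np.asarray(self._lb), np.asarray(self._ub)),
            options={"mip_rel_gap": 0.0},
        )
        if not res.success or res.x is None:
            raise SolverError(f"MILP solve failed: {res.message}")
        values = np.asarray(res.x, dtype=float)
        # snap integer variables to exact integers
        mask = np.asarray(self._integrality, dtype=bool)
        values[mask] = np.round(values[mask])
        return MilpSolution(values=values, objective=float(-res.fun))
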