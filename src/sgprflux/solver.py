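"""Thin deterministic LP/MILP layer over scipy's HiGHS interface.

All constraint-based computations in the package (FBA, FVA, pFBA, the
integration MILPs) are assembled through :class:`ProblemBuilder`, which
keeps named variables and row-wise constraints and hands a sparse
formulation to :func:`scipy.optimize.milp`.  HiGHS is deterministic for a
fixed formulation, which underpins the package's reproducibility contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["ProblemBuilder", "Solution", "InfeasibleProblemError"]


class InfeasibleProblemError(RuntimeError):
    """The LP/MILP has no feasible point (or is unbounded)."""


@dataclass
class Solution:
    objective: float
    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class _Var:
    name: str
    lb: float
    ub: float
    integer: bool
    obj: float


@dataclass
class ProblemBuilder:
    """Incremental builder for sparse LPs/MILPs with named variables."""

    sense: str = "min"  # "min" or "max"
    _vars: dict[str, _Var] = field(default_factory=dict)
    _rows: list[tuple[dict[str, float], float, float]] = field(default_factory=list)

    def add_var(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = np.inf,
        *,
        integer: bool = False,
        obj: float = 0.0,
    ) -> str:
        if name in self._vars:
            raise ValueError(f"duplicate variable {name!r}")
        self._vars[name] = _Var(name, float(lb), float(ub), integer, float(obj))
        return name

    def set_objective(self, name: str, coef: float) -> None:
        self._vars[name].obj = float(coef)

    def add_constraint(
        self, coefs: dict[str, float], lb: float = -np.inf, ub: float = np.inf
    ) -> None:
        """Add lb <= sum(coefs[v] * v) <= ub."""
        if not coefs:
            raise ValueError("empty constraint")
        self._rows.append((dict(coefs), float(lb), float(ub)))

    def solve(self) -> Solution:
        names = list(self._vars)
        index = {n: j for j, n in enumerate(names)}
        n = len(names)
        c = np.array([self._vars[v].obj for v in names])
        sign = -1.0 if self.sense == "max" else 1.0
        lb = np.array([self._vars[v].lb for v in names])
        ub = np.array([self._vars[v].ub for v in names])
        integrality = np.array(
            [1 if self._vars[v].integer else 0 for v in names], dtype=np.uint8
        )

        constraints = []
        if self._rows:
            data, rows, cols, clo, cup = [], [], [], [], []
            for i, (coefs, rlo, rup) in enumerate(self._rows):
                for name, coef in coefs.items():
                    rows.append(i)
                    cols.append(index[name])
                    data.append(coef)
                clo.append(rlo)
                cup.append(rup)
            A = sparse.csr_matrix((data, (rows, cols)), shape=(len(self._rows), n))
            constraints.append(LinearConstraint(A, np.array(clo), np.array(cup)))

        res = milp(
            c=sign * c,
            constraints=constraints,
            integrality=integrality,
            bounds=Bounds(lb, ub),
        )
        if res.status != 0 or res.x is None:
            raise InfeasibleProblemError(
                f"solver status {res.status}: {res.message}"
            )
        values = {name: float(res.x[j]) for name, j in index.items()}
        return Solution(objective=float(sign * res.fun), values=values)
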