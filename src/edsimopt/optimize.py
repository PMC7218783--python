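"""Budget-constrained integer optimization of the fitted wait-time surface.

The decision problem: choose integer resource levels X within per-factor
bounds L_i <= X_i <= U_i and a linear budget sum_i C_i X_i <= B so that
the metamodel's predicted mean wait is minimal.  The lattice is small
(648 points at the study bounds), so the solver is exhaustive
enumeration — exact and trivially auditable.  Predictions are made in
coded units via the factorial coding transform.

A multilinear objective is affine in each coordinate, so without a
budget constraint its minimum over a box always sits at a vertex; the
enumeration of course also covers budget-truncated lattices where this
need not hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .design import FactorSpec, code
from .metamodel import ResponseSurfaceRegressor
from .models import ResourceConfig

__all__ = [
    "OptimizationProblem",
    "OptimizationResult",
    "total_cost",
    "enumerate_feasible",
    "optimize",
]

#: Tie tolerance on predicted values (coded-response scale).
_TIE_ATOL = 1e-9


def total_cost(config: ResourceConfig | Sequence[int], unit_costs: Sequence[float]) -> float:
    """Linear resource cost ``sum_i C_i X_i``."""
    levels = config.as_tuple() if isinstance(config, ResourceConfig) else tuple(config)
    if len(levels) != len(unit_costs):
        raise ValueError(
            f"{len(levels)} resource levels but {len(unit_costs)} unit costs"
        )
    if any(c < 0 for c in unit_costs):
        raise ValueError("unit costs must be non-negative")
    return float(sum(c * x for c, x in zip(unit_costs, levels)))


@dataclass(frozen=True)
class OptimizationProblem:
    factors: tuple[FactorSpec, ...]
    unit_costs: tuple[float, ...]
    fit: ResponseSurfaceRegressor
    budget: float = np.inf

    def __post_init__(self) -> None:
        if len(self.unit_costs) != len(self.factors):
            raise ValueError("one unit cost per factor required")
        if any(c < 0 for c in self.unit_costs):
            raise ValueError("unit costs must be non-negative")
        if not self.budget > 0:
            raise ValueError("budget must be positive (or infinite)")
        for f in self.factors:
            if not (float(f.low).is_integer() and float(f.high).is_integer()):
                raise ValueError(f"factor {f.name!r}: bounds must be integers")
        object.__setattr__(self, "unit_costs", tuple(float(c) for c in self.unit_costs))


@dataclass
class OptimizationResult:
    argmin: ResourceConfig
    predicted_wait: float
    total_cost: float
    n_feasible: int
    ties: list[ResourceConfig] = field(default_factory=list)


def enumerate_feasible(problem: OptimizationProblem) -> list[ResourceConfig]:
    """All in-bounds integer lattice points within budget, lexicographic."""
    ranges = [range(int(f.low), int(f.high) + 1) for f in problem.factors]
    feasible = [
        ResourceConfig.from_tuple(levels)
        for levels in product(*ranges)
        if total_cost(levels, problem.unit_costs) <= problem.budget
    ]
    if not feasible:
        raise ValueError(
            "no feasible configuration: budget "
            f"{problem.budget} is below the cheapest corner "
            f"{total_cost([f.low for f in problem.factors], problem.unit_costs)}"
        )
    return feasible


def optimize(problem: OptimizationProblem) -> OptimizationResult:
    """Exhaustively minimize the predicted wait over the feasible lattice.

    Ties on predicted value break by lower total cost, then lexicographic
    order of the natural levels.
    """
    feasible = enumerate_feasible(problem)
    coded = np.array(
        [
            [code(x, f) for x, f in zip(cfg.as_tuple(), problem.factors)]
            for cfg in feasible
        ]
    )
    predicted = problem.fit.predict(coded)
    best = min(
        range(len(feasible)),
        key=lambda i: (
            predicted[i],
            total_cost(feasible[i], problem.unit_costs),
            feasible[i].as_tuple(),
        ),
    )
    tie_idx = [
        i
        for i in range(len(feasible))
        if abs(predicted[i] - predicted[best]) <= _TIE_ATOL
    ]
    return OptimizationResult(
        argmin=feasible[best],
        predicted_wait=float(predicted[best]),
        total_cost=total_cost(feasible[best], problem.unit_costs),
        n_feasible=len(feasible),
        ties=[feasible[i] for i in tie_idx],
    )
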