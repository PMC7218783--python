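"""Two-level full-factorial experiments on the simulator.

A 2^k design evaluates every combination of k factors at coded levels
-1 (the factor's low natural level L) and +1 (its high level U); the
linear coding is ``x = (X - (L+U)/2) / ((U-L)/2)``.  Columns of a full
factorial are balanced (sum to zero) and mutually orthogonal, which is
what lets main effects and interactions be estimated as simple contrast
averages downstream.

``run_experiments`` decodes each design row to a resource configuration
and simulates it a configurable number of times; per-cell seeds are a
pure function of (master seed, row, replicate), so a table is exactly
reproducible.  An optional common-random-numbers mode reuses the same
patient stream across rows within a replicate, sharpening between-row
comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .models import FACTOR_NAMES, ResourceConfig, ServiceModel, WorkloadModel
from .simulator import simulate_day

__all__ = [
    "FactorSpec",
    "DesignMatrix",
    "ExperimentTable",
    "full_factorial",
    "code",
    "decode",
    "cell_seed",
    "run_experiments",
    "default_factors",
]


@dataclass(frozen=True)
class FactorSpec:
    """A factor with its low/high natural levels (L < U)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"factor {self.name!r}: low must be strictly below high "
                f"(got L={self.low}, U={self.high})"
            )


def default_factors() -> list[FactorSpec]:
    """The five ED resource factors with their study bounds."""
    bounds = {"chw": (1, 2), "receptionists": (1, 3), "nurses": (1, 6),
              "cardiologists": (1, 3), "beds": (5, 10)}
    return [FactorSpec(n, *bounds[n]) for n in FACTOR_NAMES]


def code(value: float, factor: FactorSpec) -> float:
    """Natural units -> coded units: L maps to -1, U to +1."""
    center = 0.5 * (factor.low + factor.high)
    half = 0.5 * (factor.high - factor.low)
    return (value - center) / half


def decode(coded: float, factor: FactorSpec) -> float:
    """Coded units -> natural units (inverse of :func:`code`)."""
    center = 0.5 * (factor.low + factor.high)
    half = 0.5 * (factor.high - factor.low)
    return center + coded * half


@dataclass(frozen=True)
class DesignMatrix:
    """Coded +/-1 full-factorial plan over an ordered factor list."""

    factors: tuple[FactorSpec, ...]
    rows: np.ndarray  # shape (2^k, k), entries in {-1, +1}

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        k = len(self.factors)
        if rows.shape != (2 ** k, k):
            raise ValueError(f"expected {2 ** k} x {k} design, got {rows.shape}")
        if not np.all(np.isin(rows, (-1.0, 1.0))):
            raise ValueError("design entries must be -1 or +1")
        if len({tuple(r) for r in rows}) != rows.shape[0]:
            raise ValueError("design rows must be distinct")
        object.__setattr__(self, "rows", rows)

    @property
    def n_runs(self) -> int:
        return self.rows.shape[0]

    def natural(self) -> np.ndarray:
        """Decode every row to natural factor levels."""
        return np.array(
            [[decode(x, f) for x, f in zip(row, self.factors)] for row in self.rows]
        )

    def to_frame(self) -> pd.DataFrame:
        coded_cols = {f"X{i+1}_coded": self.rows[:, i] for i in range(len(self.factors))}
        nat = self.natural()
        nat_cols = {f.name: nat[:, i] for i, f in enumerate(self.factors)}
        return pd.DataFrame({**coded_cols, **nat_cols})


def full_factorial(k: int, factors: list[FactorSpec] | None = None) -> DesignMatrix:
    """2^k design in standard (Yates) order: factor 1 alternates fastest."""
    if k < 1 or k > 16:
        raise ValueError(f"factor count must be in 1..16, got {k}")
    if factors is None:
        factors = [FactorSpec(f"X{i+1}", -1.0, 1.0) for i in range(k)]
    if len(factors) != k:
        raise ValueError("factor list length must equal k")
    rows = np.empty((2 ** k, k))
    for j in range(k):
        block = np.repeat([-1.0, 1.0], 2 ** j)
        rows[:, j] = np.tile(block, 2 ** (k - j - 1))
    return DesignMatrix(factors=tuple(factors), rows=rows)


def cell_seed(master_seed: int, row: int, replicate: int) -> int:
    """Deterministic per-cell seed — a pure function of its arguments."""
    ss = np.random.SeedSequence([int(master_seed), int(row), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class ExperimentTable:
    """A design joined with replicate responses (mean wait, minutes)."""

    design: DesignMatrix
    responses: list[list[float]]  # per row, one value per replicate
    replications: int
    seeds: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.responses) != self.design.n_runs:
            raise ValueError("one response list per design row required")
        for r, values in enumerate(self.responses):
            if len(values) != self.replications:
                raise ValueError(f"row {r}: expected {self.replications} replicates")
            if any(v < 0 for v in values):
                raise ValueError(f"row {r}: responses must be >= 0")

    def cell_means(self) -> np.ndarray:
        return np.array([float(np.mean(v)) for v in self.responses])

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (design row, replicate)."""
        recs = []
        nat = self.design.natural()
        for r in range(self.design.n_runs):
            for j in range(self.replications):
                rec = {
                    **{f"X{i+1}_coded": self.design.rows[r, i]
                       for i in range(len(self.design.factors))},
                    **{f.name: nat[r, i]
                       for i, f in enumerate(self.design.factors)},
                    "row": r,
                    "rep": j,
                    "seed": self.seeds[r][j] if self.seeds else -1,
                    "response": self.responses[r][j],
                }
                recs.append(rec)
        return pd.DataFrame(recs)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, factors: list[FactorSpec]) -> "ExperimentTable":
        k = len(factors)
        reps = int(df["rep"].max()) + 1
        n_rows = int(df["row"].max()) + 1
        rows = np.empty((n_rows, k))
        responses: list[list[float]] = [[0.0] * reps for _ in range(n_rows)]
        seeds: list[list[int]] = [[0] * reps for _ in range(n_rows)]
        for _, rec in df.iterrows():
            r, j = int(rec["row"]), int(rec["rep"])
            rows[r] = [rec[f"X{i+1}_coded"] for i in range(k)]
            responses[r][j] = float(rec["response"])
            seeds[r][j] = int(rec["seed"])
        design = DesignMatrix(factors=tuple(factors), rows=rows)
        return cls(design=design, responses=responses, replications=reps, seeds=seeds)


def run_experiments(
    design: DesignMatrix,
    workload: WorkloadModel,
    service: ServiceModel,
    replications: int = 10,
    master_seed: int = 0,
    *,
    common_random_numbers: bool = False,
    simulator: Callable[..., object] | None = None,
) -> ExperimentTable:
    """Simulate every design point ``replications`` times.

    Each row is decoded to a :class:`ResourceConfig`.  With
    ``common_random_numbers`` the seed depends only on the replicate, so
    all rows within a replicate see the same patient stream.
    ``simulator`` may substitute :func:`edsimopt.simulator.simulate_day`
    (same signature, returning an object with a ``mean_wait``) for
    testing.
    """
    if replications < 1:
        raise ValueError("replications must be >= 1")
    sim = simulator or simulate_day
    responses: list[list[float]] = []
    seeds: list[list[int]] = []
    for r, row in enumerate(design.rows):
        natural = [decode(x, f) for x, f in zip(row, design.factors)]
        config = ResourceConfig.from_tuple([int(round(v)) for v in natural])
        row_resp: list[float] = []
        row_seeds: list[int] = []
        for j in range(replications):
            seed = cell_seed(master_seed, 0 if common_random_numbers else r, j)
            try:
                result = sim(config, workload, service, seed, keep_records=False)
            except Exception as exc:
                raise RuntimeError(f"simulation failed at design row {r}: {exc}") from exc
            row_resp.append(float(result.mean_wait))
            row_seeds.append(seed)
        responses.append(row_resp)
        seeds.append(row_seeds)
    return ExperimentTable(
        design=design, responses=responses, replications=replications, seeds=seeds
    )
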