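"""Domain types for the ED patient-flow simulation.

The decision vector is the five ED resource pools, in fixed factor order
X1..X5: community health workers, receptionists, nurses, cardiologists,
beds.  A workload describes one working day of arrivals (homogeneous
Poisson), the triage mix over Emergency Severity Index (ESI) levels 1-5,
and the fraction of cardiac presentations.  Service times are attached to
named clinical activities; families are configurable because real
per-activity distributions differ between departments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

#: Factor order X1..X5.  Everything downstream (design matrices, coded
#: coefficients, optimization bounds) indexes resources in this order.
FACTOR_NAMES: tuple[str, ...] = (
    "chw",
    "receptionists",
    "nurses",
    "cardiologists",
    "beds",
)

#: Activities that the standard ESI routing references.
STANDARD_ACTIVITIES: tuple[str, ...] = (
    "registration",
    "nurse_assessment",
    "cpr",
    "ecg",
    "gp_visit",
    "cpu_stay",
    "icu_handoff",
)

DISPOSITIONS: tuple[str, ...] = (
    "admitted_cpu",
    "admitted_icu",
    "discharged",
    "died_cpr",
    "in_system_at_close",
)


@dataclass(frozen=True)
class ResourceConfig:
    """Integer staffing/bed levels — the decision vector (X1..X5)."""

    chw: int
    receptionists: int
    nurses: int
    cardiologists: int
    beds: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not float(v).is_integer() or int(v) < 1:
                raise ValueError(
                    f"resource '{f.name}' must be an integer >= 1, got {v!r}"
                )
            object.__setattr__(self, f.name, int(v))

    def as_tuple(self) -> tuple[int, ...]:
        return tuple(getattr(self, n) for n in FACTOR_NAMES)

    @classmethod
    def from_tuple(cls, values) -> "ResourceConfig":
        if len(values) != len(FACTOR_NAMES):
            raise ValueError(f"expected {len(FACTOR_NAMES)} levels, got {len(values)}")
        return cls(*values)

    def capacity(self, pool: str) -> int:
        if pool not in FACTOR_NAMES:
            raise ValueError(f"unknown resource pool {pool!r}")
        return getattr(self, pool)


@dataclass(frozen=True)
class WorkloadModel:
    """One working day of demand.

    ``arrival_rate`` is the expected number of arrivals over the working
    day (patients/day); arrivals follow a homogeneous Poisson process over
    ``day_length`` minutes, so the per-minute rate is
    ``arrival_rate / day_length``.
    """

    arrival_rate: float = 145.0
    esi_mix: tuple[float, ...] = (0.05, 0.15, 0.30, 0.30, 0.20)
    cardiac_fraction: float = 0.40
    day_length: float = 1440.0

    def __post_init__(self) -> None:
        if self.arrival_rate < 0:
            raise ValueError("arrival_rate must be >= 0")
        if self.day_length <= 0:
            raise ValueError("day_length must be > 0 minutes")
        mix = np.asarray(self.esi_mix, dtype=float)
        if mix.shape != (5,):
            raise ValueError("esi_mix must have 5 entries (ESI levels 1..5)")
        if np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("esi_mix must be a probability vector summing to 1")
        if not 0.0 <= self.cardiac_fraction <= 1.0:
            raise ValueError("cardiac_fraction must be in [0, 1]")
        object.__setattr__(self, "esi_mix", tuple(float(p) for p in mix))


@dataclass(frozen=True)
class DistSpec:
    """Service-time distribution for one activity (minutes).

    Families: ``exponential`` (mean), ``uniform`` (low, high),
    ``deterministic`` (value).
    """

    family: str
    params: tuple[float, ...]

    _FAMILIES = ("exponential", "uniform", "deterministic")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"choose one of {self._FAMILIES}"
            )
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.mean() <= 0:
            raise ValueError(f"distribution mean must be > 0, got {self.mean()}")

    def mean(self) -> float:
        if self.family == "exponential":
            return self.params[0]
        if self.family == "uniform":
            return 0.5 * (self.params[0] + self.params[1])
        return self.params[0]

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "exponential":
            return float(rng.exponential(self.params[0]))
        if self.family == "uniform":
            return float(rng.uniform(self.params[0], self.params[1]))
        return float(self.params[0])


def _default_distributions() -> dict[str, DistSpec]:
    # Means (minutes) chosen so the current staffing (1,2,3,1,7) runs
    # congested at 145 patients/day: registration demand is ~0.096/min,
    # so a 13-min mean overloads the single community health worker
    # (utilisation ~1.24), and 90-min chest-pain-unit stays overload the
    # single cardiologist held for each ESI-2 admission (~1.4).
    means = {
        "registration": 13.0,
        "nurse_assessment": 10.0,
        "ecg": 6.0,
        "cpr": 15.0,
        "gp_visit": 12.0,
        "cpu_stay": 90.0,
        "icu_handoff": 14.0,
    }
    return {name: DistSpec("exponential", (m,)) for name, m in means.items()}


@dataclass(frozen=True)
class ServiceModel:
    """Per-activity service-time distributions plus the CPR success rate."""

    distributions: dict[str, DistSpec] = field(default_factory=_default_distributions)
    cpr_success_prob: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpr_success_prob <= 1.0:
            raise ValueError("cpr_success_prob must be in [0, 1]")
        for name, spec in self.distributions.items():
            if not isinstance(spec, DistSpec):
                raise TypeError(f"distribution for {name!r} must be a DistSpec")

    def require(self, activity: str) -> DistSpec:
        try:
            return self.distributions[activity]
        except KeyError:
            raise ValueError(
                f"no service-time distribution configured for activity {activity!r}"
            ) from None


@dataclass
class StageRecord:
    """Timestamps for one stage of a patient's journey (minutes from open)."""

    name: str
    queue_enter: float
    service_start: float | None = None
    service_end: float | None = None


@dataclass
class PatientRecord:
    patient_id: int
    esi_level: int
    cardiac: bool
    arrival_time: float
    stages: list[StageRecord] = field(default_factory=list)
    disposition: str | None = None

    @property
    def total_wait(self) -> float:
        """Sum of per-stage queueing delays; service time excluded."""
        return sum(
            s.service_start - s.queue_enter
            for s in self.stages
            if s.service_start is not None
        )


@dataclass
class SimulationResult:
    """Aggregate outcome of one simulated working day.

    ``mean_wait`` averages total queueing delay over patients whose
    journey completed within the day; patients still in the system at
    close are excluded from the mean but counted in ``dispositions``.
    """

    mean_wait: float
    per_esi_mean_wait: dict[int, float]
    n_arrived: int
    n_completed: int
    dispositions: dict[str, int]
    utilization: dict[str, float]
    seed: int
    config: ResourceConfig
    empty: bool
    records: list[PatientRecord] = field(default_factory=list, repr=False)
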