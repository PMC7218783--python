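"""Terminating discrete-event simulation of one working day of ED flow.

Patients arrive by a homogeneous Poisson process, are triaged to an
Emergency Severity Index (ESI) level, and follow a fixed level-specific
routing through stages that seize one or more resource pools:

* ESI 1 — straight to resuscitation (cardiologist + bed; service is the
  ECG plus CPR time); on success the patient moves to the chest-pain unit
  (bed), on failure the journey ends (``died_cpr``).
* ESI 2 — nurse assessment (nurse), then registration (receptionist +
  community health worker), then the chest-pain unit (bed + cardiologist).
* ESI 3-4 — registration, then ICU handoff (bed + nurse).
* ESI 5 — registration, then a general-practitioner visit (no pooled
  resource) and discharge.

Queue discipline is non-preemptive priority: lower ESI number first, FIFO
within a level (ties broken by arrival time, then patient id).  A stage
starts only when every pool it needs has a free unit; when the
highest-priority request is blocked, a lower-priority request whose pools
are all free may start (greedy allocation in priority order).  Beds are
held for the full chest-pain-unit / ICU-handoff stay; clinicians are
released at service end.

The run is a terminating simulation: it opens empty and arrivals stop at
the end of the working day.  By default (``close_out="flush"``) patients
already admitted are then served out, so the mean wait is the unbiased
average over the whole day's cohort.  The alternative
``close_out="censor"`` stops the clock at the day boundary and records
unfinished journeys as ``in_system_at_close``, excluding them from the
mean; that estimator is selection-biased under heavy load (adding
capacity lets long-waiters finish in time and *enter* the mean), which
is why flushing is the default.

Randomness uses one root seed: the arrival stream (times) has its own
substream, and every patient has a private substream driving triage,
cardiac status, service draws and the CPR outcome.  Because patient
substreams are keyed by patient index, two runs sharing a seed but
differing in resources see identical patients — the synchronisation that
common-random-number comparisons rely on.
"""

from __future__ import annotations

import heapq
from bisect import insort
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .models import (
    DISPOSITIONS,
    FACTOR_NAMES,
    PatientRecord,
    ResourceConfig,
    ServiceModel,
    SimulationResult,
    StageRecord,
    WorkloadModel,
)

__all__ = ["Stage", "route_for_esi", "sample_esi", "simulate_day"]


@dataclass(frozen=True)
class Stage:
    """One step of a routing path.

    ``pools`` are the resource pools seized simultaneously (one unit
    each) for the stage's duration; ``activities`` are the service-time
    draws summed to give that duration.
    """

    name: str
    pools: tuple[str, ...]
    activities: tuple[str, ...]

    def __post_init__(self) -> None:
        for p in self.pools:
            if p not in FACTOR_NAMES:
                raise ValueError(f"unknown resource pool {p!r} in stage {self.name!r}")


_ROUTES: dict[int, tuple[Stage, ...]] = {
    1: (
        Stage("cpr", ("cardiologists", "beds"), ("ecg", "cpr")),
        Stage("cpu_stay", ("beds",), ("cpu_stay",)),
    ),
    2: (
        Stage("nurse_assessment", ("nurses",), ("nurse_assessment",)),
        Stage("registration", ("receptionists", "chw"), ("registration",)),
        Stage("cpu_stay", ("beds", "cardiologists"), ("cpu_stay",)),
    ),
    3: (
        Stage("registration", ("receptionists", "chw"), ("registration",)),
        Stage("icu_handoff", ("beds", "nurses"), ("icu_handoff",)),
    ),
    4: (
        Stage("registration", ("receptionists", "chw"), ("registration",)),
        Stage("icu_handoff", ("beds", "nurses"), ("icu_handoff",)),
    ),
    5: (
        Stage("registration", ("receptionists", "chw"), ("registration",)),
        Stage("gp_visit", (), ("gp_visit",)),
    ),
}

_FINAL_DISPOSITION: dict[int, str] = {
    1: "admitted_cpu",
    2: "admitted_cpu",
    3: "admitted_icu",
    4: "admitted_icu",
    5: "discharged",
}


def route_for_esi(esi_level: int) -> list[Stage]:
    """Fixed routing path (ordered stages) for a triage level."""
    if esi_level not in _ROUTES:
        raise ValueError(f"ESI level must be in 1..5, got {esi_level!r}")
    return list(_ROUTES[esi_level])


def sample_esi(u: float, mix: Sequence[float]) -> int:
    """Inverse-CDF triage assignment: map a uniform draw to a level 1..5."""
    m = np.asarray(mix, dtype=float)
    if m.ndim != 1 or m.size < 1 or np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
        raise ValueError("mix must be a probability vector summing to 1")
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must be a uniform draw in [0, 1]")
    cdf = np.cumsum(m)
    level = int(np.searchsorted(cdf, u, side="right")) + 1
    return min(level, m.size)


class _Patient:
    __slots__ = ("record", "route", "stage_idx", "rng", "grant_start", "grant_pools")

    def __init__(self, record: PatientRecord, route: list[Stage], rng):
        self.record = record
        self.route = route
        self.stage_idx = 0
        self.rng = rng
        self.grant_start: float | None = None
        self.grant_pools: tuple[str, ...] = ()

    @property
    def priority(self) -> tuple:
        stage = self.record.stages[-1]
        return (self.record.esi_level, stage.queue_enter, self.record.patient_id)

    def __lt__(self, other: "_Patient") -> bool:
        return self.priority < other.priority


def _validate_routing(routing: dict[int, Sequence[Stage]], service: ServiceModel) -> None:
    for level, stages in routing.items():
        for st in stages:
            for act in st.activities:
                service.require(act)


def simulate_day(
    config: ResourceConfig,
    workload: WorkloadModel,
    service: ServiceModel,
    seed: int,
    *,
    routing: dict[int, Sequence[Stage]] | None = None,
    close_out: str = "flush",
    keep_records: bool = True,
) -> SimulationResult:
    """Simulate one working day and return aggregate statistics.

    ``routing`` overrides the standard ESI paths (used e.g. for reducing
    the model to a single-queue system when validating against queueing
    theory); by default the standard five-level routing applies.
    ``close_out`` is ``"flush"`` (serve out admitted patients after the
    day ends) or ``"censor"`` (stop the clock at the day boundary).
    Identical ``(config, workload, service, seed)`` give a bit-identical
    result.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    if close_out not in ("flush", "censor"):
        raise ValueError("close_out must be 'flush' or 'censor'")
    routes = {lvl: list(stages) for lvl, stages in (routing or _ROUTES).items()}
    _validate_routing(routes, service)
    T = workload.day_length
    rate_per_min = workload.arrival_rate / T

    arrival_ss = np.random.SeedSequence([int(seed), 0])
    arrival_rng = np.random.default_rng(arrival_ss)

    # Pre-generate the arrival stream so that it is a pure function of the
    # seed, independent of resource levels (common-random-numbers safe).
    arrival_times: list[float] = []
    if rate_per_min > 0:
        t = 0.0
        while True:
            t += arrival_rng.exponential(1.0 / rate_per_min)
            if t >= T:
                break
            arrival_times.append(t)

    patients: list[_Patient] = []
    for i, at in enumerate(arrival_times):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1, i]))
        esi = sample_esi(float(rng.random()), workload.esi_mix)
        cardiac = bool(rng.random() < workload.cardiac_fraction)
        rec = PatientRecord(patient_id=i, esi_level=esi, cardiac=cardiac, arrival_time=at)
        patients.append(_Patient(rec, routes[esi], rng))

    free = {pool: config.capacity(pool) for pool in FACTOR_NAMES}
    busy_minutes = {pool: 0.0 for pool in FACTOR_NAMES}
    pending: list[_Patient] = []  # kept sorted by priority
    events: list[tuple[float, int, str, _Patient]] = []
    seq = 0

    def push(time: float, kind: str, patient: _Patient) -> None:
        nonlocal seq
        heapq.heappush(events, (time, seq, kind, patient))
        seq += 1

    def enter_stage(p: _Patient, now: float) -> None:
        stage = p.route[p.stage_idx]
        p.record.stages.append(StageRecord(name=stage.name, queue_enter=now))
        if stage.pools:
            insort(pending, p)
        else:
            _start_service(p, now)

    def _start_service(p: _Patient, now: float) -> None:
        stage = p.route[p.stage_idx]
        rec = p.record.stages[-1]
        rec.service_start = now
        duration = sum(service.require(a).sample(p.rng) for a in stage.activities)
        rec.service_end = now + duration
        p.grant_start = now
        p.grant_pools = stage.pools
        for pool in stage.pools:
            free[pool] -= 1
        push(now + duration, "end", p)

    def try_allocate(now: float) -> None:
        # Greedy, in priority order: a blocked high-priority request does
        # not bar a lower-priority one whose pools are all free.
        granted: list[_Patient] = []
        for p in pending:
            stage = p.route[p.stage_idx]
            if all(free[pool] >= 1 for pool in stage.pools):
                granted.append(p)
                _start_service(p, now)
        for p in granted:
            pending.remove(p)

    def finish_patient(p: _Patient, disposition: str) -> None:
        p.record.disposition = disposition

    for p in patients:
        push(p.record.arrival_time, "arrival", p)

    horizon = T
    while events:
        time, _, kind, p = heapq.heappop(events)
        if close_out == "censor" and time > T:
            break
        horizon = max(horizon, time)
        if kind == "arrival":
            enter_stage(p, time)
        else:  # service end
            for pool in p.grant_pools:
                free[pool] += 1
                busy_minutes[pool] += time - p.grant_start
            p.grant_start = None
            p.grant_pools = ()
            stage = p.route[p.stage_idx]
            if stage.name == "cpr":
                if p.rng.random() >= service.cpr_success_prob:
                    finish_patient(p, "died_cpr")
                    try_allocate(time)
                    continue
            p.stage_idx += 1
            if p.stage_idx >= len(p.route):
                finish_patient(p, _FINAL_DISPOSITION.get(p.record.esi_level, "discharged"))
            else:
                enter_stage(p, time)
        try_allocate(time)

    # Censor close-out: journeys still running at the day boundary.
    for p in patients:
        if p.record.disposition is None:
            p.record.disposition = "in_system_at_close"
            if p.grant_start is not None:
                for pool in p.grant_pools:
                    busy_minutes[pool] += T - p.grant_start

    completed = [p.record for p in patients if p.record.disposition != "in_system_at_close"]
    waits = [r.total_wait for r in completed]
    mean_wait = float(np.mean(waits)) if waits else 0.0
    per_esi: dict[int, float] = {}
    for lvl in sorted(routes):
        lvl_waits = [r.total_wait for r in completed if r.esi_level == lvl]
        per_esi[lvl] = float(np.mean(lvl_waits)) if lvl_waits else 0.0

    dispositions = {d: 0 for d in DISPOSITIONS}
    for p in patients:
        dispositions[p.record.disposition] = dispositions.get(p.record.disposition, 0) + 1

    utilization = {
        pool: busy_minutes[pool] / (config.capacity(pool) * horizon)
        for pool in FACTOR_NAMES
    }

    return SimulationResult(
        mean_wait=mean_wait,
        per_esi_mean_wait=per_esi,
        n_arrived=len(patients),
        n_completed=len(completed),
        dispositions=dispositions,
        utilization=utilization,
        seed=int(seed),
        config=config,
        empty=not waits,
        records=[p.record for p in patients] if keep_records else [],
    )
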