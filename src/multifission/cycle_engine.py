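"""Deterministic event-driven simulation of multiple-fission cell cycles.

Chlorococcal and volvocean green algae divide by *multiple fission*: during
one cell cycle a mother cell completes ``n`` consecutive growth steps, each
roughly doubling biomass, and each completed step commits the cell
(commitment point, CP) to one *reproductive sequence* — DNA replication (S),
nuclear division (M) and protoplast fission (C) — so that the cycle ends
with the release of ``2**n`` daughter cells.  Light intensity sets the
growth rate and therefore how many steps fit into the light period; once a
sequence is committed it runs to completion even in the dark.

Species differ in how the ``n`` overlapping sequences interleave their S and
M rounds.  Four patterns are modelled:

* ``CONSECUTIVE_SCENEDESMUS`` — each sequence runs pS→S→G2→M independently,
  producing bi-, tetra-, ... multinuclear cells; all fissions at the end.
* ``CLUSTERED_CHLAMYDOMONAS`` — nothing happens until the last CP; then
  rapid S→M alternations, followed by the fissions.
* ``HAEMATOCOCCUS`` — all S rounds first (cell becomes polyploid with one
  nucleus), then all nuclear divisions (cell becomes polynuclear), then all
  fissions.
* ``PARACHLORELLA`` — all S rounds first (uninuclear, successively di-,
  tetra-, ... polyploid); at the very end each nuclear division is
  immediately followed by a protoplast fission, so the cell is never more
  than binuclear.

The engine is strictly deterministic: population heterogeneity (e.g. half
of the cells completing three sequences and half four) is represented by
deterministic cohort fractions, not by per-cell randomness.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lightfield import (
    AttenuationModel,
    default_attenuation_model,
    mean_light_intensity,
    transmitted_intensity,
)

__all__ = [
    "PatternType",
    "PhaseDurations",
    "GrowthParams",
    "StarchParams",
    "ScenarioConfig",
    "CellState",
    "Event",
    "CohortTrajectory",
    "CultureTrajectory",
    "growth_rate",
    "GrowthState",
    "advance_growth",
    "schedule_reproduction",
    "simulate_culture",
    "dna_fold_increase",
    "daughters_released",
    "starch_step",
]


class PatternType(enum.Enum):
    """Closed enumeration of the four multiple-fission cell cycle patterns."""

    CONSECUTIVE_SCENEDESMUS = "consecutive_scenedesmus"
    CLUSTERED_CHLAMYDOMONAS = "clustered_chlamydomonas"
    HAEMATOCOCCUS = "haematococcus"
    PARACHLORELLA = "parachlorella"


# Event kinds in tie-break order for simultaneous (grid-snapped) events.
_EVENT_ORDER = {"CP": 0, "S_start": 1, "S_end": 2, "M": 3, "FISSION": 4, "DAUGHTER_RELEASE": 5}


@dataclass(frozen=True)
class Event:
    """One timestamped cell-cycle event; ``k`` indexes the reproductive sequence."""

    time: float
    kind: str
    k: int = 0
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _EVENT_ORDER:
            raise ValueError(f"unknown event kind {self.kind!r}")


def _sort_events(events: list[Event]) -> list[Event]:
    return sorted(events, key=lambda e: (e.time, _EVENT_ORDER[e.kind], e.k))


@dataclass(frozen=True)
class PhaseDurations:
    """Durations (h) of the post-commitment cell-cycle phases.

    ``pS`` is the lag between the *first* commitment point and the first DNA
    replication; later rounds need only ``pS_later`` of preparation because
    the replication machinery is already assembled, and are additionally
    spaced by ``inter_S_gap`` (the observed ~2 h pause without DNA
    synthesis between consecutive replication rounds).
    """

    pS: float = 7.5
    pS_later: float = 1.0
    S: float = 0.75
    G2: float = 1.0
    M: float = 0.25
    G3: float = 0.5
    C: float = 0.75
    inter_S_gap: float = 2.0

    def __post_init__(self) -> None:
        for name in ("pS", "pS_later", "S", "G2", "M", "G3", "C", "inter_S_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"phase duration {name} must be nonnegative")

    def scaled(self, factor: float) -> "PhaseDurations":
        """All durations multiplied by ``factor`` (deuterium retardation)."""
        if factor < 1:
            raise ValueError(f"retardation factor must be >= 1, got {factor}")
        return PhaseDurations(
            **{
                name: getattr(self, name) * factor
                for name in ("pS", "pS_later", "S", "G2", "M", "G3", "C", "inter_S_gap")
            }
        )


@dataclass(frozen=True)
class GrowthParams:
    """Light-saturated growth kinetics and inter-step idle intervals.

    Growth within a step is exponential at the Monod rate
    ``mu_max * I_m / (K_I + I_m)``; after each completed doubling the cell
    pauses for ``idle_base / (1 + idle_light_scaling * I_m / K_I)`` hours,
    reproducing the observed no-growth intervals that shrink with light.
    """

    mu_max: float = 0.6
    K_I: float = 200.0
    idle_base: float = 4.0
    idle_light_scaling: float = 3.0

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.K_I <= 0:
            raise ValueError("mu_max and K_I must be positive")
        if self.idle_base < 0 or self.idle_light_scaling < 0:
            raise ValueError("idle parameters must be nonnegative")

    def idle_length(self, I_m: float) -> float:
        return self.idle_base / (1.0 + self.idle_light_scaling * I_m / self.K_I)


@dataclass(frozen=True)
class StarchParams:
    """Net starch balance: light-driven synthesis minus consumption.

    Synthesis scales with biomass and saturates with mean light
    (``sigma_max * I_m / (K_sigma + I_m)`` µg starch per µg dry matter per
    hour).  Consumption has three routes: a biomass-proportional drain in
    the light (``maintenance_light``, the cost of the synthetic processes
    that suppresses net accumulation at low light), a first-order decay in
    the dark (``maintenance_dark``), and a fractional cost per protoplast
    fission (``division_cost``) since divisions are key starch consumers.
    """

    sigma_max: float = 0.023
    K_sigma: float = 100.0
    division_cost: float = 0.05
    maintenance_dark: float = 0.01
    maintenance_light: float = 0.00687

    def __post_init__(self) -> None:
        if min(self.sigma_max, self.K_sigma) <= 0:
            raise ValueError("sigma_max and K_sigma must be positive")
        if not 0 <= self.division_cost <= 1:
            raise ValueError("division_cost must be in [0, 1]")
        if min(self.maintenance_dark, self.maintenance_light) < 0:
            raise ValueError("maintenance rates must be nonnegative")


@dataclass(frozen=True)
class ScenarioConfig:
    """All constants of one simulated culture scenario.

    ``light_schedule`` is either ``None`` (continuous light) or a sequence
    of ``(light_h, dark_h)`` segments applied cyclically, e.g. ``[(18, 7)]``
    for the standard synchronization regime.  ``cohort_fractions`` maps the
    number of reproductive sequences ``n`` to the deterministic fraction of
    the population completing exactly ``n`` of them; each cohort's ``n``
    caps its growth steps.  ``retardation`` holds the two deuterium stress
    factors ``(rho_growth, rho_division)``: the first divides the growth
    rate, the second multiplies every phase duration.
    """

    name: str = "custom"
    I_i: float = 500.0
    light_schedule: tuple[tuple[float, float], ...] | None = ((18.0, 7.0),)
    pattern: PatternType = PatternType.PARACHLORELLA
    initial_dry_matter: float = 100.0
    initial_cell_conc: float = 1.0
    initial_DNA: float = 0.1
    initial_cell_volume: float = 25.0
    initial_starch: float = 5.0
    phase: PhaseDurations = field(default_factory=PhaseDurations)
    growth: GrowthParams = field(default_factory=GrowthParams)
    starch: StarchParams = field(default_factory=StarchParams)
    attenuation: AttenuationModel | None = None
    max_sequences: int = 4
    cohort_fractions: Mapping[int, float] = field(default_factory=lambda: {4: 1.0})
    retardation: tuple[float, float] = (1.0, 1.0)
    time_step: float = 0.05
    horizon: float = 25.0

    def __post_init__(self) -> None:
        if self.I_i <= 0:
            raise ValueError("incident intensity must be positive")
        for fname in (
            "initial_dry_matter",
            "initial_cell_conc",
            "initial_DNA",
            "initial_cell_volume",
            "time_step",
            "horizon",
        ):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        if self.initial_starch < 0:
            raise ValueError("initial_starch must be nonnegative")
        if not isinstance(self.pattern, PatternType):
            raise ValueError(f"pattern must be a PatternType, got {self.pattern!r}")
        fr = dict(self.cohort_fractions)
        if not fr:
            raise ValueError("cohort_fractions must not be empty")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValueError(f"cohort fractions must sum to 1, got {sum(fr.values())}")
        for n, f in fr.items():
            if n < 0 or n != int(n):
                raise ValueError(f"cohort key must be a nonnegative integer, got {n}")
            if f < 0:
                raise ValueError(f"cohort fraction must be nonnegative, got {f}")
            if n > self.max_sequences:
                raise ValueError(
                    f"cohort n={n} exceeds max_sequences={self.max_sequences}"
                )
        if self.retardation[0] < 1 or self.retardation[1] < 1:
            raise ValueError("retardation factors must be >= 1")
        if self.light_schedule is not None:
            for seg in self.light_schedule:
                if len(seg) != 2 or seg[0] <= 0 or seg[1] < 0:
                    raise ValueError(f"invalid light schedule segment {seg}")

    def attenuation_model(self) -> AttenuationModel:
        return self.attenuation if self.attenuation is not None else default_attenuation_model()

    def light_on(self, t: float) -> bool:
        """Whether the lamps are on at time ``t`` (boundaries count as dark)."""
        if self.light_schedule is None:
            return True
        period = sum(on + off for on, off in self.light_schedule)
        tau = t % period if period > 0 else t
        for on, off in self.light_schedule:
            if tau < on - 1e-12:
                return True
            tau -= on + off
            if tau < 0:
                return False
        return False


@dataclass(frozen=True)
class CellState:
    """Instantaneous per-cell state of one cohort."""

    t: float
    rna_rel: float
    dry_matter_rel: float
    volume_rel: float
    dna_pg_per_cell: float
    nuclei: int
    ploidy_per_nucleus: float
    protoplasts: int
    completed_growth_steps: int
    committed_sequences: int
    starch: float


# ---------------------------------------------------------------------------
# Growth steps and commitment


def growth_rate(I_m: float, g: GrowthParams, rho_growth: float = 1.0) -> float:
    """Specific growth rate (h⁻¹): Monod in mean light, divided by stress factor."""
    if I_m < 0:
        raise ValueError(f"mean light intensity must be nonnegative, got {I_m}")
    if rho_growth < 1:
        raise ValueError(f"rho_growth must be >= 1, got {rho_growth}")
    return g.mu_max * I_m / (g.K_I + I_m) / rho_growth


@dataclass(frozen=True)
class GrowthState:
    """Progress of one cohort through its stepwise growth.

    ``proxies`` hold biomass proxies relative to their initial values; all
    proxies grow at the common rate, but each may carry a cap on doublings
    (``caps``) after which it freezes — e.g. RNA completes one doubling
    fewer than cell volume in fast-growing cells.  Cell volume is the sizer
    reference: a commitment point fires exactly when it completes a
    doubling, at which point every uncapped proxy is snapped to exactly
    ``2**k`` to keep step arithmetic exact.
    """

    t: float = 0.0
    completed_steps: int = 0
    idle_until: float = 0.0
    step_start_ref: float = 1.0
    proxies: Mapping[str, float] = field(
        default_factory=lambda: {"rna": 1.0, "dry_matter": 1.0, "volume": 1.0}
    )
    caps: Mapping[str, int] = field(default_factory=dict)
    reference: str = "volume"

    def cap_of(self, name: str) -> int:
        return int(self.caps.get(name, 10**9))


def advance_growth(
    state: GrowthState,
    dt: float,
    rate: float,
    idle_length: float = 0.0,
    max_steps: int = 10**9,
) -> tuple[GrowthState, float | None]:
    """Advance growth by ``dt`` hours at specific rate ``rate``.

    Proxies multiply by ``exp(rate * dt)`` while inside an active growth
    step; growth is frozen during idle intervals and when ``rate`` is zero
    (dark).  When the reference proxy reaches twice its value at step
    start, the step completes: the commitment time is returned, proxies are
    snapped to exact powers of two, and an idle interval of ``idle_length``
    hours begins.  At most one completion can occur per call (callers use
    sub-hour steps).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    t_end = state.t + dt
    if rate <= 0 or state.completed_steps >= max_steps:
        return replace(state, t=t_end), None
    grow_start = max(state.t, state.idle_until)
    if grow_start >= t_end:
        return replace(state, t=t_end), None
    span = t_end - grow_start
    k = state.completed_steps
    ref_val = state.proxies[state.reference]
    target = 2.0 * state.step_start_ref
    factor = math.exp(rate * span)
    if ref_val * factor < target - 1e-12:
        new_proxies = {
            name: (val * factor if k < state.cap_of(name) else val)
            for name, val in state.proxies.items()
        }
        return replace(state, t=t_end, proxies=new_proxies), None
    # step completes within this interval: locate the crossing exactly
    t_cross = grow_start + math.log(target / ref_val) / rate
    k_new = k + 1
    new_proxies = {
        name: (2.0**min(k_new, state.cap_of(name)))
        for name in state.proxies
    }
    new_state = replace(
        state,
        t=t_end,
        completed_steps=k_new,
        idle_until=t_cross + idle_length,
        step_start_ref=2.0**k_new,
        proxies=new_proxies,
    )
    return new_state, t_cross


# ---------------------------------------------------------------------------
# Reproductive sequence scheduling


def _schedule_s_rounds(
    cp_times: Sequence[float], phase: PhaseDurations
) -> list[tuple[float, float]]:
    """Consecutive replication rounds: the first waits out the full pre-S
    lag after its commitment; later rounds start as soon as their commitment
    plus a short preparation allows, but never closer than ``inter_S_gap``
    after the previous round ended."""
    rounds: list[tuple[float, float]] = []
    for k, cp in enumerate(cp_times):
        if k == 0:
            start = cp + phase.pS
        else:
            start = max(cp + phase.pS_later, rounds[-1][1] + phase.inter_S_gap)
        rounds.append((start, start + phase.S))
    return rounds


def schedule_reproduction(
    pattern: PatternType,
    cp_times: Sequence[float],
    phase: PhaseDurations,
) -> list[Event]:
    """Build the pattern-lawful event log for ``n = len(cp_times)`` sequences.

    ``cp_times`` must be sorted ascending; an empty list yields an empty
    log (no division, a single persisting cell).
    """
    cps = list(cp_times)
    if any(b < a for a, b in zip(cps, cps[1:])):
        raise ValueError("cp_times must be sorted ascending")
    n = len(cps)
    if n == 0:
        return []
    events: list[Event] = [Event(cp, "CP", k + 1) for k, cp in enumerate(cps)]

    if pattern is PatternType.PARACHLORELLA:
        s_rounds = _schedule_s_rounds(cps, phase)
        for k, (s0, s1) in enumerate(s_rounds, start=1):
            events += [Event(s0, "S_start", k), Event(s1, "S_end", k)]
        # all replication first; then M/fission pairs with no G3 and a
        # binuclear state lasting exactly the fission duration C
        t = s_rounds[-1][1] + phase.G2 + phase.M
        for k in range(1, n + 1):
            events.append(Event(t, "M", k))
            events.append(Event(t + phase.C, "FISSION", k))
            t += phase.C + phase.M
        events.append(Event(events[-1].time + phase.C, "DAUGHTER_RELEASE", n))

    elif pattern is PatternType.HAEMATOCOCCUS:
        s_rounds = _schedule_s_rounds(cps, phase)
        for k, (s0, s1) in enumerate(s_rounds, start=1):
            events += [Event(s0, "S_start", k), Event(s1, "S_end", k)]
        t = s_rounds[-1][1] + phase.G2
        for k in range(1, n + 1):
            t += phase.M
            events.append(Event(t, "M", k))
        t += phase.G3
        for k in range(1, n + 1):
            t += phase.C
            events.append(Event(t, "FISSION", k))
        events.append(Event(t + phase.C, "DAUGHTER_RELEASE", n))

    elif pattern is PatternType.CLUSTERED_CHLAMYDOMONAS:
        # nothing before the last commitment; then rapid S/M alternation
        t = cps[-1] + phase.pS
        for k in range(1, n + 1):
            events.append(Event(t, "S_start", k))
            t += phase.S
            events.append(Event(t, "S_end", k))
            t += phase.M
            events.append(Event(t, "M", k))
        t += phase.G3
        for k in range(1, n + 1):
            t += phase.C
            events.append(Event(t, "FISSION", k))
        events.append(Event(t + phase.C, "DAUGHTER_RELEASE", n))

    else:  # CONSECUTIVE_SCENEDESMUS
        m_times = []
        for k, cp in enumerate(cps, start=1):
            s0 = cp + phase.pS
            s1 = s0 + phase.S
            m = s1 + phase.G2 + phase.M
            events += [Event(s0, "S_start", k), Event(s1, "S_end", k)]
            m_times.append(m)
            events.append(Event(m, "M", k))
        if any(b < a for a, b in zip(m_times, m_times[1:])):
            raise ValueError("phase durations produce out-of-order nuclear divisions")
        t = m_times[-1] + phase.G3
        for k in range(1, n + 1):
            t += phase.C
            events.append(Event(t, "FISSION", k))
        events.append(Event(t + phase.C, "DAUGHTER_RELEASE", n))

    return _sort_events(events)


# ---------------------------------------------------------------------------
# Simple closed-form population statistics


def dna_fold_increase(cohort_fractions: Mapping[int, float]) -> float:
    """Population-mean DNA fold: sum of fraction(n) * 2**n over cohorts."""
    total = 0.0
    s = 0.0
    for n, f in cohort_fractions.items():
        if f < 0:
            raise ValueError(f"cohort fraction must be nonnegative, got {f}")
        if n < 0 or n != int(n):
            raise ValueError(f"cohort key must be a nonnegative integer, got {n}")
        total += f * 2.0**n
        s += f
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"cohort fractions must sum to 1, got {s}")
    return total


def daughters_released(n: int) -> int:
    """Daughter cells released by a mother completing ``n`` sequences: 2**n."""
    if n < 0 or n != int(n):
        raise ValueError(f"n must be a nonnegative integer, got {n}")
    return 2 ** int(n)


def starch_step(
    starch: float,
    biomass: float,
    dt: float,
    I_m: float,
    p: StarchParams,
    dark: bool = False,
    fissions: int = 0,
) -> float:
    """One integration step of the net starch balance (culture basis, µg/mL).

    In the light, synthesis ``biomass * sigma_max * I_m / (K_sigma + I_m)``
    competes with the biomass-proportional maintenance drain; in the dark
    starch decays first-order.  Each fission event multiplies the pool by
    ``1 - division_cost``.  The pool is clamped at zero.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if dark:
        starch = starch * math.exp(-p.maintenance_dark * dt)
    else:
        net = biomass * (p.sigma_max * I_m / (p.K_sigma + I_m) - p.maintenance_light)
        starch = starch + dt * net
    for _ in range(fissions):
        starch *= 1.0 - p.division_cost
    return max(starch, 0.0)


# ---------------------------------------------------------------------------
# Full culture simulation


@dataclass
class CohortTrajectory:
    """Per-cohort time series plus its own event log."""

    n: int
    fraction: float
    data: pd.DataFrame
    events: list[Event]
    release_time: float | None

    def state_at(self, t: float) -> CellState:
        idx = int(np.searchsorted(self.data["time_h"].to_numpy(), t, side="right")) - 1
        idx = max(idx, 0)
        row = self.data.iloc[idx]
        return CellState(
            t=float(row["time_h"]),
            rna_rel=float(row["rna_rel"]),
            dry_matter_rel=float(row["dry_matter_rel"]),
            volume_rel=float(row["volume_rel"]),
            dna_pg_per_cell=float(row["dna_pg_per_cell"]),
            nuclei=int(row["nuclei"]),
            ploidy_per_nucleus=float(row["ploidy_C"]),
            protoplasts=int(row["protoplasts"]),
            completed_growth_steps=int(row["completed_steps"]),
            committed_sequences=int(row["committed_sequences"]),
            starch=float(row["starch_ug_per_ml"]),
        )


@dataclass
class CultureTrajectory:
    """Uniformly sampled culture state plus the merged event log.

    ``data`` carries the culture-level and fraction-weighted per-cell
    columns; ``cohorts`` the per-cohort detail.  ``truncated`` flags a
    horizon that ended before every committed sequence completed.
    """

    config: ScenarioConfig
    data: pd.DataFrame
    events: list[Event]
    cohorts: dict[int, CohortTrajectory]
    truncated: bool

    @property
    def dna_fold(self) -> float:
        """Fraction-weighted mean of per-cohort peak DNA folds."""
        return sum(
            c.fraction * c.data["dna_pg_per_cell"].max() / self.config.initial_DNA
            for c in self.cohorts.values()
        )

    def daughters_per_mother(self) -> float:
        """Fraction-weighted daughters released per mother cell."""
        total = 0.0
        for c in self.cohorts.values():
            rel = [e for e in c.events if e.kind == "DAUGHTER_RELEASE"]
            total += c.fraction * (rel[0].payload["daughters"] if rel else 1)
        return total


def _snap(t: float, dt: float) -> float:
    """Earliest grid point at or after ``t``."""
    return math.ceil(t / dt - 1e-9) * dt


def simulate_culture(config: ScenarioConfig) -> CultureTrajectory:
    """Run the full deterministic scenario and assemble the trajectory.

    The integration proceeds in two passes.  Pass one integrates stepwise
    growth of every cohort jointly with the light feedback (culture dry
    matter → mean light → growth rate) on a fixed grid, collecting the
    commitment times.  Pass two schedules each cohort's reproductive events
    from those commitments, replays the nuclear bookkeeping (ploidy, nuclei,
    protoplasts, DNA) and integrates the starch balance, then merges the
    cohorts into culture-level series.
    """
    dt = config.time_step
    n_pts = int(round(config.horizon / dt)) + 1
    grid = np.arange(n_pts) * dt
    model = config.attenuation_model()
    rho_growth, rho_division = config.retardation
    phase = config.phase.scaled(rho_division)

    cohort_ns = sorted(config.cohort_fractions)
    fracs = {n: float(config.cohort_fractions[n]) for n in cohort_ns}

    # --- pass one: growth with light feedback ---
    states: dict[int, GrowthState] = {
        n: GrowthState(caps={"rna": min(n, 3), "dry_matter": n, "volume": n})
        for n in cohort_ns
    }
    cp_times: dict[int, list[float]] = {n: [] for n in cohort_ns}
    growth_series: dict[int, dict[str, np.ndarray]] = {
        n: {p: np.empty(n_pts) for p in ("rna", "dry_matter", "volume")}
        for n in cohort_ns
    }
    steps_series: dict[int, np.ndarray] = {n: np.empty(n_pts, dtype=int) for n in cohort_ns}
    im_series = np.empty(n_pts)
    lit_series = np.empty(n_pts, dtype=bool)

    for i, t in enumerate(grid):
        X = sum(
            fracs[n] * config.initial_dry_matter * states[n].proxies["dry_matter"]
            for n in cohort_ns
        )
        lit = config.light_on(t)
        if lit:
            I_t = transmitted_intensity(config.I_i, X, model)
            I_m = mean_light_intensity(config.I_i, I_t)
        else:
            I_m = 0.0
        im_series[i] = I_m
        lit_series[i] = lit
        for n in cohort_ns:
            for p in ("rna", "dry_matter", "volume"):
                growth_series[n][p][i] = states[n].proxies[p]
            steps_series[n][i] = states[n].completed_steps
        if i == n_pts - 1:
            break
        rate = growth_rate(I_m, config.growth, rho_growth) if lit else 0.0
        for n in cohort_ns:
            idle = config.growth.idle_length(I_m)
            states[n], cp = advance_growth(states[n], dt, rate, idle, max_steps=n)
            if cp is not None:
                cp_times[n].append(_snap(cp, dt))

    # --- pass two: reproduction, nuclear bookkeeping and starch ---
    cohorts: dict[int, CohortTrajectory] = {}
    truncated = False
    for n in cohort_ns:
        events = schedule_reproduction(config.pattern, cp_times[n], phase)
        events = [replace(e, time=_snap(e.time, dt)) for e in events]
        events = _sort_events(events)
        release = next((e for e in events if e.kind == "DAUGHTER_RELEASE"), None)
        release_time = release.time if release is not None else None
        if release_time is not None and release_time > config.horizon + 1e-9:
            truncated = True

        dna_rel = np.ones(n_pts)  # total DNA per mother, units of initial_DNA
        nuclei = np.ones(n_pts, dtype=int)
        ploidy = np.ones(n_pts)
        protoplasts = np.ones(n_pts, dtype=int)
        committed = np.zeros(n_pts, dtype=int)
        released = np.zeros(n_pts, dtype=bool)

        for k, cp in enumerate(cp_times[n], start=1):
            committed[grid >= cp - 1e-9] = k
        s_rounds = [
            (e.time, next(x.time for x in events if x.kind == "S_end" and x.k == e.k))
            for e in events
            if e.kind == "S_start"
        ]
        for k, (s0, s1) in enumerate(s_rounds, start=1):
            pre = 2.0 ** (k - 1)
            in_s = (grid >= s0 - 1e-9) & (grid < s1 - 1e-9)
            dna_rel[in_s] = pre * (1.0 + (grid[in_s] - s0) / (s1 - s0))
            dna_rel[grid >= s1 - 1e-9] = 2.0**k
        # the nuclear counters apply the uniform event algebra:
        # S_end doubles per-nucleus ploidy, M doubles nuclei and halves
        # ploidy, FISSION doubles protoplasts and halves per-protoplast nuclei
        for e in events:
            after = grid >= e.time - 1e-9
            if e.kind == "S_end":
                ploidy[after] *= 2.0
            elif e.kind == "M":
                nuclei[after] *= 2
                ploidy[after] /= 2.0
            elif e.kind == "FISSION":
                protoplasts[after] *= 2
                nuclei[after] //= 2
            elif e.kind == "DAUGHTER_RELEASE":
                released[after] = True

        # starch (culture basis, this cohort's share)
        starch = np.empty(n_pts)
        s_val = config.initial_starch * fracs[n]
        fission_times = {e.time for e in events if e.kind == "FISSION"}
        starch[0] = s_val
        for i in range(1, n_pts):
            biomass = fracs[n] * config.initial_dry_matter * growth_series[n]["dry_matter"][i - 1]
            s_val = starch_step(
                s_val,
                biomass,
                dt,
                im_series[i - 1],
                config.starch,
                dark=not lit_series[i - 1],
                fissions=1 if grid[i] in fission_times else 0,
            )
            starch[i] = s_val

        m = len(cp_times[n])  # sequences actually committed (may trail the cap)
        factor = float(2**m)
        divisor = np.where(released, factor, 1.0)
        cell_conc = fracs[n] * config.initial_cell_conc * divisor
        # per-protoplast DNA in pg; equals per-daughter DNA after release
        dna_pg = config.initial_DNA * dna_rel / protoplasts
        dna_pg[released] = config.initial_DNA
        data = pd.DataFrame(
            {
                "time_h": grid,
                "cell_conc_1e6_per_ml": cell_conc,
                "dry_matter_ug_per_ml": fracs[n]
                * config.initial_dry_matter
                * growth_series[n]["dry_matter"],
                "mean_light": im_series,
                "dna_pg_per_cell": dna_pg,
                "rna_rel": growth_series[n]["rna"] / divisor,
                "dry_matter_rel": growth_series[n]["dry_matter"] / divisor,
                "volume_rel": growth_series[n]["volume"] / divisor,
                "volume_um3": config.initial_cell_volume
                * growth_series[n]["volume"]
                / divisor,
                "starch_ug_per_ml": starch,
                "nuclei": np.where(released, 1, nuclei),
                "ploidy_C": np.where(released, 1.0, ploidy),
                "protoplasts": np.where(released, 1, protoplasts),
                "completed_steps": steps_series[n],
                "committed_sequences": committed,
            }
        )
        if release is not None:
            events = [
                replace(e, payload={**e.payload, "daughters": 2**m})
                if e.kind == "DAUGHTER_RELEASE"
                else e
                for e in events
            ]
        cohorts[n] = CohortTrajectory(
            n=n, fraction=fracs[n], data=data, events=events, release_time=release_time
        )

    # --- merge cohorts into culture-level series ---
    merged_events = _sort_events(
        [
            replace(e, payload={**e.payload, "cohort_n": n})
            for n, c in cohorts.items()
            for e in c.events
        ]
    )
    frame = pd.DataFrame({"time_h": grid, "mean_light": im_series})
    frame["cell_conc_1e6_per_ml"] = sum(
        c.data["cell_conc_1e6_per_ml"] for c in cohorts.values()
    )
    frame["dry_matter_ug_per_ml"] = sum(
        c.data["dry_matter_ug_per_ml"] for c in cohorts.values()
    )
    frame["starch_ug_per_ml"] = sum(c.data["starch_ug_per_ml"] for c in cohorts.values())
    for col in ("dna_pg_per_cell", "rna_rel", "volume_um3", "nuclei", "ploidy_C"):
        frame[col] = sum(c.fraction * c.data[col] for c in cohorts.values())
    frame = frame[
        [
            "time_h",
            "cell_conc_1e6_per_ml",
            "dry_matter_ug_per_ml",
            "mean_light",
            "dna_pg_per_cell",
            "rna_rel",
            "volume_um3",
            "starch_ug_per_ml",
            "nuclei",
            "ploidy_C",
        ]
    ]
    return CultureTrajectory(
        config=config,
        data=frame,
        events=merged_events,
        cohorts=cohorts,
        truncated=truncated,
    )
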