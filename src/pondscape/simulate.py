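"""Event-driven metacommunity simulation.

The metacommunity state couples discrete occupancy (which species are present
at which sites) with continuous biomasses that always sit at the local
Lotka-Volterra equilibrium of each active site's survivor set.  Three kinds
of events drive the dynamics:

* **activation / deactivation** -- deterministic, read off the activation
  schedule; deactivation zeroes the site, activation opens an empty site.
* **dispersal** -- a continuous-time Markov chain.  Species ``s`` can move
  along a landscape edge (p, q) when both sites are active, ``s`` is present
  in p and absent from q, and ``s`` is basal or has at least one prey present
  in q (prey gating).  The per-event rate is ``a / d(p, q)``, floored to zero
  when below 0.1.  The next event is chosen by the first-reaction method:
  every candidate draws an independent exponential waiting time and the
  minimum fires; waiting times are redrawn after every event, which is
  statistically exact by memorylessness.

An arrival triggers an instantaneous equilibrium recomputation at the
destination, including secondary-extinction cascades.  An arrival whose own
species is cascade-removed leaves the destination unchanged (failed
invasion).  Because the cascade is deterministic given the destination's
composition, a failed (site, species) invasion is a null event of the Markov
chain and would fail identically until the composition changes; such pairs
are therefore blocked until the site changes, which leaves the law of the
state trajectory unchanged while avoiding re-simulating no-op events.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .community import LocalDynamics, local_equilibrium
from .exceptions import ConsistencyError
from .foodweb import FoodWeb
from .landscape import ActivationSchedule, Landscape, is_active

__all__ = [
    "RATE_CUTOFF",
    "MetacommunityState",
    "Event",
    "Trajectory",
    "effective_rate",
    "eligible_dispersal_events",
    "first_reaction_step",
    "apply_event",
    "simulate_run",
]

#: Dispersal rates a/d below this value are set to zero.
RATE_CUTOFF = 0.1

_KIND_PRIORITY = {"deactivate": 0, "activate": 1, "dispersal": 2}


def effective_rate(a: float, d: float) -> float:
    """Dispersal rate along an edge of length ``d``: ``a/d``, floored to 0
    when below the 0.1 cutoff."""
    if d <= 0:
        raise ValueError("distance must be positive")
    rate = a / d
    return rate if rate >= RATE_CUTOFF else 0.0


@dataclass
class Event:
    time: float
    kind: str  # "activate" | "deactivate" | "dispersal"
    site: int | None = None
    species: int | None = None
    source: int | None = None
    success: bool | None = None
    extinctions: tuple = ()


@dataclass
class MetacommunityState:
    """Occupancy, biomass and activity of every site at time ``t``."""

    t: float
    present: np.ndarray  # (n_P, n_S) bool
    biomass: np.ndarray  # (n_P, n_S) float
    active: np.ndarray  # (n_P,) bool
    blocked: np.ndarray  # (n_P, n_S) bool: invasions known to fail
    mainland: int

    @property
    def n_P(self) -> int:
        return self.present.shape[0]

    @property
    def n_S(self) -> int:
        return self.present.shape[1]

    def richness(self) -> np.ndarray:
        return self.present.sum(axis=1)

    def site_biomass(self) -> np.ndarray:
        return self.biomass.sum(axis=1)

    def copy(self) -> "MetacommunityState":
        return MetacommunityState(
            t=self.t,
            present=self.present.copy(),
            biomass=self.biomass.copy(),
            active=self.active.copy(),
            blocked=self.blocked.copy(),
            mainland=self.mainland,
        )


def initial_state(
    L: Landscape, schedule: ActivationSchedule, dyn: LocalDynamics
) -> MetacommunityState:
    """State at t = 0: mainland active and full; every site whose schedule
    covers 0 is active and empty."""
    n_P, n_S = L.n_P, dyn.n_S
    present = np.zeros((n_P, n_S), dtype=bool)
    biomass = np.zeros((n_P, n_S))
    active = np.array([is_active(schedule, p, 0.0) for p in range(n_P)])
    present[L.mainland] = True
    biomass[L.mainland] = dyn.x_star
    return MetacommunityState(
        t=0.0,
        present=present,
        biomass=biomass,
        active=active,
        blocked=np.zeros((n_P, n_S), dtype=bool),
        mainland=L.mainland,
    )


def _directed_edges(L: Landscape, a: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed (src, dst, rate) arrays for all edges with non-zero rate."""
    rates = np.array([effective_rate(a, d) for d in L.weights]) if a > 0 else np.zeros(L.n_E)
    keep = rates > 0
    u, v = L.edges[keep, 0], L.edges[keep, 1]
    r = rates[keep]
    src = np.concatenate([u, v])
    dst = np.concatenate([v, u])
    return src, dst, np.concatenate([r, r])


def eligible_dispersal_events(
    state: MetacommunityState, L: Landscape, W: FoodWeb, a: float
) -> list[tuple[int, int, int, float]]:
    """All (species, from-site, to-site, rate) candidates at the current state.

    Both directions of every edge are considered; the mainland is a valid
    source and (being always saturated) never a destination in practice.
    """
    src, dst, rates = _directed_edges(L, a)
    sp, si, di, ra = _eligible_arrays(state, W, src, dst, rates)
    return list(zip(sp.tolist(), si.tolist(), di.tolist(), ra.tolist()))


def _eligible_arrays(
    state: MetacommunityState,
    W: FoodWeb,
    src: np.ndarray,
    dst: np.ndarray,
    rates: np.ndarray,
):
    """Vectorized candidate enumeration; returns (species, src, dst, rate)."""
    ok = state.active[src] & state.active[dst]
    src, dst, rates = src[ok], dst[ok], rates[ok]
    if src.size == 0:
        e = np.empty(0, dtype=int)
        return e, e, e, np.empty(0)
    # prey support at the destination: basal, or >= 1 prey present
    support = (state.present @ W.prey_matrix) > 0
    support |= W.basal[None, :]
    elig = (
        state.present[src]
        & ~state.present[dst]
        & support[dst]
        & ~state.blocked[dst]
    )
    edge_idx, species = np.nonzero(elig)
    return species, src[edge_idx], dst[edge_idx], rates[edge_idx]


def first_reaction_step(
    t: float,
    candidates,
    next_scheduled: tuple[float, str, int] | None,
    horizon: float,
    rng: np.random.Generator,
) -> tuple[float, Event | None]:
    """Pick the next event: the minimum of one exponential waiting time per
    dispersal candidate and the next deterministic schedule entry.

    ``candidates`` is a sequence of (species, from, to, rate) tuples or the
    equivalent column arrays. Returns ``(horizon, None)`` when nothing fires
    before the horizon. Schedule events win ties against dispersal (their
    times are deterministic; dispersal ties have probability zero).
    """
    t_sched = next_scheduled[0] if next_scheduled is not None else np.inf
    if (
        isinstance(candidates, tuple)
        and len(candidates) == 4
        and all(isinstance(c, np.ndarray) for c in candidates)
    ):
        species, src, dst, rates = candidates
    else:
        arr = np.array([(c[0], c[1], c[2], c[3]) for c in candidates], dtype=float)
        if arr.size == 0:
            species = src = dst = np.empty(0, dtype=int)
            rates = np.empty(0)
        else:
            species, src, dst = arr[:, 0].astype(int), arr[:, 1].astype(int), arr[:, 2].astype(int)
            rates = arr[:, 3]

    t_disp = np.inf
    winner = -1
    if len(rates):
        waits = rng.exponential(size=len(rates)) / rates
        winner = int(np.argmin(waits))
        t_disp = t + waits[winner]

    t_next = min(t_disp, t_sched, horizon)
    if t_next >= horizon:
        return horizon, None
    if t_sched <= t_disp:
        time, kind, site = next_scheduled
        return t_next, Event(time=time, kind=kind, site=site)
    return t_next, Event(
        time=float(t_disp),
        kind="dispersal",
        site=int(dst[winner]),
        species=int(species[winner]),
        source=int(src[winner]),
    )


def apply_event(
    state: MetacommunityState, event: Event, dynamics: LocalDynamics
) -> MetacommunityState:
    """Apply one event in place (and return the state).

    Deactivation zeroes the site; activation opens it empty; a dispersal
    arrival inserts the species and recomputes the destination equilibrium,
    cascading secondary extinctions. The mainland never changes.
    """
    if event.time < state.t:
        raise ConsistencyError("event time precedes current state time")
    if event.site is None or not 0 <= event.site < state.n_P:
        raise ConsistencyError(f"invalid site in event: {event.site}")
    p = event.site
    state.t = event.time

    if event.kind == "deactivate":
        if p == state.mainland:
            raise ConsistencyError("mainland cannot deactivate")
        state.active[p] = False
        state.present[p] = False
        state.biomass[p] = 0.0
        state.blocked[p] = False
        return state

    if event.kind == "activate":
        if p == state.mainland:
            raise ConsistencyError("mainland is always active")
        state.active[p] = True
        state.present[p] = False
        state.biomass[p] = 0.0
        state.blocked[p] = False
        return state

    if event.kind == "dispersal":
        s, q = event.species, p
        if q == state.mainland:
            raise ConsistencyError("mainland composition is fixed")
        if not state.active[q] or (event.source is not None and not state.active[event.source]):
            raise ConsistencyError("dispersal between inactive sites")
        if state.present[q, s]:
            raise ConsistencyError("species already present at destination")
        trial = state.present[q].copy()
        trial[s] = True
        res = local_equilibrium(dynamics, trial, invader=s)
        if s in res.survivors:
            state.present[q] = False
            state.present[q, res.survivors] = True
            state.biomass[q] = res.biomass
            state.blocked[q] = False  # composition changed: retry everything
            event.success = True
            event.extinctions = tuple(res.extinctions)
        else:
            # failed invasion: destination unchanged, remember the failure
            state.blocked[q, s] = True
            event.success = False
            event.extinctions = tuple(res.extinctions)
        return state

    raise ConsistencyError(f"unknown event kind: {event.kind}")


@dataclass
class Trajectory:
    """Piecewise-constant record of a run.

    ``intervals`` rows are (t0, t1); per-interval site summaries are stored in
    the parallel arrays ``richness`` (n_int, n_P), ``site_biomass``
    (n_int, n_P), ``active`` (n_int, n_P) and ``gamma_richness`` (n_int,)
    (union of species over non-mainland sites).
    """

    horizon: float
    n_S: int
    mainland: int
    intervals: np.ndarray
    richness: np.ndarray
    site_biomass: np.ndarray
    active: np.ndarray
    gamma_richness: np.ndarray
    events: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def events_to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time", "kind", "species", "from", "to", "success", "n_extinctions"])
            for e in self.events:
                w.writerow(
                    [e.time, e.kind, e.species, e.source, e.site, e.success, len(e.extinctions)]
                )

    def snapshots_to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_start", "t_end", "site", "richness", "biomass", "active"])
            for k, (t0, t1) in enumerate(self.intervals):
                for p in range(self.richness.shape[1]):
                    w.writerow(
                        [t0, t1, p, int(self.richness[k, p]),
                         float(self.site_biomass[k, p]), int(self.active[k, p])]
                    )

    def metadata_to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"horizon": self.horizon, "n_S": self.n_S, "mainland": self.mainland,
                 **{k: v for k, v in self.params.items()}},
                fh, indent=2, default=str,
            )


def _snapshot(state: MetacommunityState):
    nm = np.arange(state.n_P) != state.mainland
    gamma = int(state.present[nm].any(axis=0).sum())
    return state.richness(), state.site_biomass(), state.active.copy(), gamma


def simulate_run(
    L: Landscape,
    schedule: ActivationSchedule,
    W: FoodWeb,
    D: LocalDynamics,
    a: float,
    horizon: float,
    seed: int,
    record_events: bool = True,
    check_invariants: bool = False,
) -> Trajectory:
    """Run the event loop from t = 0 to ``horizon`` and record the trajectory.

    The mainland starts full at the regional equilibrium; all other sites
    start empty (active or not per their schedule). ``check_invariants``
    re-verifies prey gating after every event (used by the test suite).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = np.random.default_rng(seed)
    state = initial_state(L, schedule, D)
    sched_events = schedule.events(horizon)
    src, dst, rates = _directed_edges(L, a)
    ptr = 0

    times: list[tuple[float, float]] = []
    rich: list[np.ndarray] = []
    biom: list[np.ndarray] = []
    act: list[np.ndarray] = []
    gam: list[int] = []
    events: list[Event] = []

    while state.t < horizon:
        cands = _eligible_arrays(state, W, src, dst, rates)
        nxt = sched_events[ptr] if ptr < len(sched_events) else None
        t_next, event = first_reaction_step(state.t, cands, nxt, horizon, rng)

        r, b, av, g = _snapshot(state)
        times.append((state.t, t_next))
        rich.append(r)
        biom.append(b)
        act.append(av)
        gam.append(g)

        if event is None:
            state.t = horizon
            break
        if event.kind != "dispersal":
            ptr += 1
        apply_event(state, event, D)
        if record_events:
            events.append(event)
        if check_invariants:
            _assert_prey_gating(state, W)

    return Trajectory(
        horizon=horizon,
        n_S=D.n_S,
        mainland=L.mainland,
        intervals=np.array(times).reshape(-1, 2),
        richness=np.array(rich, dtype=np.int32),
        site_biomass=np.array(biom),
        active=np.array(act, dtype=bool),
        gamma_richness=np.array(gam, dtype=np.int32),
        events=events,
        params={"a": a, "seed": seed, "A": schedule.A, "years": schedule.years},
    )


def _assert_prey_gating(state: MetacommunityState, W: FoodWeb) -> None:
    support = (state.present @ W.prey_matrix) > 0
    support |= W.basal[None, :]
    bad = state.present & ~support
    if bad.any():
        where = np.argwhere(bad)
        raise AssertionError(f"consumer without prey at (site, species) {where.tolist()}")
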