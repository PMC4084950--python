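"""Hybrid deterministic/stochastic simulation of CRISPR host-phage coevolution.

Ecology is density-dependent Lotka-Volterra: logistic host growth, mass-action
adsorption, burst-size viral replication and free-virion decay, integrated
with fixed-step RK4. Evolution is stochastic strain creation layered on top:
hosts acquire spacers by copying a protospacer of an adsorbing virus
(leader-end insertion, trailer-end loss when the locus of length S is full),
and viruses mutate protospacers to globally novel alleles during replication
(infinite-alleles, no back-mutation). Event counts per step are Poisson draws
of the corresponding rate fluxes; the simulation volume is fixed at 1 mL so
densities double as expected counts.

An adsorption by a vulnerable host leads to spacer acquisition (probability
q, host survives) or lysis; immune hosts deactivate the virion, with
immunity failing at probability f. Every adsorption removes a virion.

Strain arrays are stored in capacity-doubling buffers so that the frequent
strain births and deaths cost amortized O(strains), not a full matrix copy
per event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .community import Community, HostStrain, ViralStrain, normalize_community

logger = logging.getLogger(__name__)


@dataclass
class SimParams:
    """Simulation parameters.

    Rates are per hour; one hour equals one host generation (the inverse of
    the host growth rate r). Densities are per mL.
    """

    S: int = 10            # max spacers per host locus
    P: int = 10            # protospacers per virus
    q: float = 1e-5        # spacer acquisition probability per adsorption
    mu: float = 5e-7       # protospacer mutation probability per protospacer per virion
    r: float = 1.0         # host growth rate (1/h)
    K: float = 3.158e5     # carrying capacity (cells/mL); 3e5 is ~95% of K
    phi: float = 1e-7      # adsorption rate (mL/h)
    beta: float = 50.0     # burst size
    m_v: float = 0.1       # free-virion decay rate (1/h)
    f: float = 1e-5        # probability immunity fails despite a matching spacer
    dt: float = 0.05       # RK4 step (h)
    cutoff: float = 0.1    # extinction / pruning density (1/mL)
    t_end: float = 10000.0
    record_every: float = 1.0
    host_init_density: float = 1e5
    viral_init_density: float = 1e6
    seed: Optional[int] = None

    def validate(self) -> None:
        for name in ("q", "mu", "f"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("r", "K", "phi", "beta", "m_v", "t_end", "record_every",
                     "host_init_density", "viral_init_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.dt < 1:
            raise ValueError("dt must be in (0, 1)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.S < 1 or self.P < 1:
            raise ValueError("S and P must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


class SimState:
    """Mutable simulation state: genotypes, densities, and the host-virus
    match-presence matrix, all in growable buffers.

    Pruned strains are tombstoned (density zeroed, genotype set to None) so
    they contribute exactly nothing to the dynamics; buffers are compacted
    only when a quarter of the slots are dead, keeping per-event cost
    amortized O(strains).
    """

    __slots__ = (
        "time", "n_h", "n_v", "host_ids", "host_spacers", "host_sets",
        "viral_ids", "viral_protospacers", "viral_sets",
        "_N", "_V", "_M", "dead_h", "dead_v",
        "next_allele", "next_host_id", "next_viral_id",
        "n_acquisitions", "n_mutations",
    )

    def __init__(self, params: SimParams):
        cap = 16
        self.time = 0.0
        self.n_h = 1
        self.n_v = 1
        self.host_ids = [0]
        self.host_spacers: list[tuple[int, ...] | None] = [()]
        self.host_sets: list[frozenset | None] = [frozenset()]
        proto = tuple(range(params.P))
        self.viral_ids = [0]
        self.viral_protospacers: list[tuple[int, ...] | None] = [proto]
        self.viral_sets: list[frozenset | None] = [frozenset(proto)]
        self._N = np.zeros(cap)
        self._N[0] = params.host_init_density
        self._V = np.zeros(cap)
        self._V[0] = params.viral_init_density
        self._M = np.zeros((cap, cap), dtype=np.float32)
        self.dead_h = 0
        self.dead_v = 0
        self.next_allele = params.P
        self.next_host_id = 1
        self.next_viral_id = 1
        self.n_acquisitions = 0
        self.n_mutations = 0

    # -- views ------------------------------------------------------------

    @property
    def host_density(self) -> np.ndarray:
        return self._N[: self.n_h]

    @host_density.setter
    def host_density(self, values: np.ndarray) -> None:
        self._N[: self.n_h] = values

    @property
    def viral_density(self) -> np.ndarray:
        return self._V[: self.n_v]

    @viral_density.setter
    def viral_density(self, values: np.ndarray) -> None:
        self._V[: self.n_v] = values

    @property
    def match(self) -> np.ndarray:
        return self._M[: self.n_h, : self.n_v]

    # -- growth -----------------------------------------------------------

    def _grow(self, axis: int) -> None:
        if axis == 0:
            self._N = np.concatenate([self._N, np.zeros(len(self._N))])
            self._M = np.vstack([self._M, np.zeros_like(self._M)])
        else:
            self._V = np.concatenate([self._V, np.zeros(len(self._V))])
            self._M = np.hstack([self._M, np.zeros_like(self._M)])

    def add_host(self, spacers: tuple[int, ...], density: float) -> int:
        if self.n_h == len(self._N):
            self._grow(0)
        i = self.n_h
        self.n_h += 1
        self.host_ids.append(self.next_host_id)
        self.next_host_id += 1
        self.host_spacers.append(spacers)
        ss = frozenset(spacers)
        self.host_sets.append(ss)
        self._N[i] = density
        for k in range(self.n_v):
            vs = self.viral_sets[k]
            self._M[i, k] = float(vs is not None and not ss.isdisjoint(vs))
        return i

    def add_virus(self, proto: tuple[int, ...], density: float) -> int:
        if self.n_v == len(self._V):
            self._grow(1)
        k = self.n_v
        self.n_v += 1
        self.viral_ids.append(self.next_viral_id)
        self.next_viral_id += 1
        self.viral_protospacers.append(proto)
        ps = frozenset(proto)
        self.viral_sets.append(ps)
        self._V[k] = density
        for i in range(self.n_h):
            hs = self.host_sets[i]
            self._M[i, k] = float(hs is not None and not ps.isdisjoint(hs))
        return k

    def prune(self, cutoff: float) -> None:
        """Tombstone strains below the cutoff; compact buffers when 25% dead."""
        for i in np.flatnonzero(self._N[: self.n_h] < cutoff):
            if self.host_spacers[i] is not None:
                self._N[i] = 0.0
                self.host_spacers[i] = None
                self.host_sets[i] = None
                self.dead_h += 1
        for k in np.flatnonzero(self._V[: self.n_v] < cutoff):
            if self.viral_protospacers[k] is not None:
                self._V[k] = 0.0
                self.viral_protospacers[k] = None
                self.viral_sets[k] = None
                self.dead_v += 1
        if self.dead_h > 8 and 4 * self.dead_h > self.n_h:
            keep = [i for i in range(self.n_h) if self.host_spacers[i] is not None]
            self.host_ids = [self.host_ids[i] for i in keep]
            self.host_spacers = [self.host_spacers[i] for i in keep]
            self.host_sets = [self.host_sets[i] for i in keep]
            self._N[: len(keep)] = self._N[keep]
            self._N[len(keep): self.n_h] = 0.0
            self._M[: len(keep), : self.n_v] = self._M[keep, : self.n_v]
            self.n_h = len(keep)
            self.dead_h = 0
        if self.dead_v > 8 and 4 * self.dead_v > self.n_v:
            keep = [k for k in range(self.n_v)
                    if self.viral_protospacers[k] is not None]
            self.viral_ids = [self.viral_ids[k] for k in keep]
            self.viral_protospacers = [self.viral_protospacers[k] for k in keep]
            self.viral_sets = [self.viral_sets[k] for k in keep]
            self._V[: len(keep)] = self._V[keep]
            self._V[len(keep): self.n_v] = 0.0
            self._M[: self.n_h, : len(keep)] = self._M[: self.n_h, keep]
            self.n_v = len(keep)
            self.dead_v = 0

    def alive_hosts(self) -> list[int]:
        return [i for i in range(self.n_h) if self.host_spacers[i] is not None]

    def alive_viruses(self) -> list[int]:
        return [k for k in range(self.n_v)
                if self.viral_protospacers[k] is not None]

    @classmethod
    def initial(cls, params: SimParams) -> "SimState":
        """One naive host (empty locus), one virus with P distinct alleles."""
        return cls(params)


@dataclass
class Snapshot:
    time: float
    host_density: dict[int, float]
    viral_density: dict[int, float]
    all_loci_full: bool


@dataclass
class TrajectoryRecord:
    """Recorded output of one simulation run."""

    params: SimParams
    snapshots: list[Snapshot]
    host_registry: dict[int, tuple[int, ...]]
    viral_registry: dict[int, tuple[int, ...]]
    outcome: str                      # completed | viral_extinction | host_extinction
    locus_filled_in_window: bool
    filled_before_end: bool           # loci were ever all-full while virus alive
    n_acquisitions: int
    n_mutations: int

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.snapshots])

    @property
    def host_totals(self) -> np.ndarray:
        return np.array([sum(s.host_density.values()) for s in self.snapshots])

    @property
    def viral_totals(self) -> np.ndarray:
        return np.array([sum(s.viral_density.values()) for s in self.snapshots])

    def host_strain_counts(self) -> np.ndarray:
        return np.array([len(s.host_density) for s in self.snapshots])

    def viral_strain_counts(self) -> np.ndarray:
        return np.array([len(s.viral_density) for s in self.snapshots])

    def community_at(self, index: int) -> Community:
        """Build a normalized Community from the snapshot at ``index``."""
        snap = self.snapshots[index]
        hosts = [
            HostStrain(i, self.host_registry[i], density=d)
            for i, d in snap.host_density.items()
        ]
        viruses = [
            ViralStrain(k, self.viral_registry[k], density=d)
            for k, d in snap.viral_density.items()
        ]
        return normalize_community(hosts, viruses, time=snap.time)


def ecological_derivatives(
    host_density: np.ndarray,
    viral_density: np.ndarray,
    match: np.ndarray,
    p: SimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-strain density derivatives at the current strain composition.

    With effective susceptibility s_ik = (1 - m_ik) + m_ik * f:

        dN_i/dt = r N_i (1 - sum(N)/K) - (1-q) phi N_i sum_k V_k s_ik
        dV_k/dt = beta (1-q) phi V_k sum_i N_i s_ik - phi V_k sum(N) - m_v V_k

    Only vulnerable, non-acquiring hosts lyse; every adsorption removes a
    virion regardless of outcome. Because s = 1 - (1-f) m, the susceptibility
    sums reduce to totals minus (1-f) times match-matrix products, so the
    susceptibility matrix is never materialized.
    """
    n_tot = host_density.sum()
    v_tot = viral_density.sum()
    if match.dtype == np.float32:
        # match entries are exactly 0/1; single-precision products keep the
        # infection sums accurate to ~1e-6 relative at half the memory traffic
        mv = (match @ viral_density.astype(np.float32)).astype(np.float64)
        mn = (match.T @ host_density.astype(np.float32)).astype(np.float64)
    else:
        mv = match @ viral_density
        mn = match.T @ host_density
    sv = v_tot - (1.0 - p.f) * mv
    sn = n_tot - (1.0 - p.f) * mn
    dN = (
        p.r * host_density * (1.0 - n_tot / p.K)
        - (1.0 - p.q) * p.phi * host_density * sv
    )
    dV = (
        p.beta * (1.0 - p.q) * p.phi * viral_density * sn
        - p.phi * viral_density * n_tot
        - p.m_v * viral_density
    )
    return dN, dV


def _rk4(state: SimState, p: SimParams) -> None:
    N = state.host_density.copy()
    V = state.viral_density.copy()
    M = state.match
    dt = p.dt
    k1n, k1v = ecological_derivatives(N, V, M, p)
    k2n, k2v = ecological_derivatives(
        N + 0.5 * dt * k1n, V + 0.5 * dt * k1v, M, p)
    k3n, k3v = ecological_derivatives(
        N + 0.5 * dt * k2n, V + 0.5 * dt * k2v, M, p)
    k4n, k4v = ecological_derivatives(N + dt * k3n, V + dt * k3v, M, p)
    N_new = N + dt / 6.0 * (k1n + 2 * k2n + 2 * k3n + k4n)
    V_new = V + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    if np.any(N_new < 0) or np.any(V_new < 0):
        logger.warning(
            "negative density after RK4 step at t=%.2f; clipped to 0 "
            "(integration step too coarse)", state.time
        )
        np.clip(N_new, 0.0, None, out=N_new)
        np.clip(V_new, 0.0, None, out=V_new)
    state.host_density = N_new
    state.viral_density = V_new


def _acquire(state: SimState, i: int, k: int, p: SimParams, rng) -> None:
    """One spacer-acquisition founder event: host i copies a uniformly chosen
    protospacer allele of virus k to the leader end of its locus."""
    allele = state.viral_protospacers[k][rng.integers(p.P)]
    parent = state.host_spacers[i]
    if allele in parent:
        return  # locus already carries this allele
    new_locus = ((allele,) + parent)[: p.S]
    founder = min(1.0, float(state._N[i]))
    if founder <= 0:
        return
    state._N[i] -= founder
    try:
        j = state.host_spacers.index(new_locus)
        state._N[j] += founder  # merge into existing genotype
    except ValueError:
        state.add_host(new_locus, founder)
    state.n_acquisitions += 1


def _mutate(state: SimState, k: int, p: SimParams, rng) -> None:
    """One protospacer-mutation founder event: a new virion of strain k carries
    a globally novel allele at a uniformly chosen position."""
    founder = min(1.0, float(state._V[k]))
    if founder <= 0:
        return
    pos = int(rng.integers(p.P))
    proto = list(state.viral_protospacers[k])
    proto[pos] = state.next_allele
    state.next_allele += 1
    state._V[k] -= founder
    state.add_virus(tuple(proto), founder)
    state.n_mutations += 1


def step(state: SimState, p: SimParams, rng: np.random.Generator) -> SimState:
    """Advance the state by one dt: RK4 ecology, then stochastic evolution.

    Acquisition events arrive at total rate q phi N_tot V_tot; because the
    per-pair rate factorizes as q phi N_i V_k, each event is attributed to a
    (host, virus) pair drawn proportionally to N_i and V_k. Mutation events
    arrive per viral strain at rate mu P beta (1-q) phi V_k sum_i N_i s_ik
    (mutants per new virion produced). Strains below the density cutoff are
    pruned after events are applied.
    """
    _rk4(state, p)
    state.time += p.dt

    N = state.host_density
    V = state.viral_density
    n_tot, v_tot = N.sum(), V.sum()

    if p.q > 0 and n_tot > 0 and v_tot > 0:
        total_rate = p.q * p.phi * n_tot * v_tot * p.dt
        n_events = rng.poisson(total_rate)
        if n_events:
            hi = rng.choice(state.n_h, size=n_events, p=N / n_tot)
            vi = rng.choice(state.n_v, size=n_events, p=V / v_tot)
            for i, k in zip(hi, vi):
                _acquire(state, int(i), int(k), p, rng)

    if p.mu > 0:
        N = state.host_density
        V = state.viral_density
        if V.sum() > 0 and N.sum() > 0:
            M = state.match
            mn = (M.T @ N.astype(np.float32)).astype(np.float64) \
                if M.dtype == np.float32 else M.T @ N
            sn = N.sum() - (1.0 - p.f) * mn
            production = p.beta * (1.0 - p.q) * p.phi * V * sn
            rates = p.mu * p.P * production * p.dt
            total = rates.sum()
            if total > 0:
                n_events = rng.poisson(total)
                if n_events:
                    ks = rng.choice(len(rates), size=n_events, p=rates / total)
                    for k in ks:
                        _mutate(state, int(k), p, rng)

    state.prune(p.cutoff)
    return state


def run_simulation(params: SimParams, rng: np.random.Generator | None = None
                   ) -> TrajectoryRecord:
    """Run one simulation from a naive host and a single viral strain.

    Stops at t_end, or earlier when one side's total density falls below the
    extinction cutoff. Snapshots are recorded every ``record_every`` hours.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = SimState.initial(params)
    snapshots: list[Snapshot] = []
    host_registry: dict[int, tuple[int, ...]] = {}
    viral_registry: dict[int, tuple[int, ...]] = {}
    filled_before_end = False
    outcome = "completed"

    def record() -> None:
        nonlocal filled_before_end
        alive_h = state.alive_hosts()
        alive_v = state.alive_viruses()
        for i in alive_h:
            host_registry.setdefault(state.host_ids[i], state.host_spacers[i])
        for k in alive_v:
            viral_registry.setdefault(
                state.viral_ids[k], state.viral_protospacers[k])
        all_full = len(alive_h) > 0 and all(
            len(state.host_spacers[i]) == params.S for i in alive_h
        )
        if all_full and state.viral_density.sum() >= params.cutoff:
            filled_before_end = True
        snapshots.append(
            Snapshot(
                time=state.time,
                host_density={
                    state.host_ids[i]: float(state._N[i]) for i in alive_h
                },
                viral_density={
                    state.viral_ids[k]: float(state._V[k]) for k in alive_v
                },
                all_loci_full=all_full,
            )
        )

    record()
    steps_per_record = max(1, round(params.record_every / params.dt))
    n_steps = 0
    while state.time < params.t_end - 1e-9:
        step(state, params, rng)
        n_steps += 1
        if n_steps % steps_per_record == 0:
            record()
        if state.viral_density.sum() < params.cutoff:
            outcome = "viral_extinction"
            break
        if state.host_density.sum() < params.cutoff:
            outcome = "host_extinction"
            break
    if not snapshots or snapshots[-1].time < state.time - 1e-9:
        record()

    window_start = params.t_end - 500.0
    in_window = [s for s in snapshots if s.time > window_start]
    locus_filled = (
        outcome == "completed"
        and len(in_window) > 0
        and all(s.all_loci_full for s in in_window)
    )
    return TrajectoryRecord(
        params=params,
        snapshots=snapshots,
        host_registry=host_registry,
        viral_registry=viral_registry,
        outcome=outcome,
        locus_filled_in_window=locus_filled,
        filled_before_end=filled_before_end,
        n_acquisitions=state.n_acquisitions,
        n_mutations=state.n_mutations,
    )
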