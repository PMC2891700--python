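"""Replica exchange: exponential ladders, Metropolis swaps, bookkeeping.

Swaps exchange temperatures between neighbouring replicas (velocities are
rescaled by sqrt(T_new/T_old)); neighbour pairs are attempted in alternating
even/odd sweeps at a fixed attempt interval measured in MD steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from .units import KB


class RemdError(ValueError):
    pass


@dataclass(frozen=True)
class TemperatureLadder:
    temperatures: tuple

    def __post_init__(self):
        t = np.asarray(self.temperatures)
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise RemdError("ladder must be >= 2 strictly increasing temperatures")

    def __len__(self):
        return len(self.temperatures)

    def __getitem__(self, i):
        return self.temperatures[i]


def make_ladder(n: int, T_min: float = 100.0, T_max: float = 700.0) -> TemperatureLadder:
    """Exponential spacing: T_i = T_min (T_max/T_min)^(i/(n-1))."""
    if n < 2:
        raise RemdError("need at least 2 replicas")
    if not 0 < T_min < T_max:
        raise RemdError("need 0 < T_min < T_max")
    i = np.arange(n)
    T = T_min * (T_max / T_min) ** (i / (n - 1))
    T[0], T[-1] = T_min, T_max   # pin endpoints exactly
    return TemperatureLadder(tuple(T))


def attempt_exchange(U_i: float, U_j: float, T_i: float, T_j: float,
                     rng) -> bool:
    """Metropolis criterion for swapping configurations between T_i < T_j.

    Accept with probability min{1, exp[(1/kT_i - 1/kT_j)(U_i - U_j)]}.
    """
    delta = (1.0 / (KB * T_i) - 1.0 / (KB * T_j)) * (U_i - U_j)
    if delta >= 0:
        return True
    return rng.random() < np.exp(delta)


class ReplicaWalker(Protocol):
    """Minimal interface REMD needs from a per-replica sampler."""

    def propagate(self, state, T: float, n_steps: int, rng): ...
    def energy(self, state) -> float: ...
    def rescale_velocities(self, state, factor: float): ...
    def snapshot(self, state): ...


@dataclass
class ExchangeRecord:
    step: int
    slot_pair: tuple        # (lower temperature slot, upper slot)
    replicas: tuple         # replica ids occupying the slots at attempt time
    accepted: bool


@dataclass
class ReplicaEnsemble:
    ladder: TemperatureLadder
    energies: list                  # per temperature slot: list of energies
    snapshots: list                 # per slot: list of recorded snapshots
    exchange_records: list
    occupancy: list                 # per record interval: replica->slot perm
    attempts: dict = field(default_factory=dict)
    accepts: dict = field(default_factory=dict)

    def acceptance_rates(self):
        out = {}
        for pair, n in self.attempts.items():
            out[pair] = (self.accepts.get(pair, 0) / n) if n else None
        return out


def run_remd(walker: ReplicaWalker, initial_states, ladder: TemperatureLadder,
             n_steps: int, exchange_interval: int, record_interval: int,
             seed: int = 0) -> ReplicaEnsemble:
    """Sequential REMD driver.

    initial_states: one state per replica (replica r starts in slot r).
    Exchange attempts sweep even neighbour pairs, then odd, alternating per
    attempt.  Snapshots/energies are recorded per temperature slot.
    """
    n_rep = len(ladder)
    states = [walker.snapshot(s) for s in initial_states]
    if len(states) != n_rep:
        raise RemdError("one initial state per replica required")
    rngs = [np.random.default_rng([seed, r]) for r in range(n_rep)]
    swap_rng = np.random.default_rng([seed, 10 ** 6])

    slot_of = list(range(n_rep))        # replica -> temperature slot
    rep_at = list(range(n_rep))         # slot -> replica
    energies = [[] for _ in range(n_rep)]
    snapshots = [[] for _ in range(n_rep)]
    records = []
    occupancy = []
    attempts, accepts = {}, {}
    sweep_parity = 0

    step = 0
    while step < n_steps:
        chunk = min(exchange_interval, n_steps - step)
        for r in range(n_rep):
            states[r] = walker.propagate(states[r], ladder[slot_of[r]], chunk,
                                         rngs[r])
        step += chunk

        if step % record_interval == 0 or step == n_steps:
            for slot in range(n_rep):
                r = rep_at[slot]
                energies[slot].append(walker.energy(states[r]))
                snapshots[slot].append(walker.snapshot(states[r]))
            occupancy.append(tuple(rep_at))

        if chunk == exchange_interval and step < n_steps:
            start = sweep_parity % 2
            for lo in range(start, n_rep - 1, 2):
                hi = lo + 1
                ri, rj = rep_at[lo], rep_at[hi]
                U_i, U_j = walker.energy(states[ri]), walker.energy(states[rj])
                T_i, T_j = ladder[lo], ladder[hi]
                ok = attempt_exchange(U_i, U_j, T_i, T_j, swap_rng)
                pair = (lo, hi)
                attempts[pair] = attempts.get(pair, 0) + 1
                if ok:
                    accepts[pair] = accepts.get(pair, 0) + 1
                    states[ri] = walker.rescale_velocities(
                        states[ri], np.sqrt(T_j / T_i))
                    states[rj] = walker.rescale_velocities(
                        states[rj], np.sqrt(T_i / T_j))
                    rep_at[lo], rep_at[hi] = rj, ri
                    slot_of[ri], slot_of[rj] = hi, lo
                records.append(ExchangeRecord(step, pair, (ri, rj), ok))
            sweep_parity += 1

    return ReplicaEnsemble(ladder, energies, snapshots, records, occupancy,
                           attempts, accepts)


@dataclass
class AcceptanceReport:
    rates: dict
    flagged: dict           # pair -> "low" | "high"
    band: tuple

    def __str__(self):
        lines = [f"# acceptance band {self.band[0]:.2f}-{self.band[1]:.2f}"]
        for pair in sorted(self.rates):
            rate = self.rates[pair]
            tag = self.flagged.get(pair, "")
            txt = "undefined" if rate is None else f"{rate:.3f}"
            lines.append(f"slots {pair[0]}-{pair[1]}: {txt} {tag}".rstrip())
        return "\n".join(lines)


def acceptance_report(ensemble: ReplicaEnsemble,
                      band=(0.2, 0.4)) -> AcceptanceReport:
    rates = ensemble.acceptance_rates()
    flagged = {}
    for pair, rate in rates.items():
        if rate is None:
            continue
        if rate < band[0]:
            flagged[pair] = "low"
        elif rate > band[1]:
            flagged[pair] = "high"
    return AcceptanceReport(rates, flagged, tuple(band))


class MDWalker:
    """Adapter running cgfold.simulate systems under the REMD driver."""

    def __init__(self, system, steps_stride: int = 1):
        from . import simulate as _sim
        self._sim = _sim
        self.system = system

    def propagate(self, state, T, n_steps, rng):
        for _ in range(n_steps):
            self._sim.langevin_step(self.system, state, rng, temperature=T)
        return state

    def energy(self, state):
        return state.energies["potential"]

    def rescale_velocities(self, state, factor):
        state.velocities = state.velocities * factor
        return state

    def snapshot(self, state):
        import copy
        s = copy.copy(state)
        s.positions = state.positions.copy()
        s.velocities = state.velocities.copy()
        s.forces = None if state.forces is None else state.forces.copy()
        s.energies = dict(state.energies)
        return s
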