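"""Exact stochastic simulation (Gillespie direct method).

The engine draws statistically exact event sequences for any
:class:`~litrswitch.network.ReactionNetwork` and records the state on a
fixed time grid (the sample at time ``t`` is the state immediately after the
last event at or before ``t``).  Two execution paths share identical
semantics and an identical PCG32 random stream:

* a numba-compiled core for pure mass-action networks (the LITR circuit at
  full length runs tens of millions of events), and
* a Python core used when any reaction carries a custom propensity
  (e.g. the square-root birth rates of the reduced toggle model).

Runs are reproducible: the same seed and network give byte-identical sampled
output, and a run checkpoint (state + generator state) lets
:func:`resume` extend a trajectory so that split runs concatenate bitwise
equal to a single long run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from .network import CompiledNetwork, ReactionNetwork

__all__ = ["Trajectory", "simulate", "resume"]

_PCG_MULT = np.uint64(6364136223846793005)
_PCG_INC = np.uint64(1442695040888963407)  # fixed odd stream increment
_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True)
def _pcg32_next(state):
    old = state[0]
    state[0] = old * _PCG_MULT + np.uint64(_PCG_INC)
    xorshifted = np.uint32(((old >> np.uint64(18)) ^ old) >> np.uint64(27))
    rot = np.uint32(old >> np.uint64(59))
    return np.uint32((xorshifted >> rot) | (xorshifted << ((-rot) & np.uint32(31))))


@njit(cache=True)
def _pcg32_uniform(state):
    hi = np.uint64(_pcg32_next(state)) >> np.uint64(5)   # 27 bits
    lo = np.uint64(_pcg32_next(state)) >> np.uint64(6)   # 26 bits
    u = (float(hi) * 67108864.0 + float(lo)) * 1.1102230246251565e-16
    if u <= 0.0:
        u = 1.1102230246251565e-16
    return u


def _pcg32_seed_state(seed: int) -> np.ndarray:
    state = np.zeros(1, dtype=np.uint64)
    state[0] = np.uint64(0)
    _seed_step(state, np.uint64(seed & 0xFFFFFFFFFFFFFFFF))
    return state


@njit(cache=True)
def _seed_step(state, seed):
    state[0] = np.uint64(0)
    _pcg32_next(state)
    state[0] = state[0] + seed
    _pcg32_next(state)


@njit(cache=True)
def _ssa_mass_action(counts, order, r0, r1, rate_eff, net, t, t_end,
                     sample_dt, j_start, samples, state):
    """Direct-method loop; returns (t_last_event, next_sample, absorbed)."""
    n_rxn = order.shape[0]
    j_max = samples.shape[0] - 1
    j = j_start
    while True:
        a_tot = 0.0
        for m in range(n_rxn):
            o = order[m]
            if o == 0:
                a = rate_eff[m]
            elif o == 1:
                a = rate_eff[m] * counts[r0[m]]
            else:
                i0 = r0[m]
                i1 = r1[m]
                if i0 == i1:
                    a = rate_eff[m] * counts[i0] * (counts[i0] - 1)
                else:
                    a = rate_eff[m] * counts[i0] * counts[i1]
            if a < 0.0:
                a = 0.0
            a_tot += a
        if a_tot <= 0.0:
            while j <= j_max:
                for s in range(counts.shape[0]):
                    samples[j, s] = counts[s]
                j += 1
            return t, j, True
        s_save = state[0]
        u1 = _pcg32_uniform(state)
        tau = -np.log(u1) / a_tot
        t_next = t + tau
        while j <= j_max and j * sample_dt < t_next:
            for s in range(counts.shape[0]):
                samples[j, s] = counts[s]
            j += 1
        if t_next > t_end:
            state[0] = s_save
            return t, j, False
        # select reaction by recomputing the cumulative propensity
        u2 = _pcg32_uniform(state) * a_tot
        acc = 0.0
        chosen = n_rxn - 1
        for m in range(n_rxn):
            o = order[m]
            if o == 0:
                a = rate_eff[m]
            elif o == 1:
                a = rate_eff[m] * counts[r0[m]]
            else:
                i0 = r0[m]
                i1 = r1[m]
                if i0 == i1:
                    a = rate_eff[m] * counts[i0] * (counts[i0] - 1)
                else:
                    a = rate_eff[m] * counts[i0] * counts[i1]
            if a < 0.0:
                a = 0.0
            acc += a
            if u2 <= acc:
                chosen = m
                break
        for s in range(counts.shape[0]):
            counts[s] += net[chosen, s]
        t = t_next


class _PCG32Py:
    """Python twin of the numba PCG32 (identical stream for a given seed)."""

    __slots__ = ("state",)
    MASK = (1 << 64) - 1

    def __init__(self, seed: int | None = None, state: int | None = None):
        if state is not None:
            self.state = state & self.MASK
        else:
            self.state = 0
            self._next()
            self.state = (self.state + (seed & self.MASK)) & self.MASK
            self._next()

    def _next(self) -> int:
        old = self.state
        self.state = (old * 6364136223846793005 + 1442695040888963407) & self.MASK
        xorshifted = ((old >> 18) ^ old) >> 27 & 0xFFFFFFFF
        rot = old >> 59
        return ((xorshifted >> rot) | (xorshifted << ((-rot) & 31))) & 0xFFFFFFFF

    def uniform(self) -> float:
        hi = self._next() >> 5
        lo = self._next() >> 6
        u = (hi * 67108864.0 + lo) * 1.1102230246251565e-16
        return u if u > 0.0 else 1.1102230246251565e-16


def _propensities_py(compiled: CompiledNetwork, counts: np.ndarray) -> np.ndarray:
    a = np.zeros(len(compiled.order))
    for m in range(len(compiled.order)):
        fn = compiled.custom[m]
        if fn is not None:
            a[m] = max(fn(counts), 0.0)
            continue
        o = compiled.order[m]
        if o == 0:
            a[m] = compiled.rate_eff[m]
        elif o == 1:
            a[m] = compiled.rate_eff[m] * counts[compiled.r0[m]]
        else:
            i0, i1 = compiled.r0[m], compiled.r1[m]
            if i0 == i1:
                a[m] = compiled.rate_eff[m] * counts[i0] * (counts[i0] - 1)
            else:
                a[m] = compiled.rate_eff[m] * counts[i0] * counts[i1]
    return a


def _ssa_python(compiled: CompiledNetwork, counts, t, t_end, sample_dt,
                j_start, samples, rng: _PCG32Py):
    j_max = samples.shape[0] - 1
    j = j_start
    while True:
        a = _propensities_py(compiled, counts)
        a_tot = float(a.sum())
        if a_tot <= 0.0:
            while j <= j_max:
                samples[j] = counts
                j += 1
            return t, j, True
        s_save = rng.state
        tau = -np.log(rng.uniform()) / a_tot
        t_next = t + tau
        while j <= j_max and j * sample_dt < t_next:
            samples[j] = counts
            j += 1
        if t_next > t_end:
            rng.state = s_save
            return t, j, False
        u2 = rng.uniform() * a_tot
        chosen = int(np.searchsorted(np.cumsum(a), u2))
        chosen = min(chosen, len(a) - 1)
        counts += compiled.net[chosen]
        t = t_next


@dataclass
class Trajectory:
    """Fixed-interval sampled SSA realization with a resume checkpoint."""

    sample_times: np.ndarray
    counts: np.ndarray               # (n_samples, n_species) int64
    species: list[str]
    seed: int
    sample_dt: float
    t_end: float
    network: ReactionNetwork
    absorbed: bool = False
    checkpoint: dict = field(default_factory=dict)

    def species_series(self, name: str) -> np.ndarray:
        return self.counts[:, self.species.index(name)]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.counts, columns=self.species)
        df.insert(0, "time_s", self.sample_times)
        return df

    def conservation_ok(self, rtol: float = 0.0) -> bool:
        compiled = self.network.compile()
        if compiled.cons_matrix.shape[0] == 0:
            return True
        totals = self.counts @ compiled.cons_matrix.T
        expected = compiled.cons_totals[None, :]
        return bool(np.all(np.abs(totals - expected) <= rtol * np.abs(expected)))


def simulate(network: ReactionNetwork, t_end: float, sample_dt: float,
             seed: int) -> Trajectory:
    """Run the direct-method SSA and sample every ``sample_dt`` seconds.

    Sample times are 0, dt, ..., floor(t_end/dt)*dt; the recorded state at a
    sample time is the state after the last event at or before it.  If every
    propensity vanishes the remaining samples are padded with the absorbed
    state and the trajectory flagged.
    """
    if t_end <= 0 or sample_dt <= 0:
        raise ValueError("t_end and sample_dt must be positive")
    compiled = network.compile()
    n_samples = int(np.floor(t_end / sample_dt + 1e-12)) + 1
    samples = np.zeros((n_samples, len(compiled.species)), dtype=np.int64)
    counts = compiled.initial.copy()
    if compiled.has_custom:
        rng = _PCG32Py(seed=seed)
        t_last, j, absorbed = _ssa_python(compiled, counts, 0.0, float(t_end),
                                          float(sample_dt), 0, samples, rng)
        rng_state = rng.state
    else:
        state = _pcg32_seed_state(seed)
        t_last, j, absorbed = _ssa_mass_action(
            counts, compiled.order, compiled.r0, compiled.r1,
            compiled.rate_eff, compiled.net, 0.0, float(t_end),
            float(sample_dt), 0, samples, state)
        rng_state = int(state[0])
    times = np.arange(n_samples) * sample_dt
    return Trajectory(
        sample_times=times, counts=samples, species=list(compiled.species),
        seed=seed, sample_dt=sample_dt, t_end=float(t_end), network=network,
        absorbed=absorbed,
        checkpoint={"counts": counts.copy(), "t": float(t_last),
                    "rng_state": rng_state, "next_sample": int(j)})


def resume(trajectory: Trajectory, extra_time: float) -> Trajectory:
    """Extend a trajectory; the result equals a single run of the full span.

    Requires the checkpoint produced by :func:`simulate`; the generator
    state stored there makes the continuation bitwise identical to an
    unsplit run with the same seed.
    """
    if extra_time < 0:
        raise ValueError("extra_time must be non-negative")
    if not trajectory.checkpoint:
        raise ValueError("trajectory carries no checkpoint; cannot resume")
    if extra_time == 0:
        return trajectory
    compiled = trajectory.network.compile()
    new_t_end = trajectory.t_end + extra_time
    dt = trajectory.sample_dt
    n_samples = int(np.floor(new_t_end / dt + 1e-12)) + 1
    samples = np.zeros((n_samples, len(compiled.species)), dtype=np.int64)
    n_old = trajectory.counts.shape[0]
    samples[:n_old] = trajectory.counts
    counts = trajectory.checkpoint["counts"].copy()
    j0 = trajectory.checkpoint["next_sample"]
    t0 = trajectory.checkpoint["t"]
    if trajectory.absorbed:
        samples[n_old:] = counts
        t_last, j, absorbed, rng_state = t0, n_samples, True, \
            trajectory.checkpoint["rng_state"]
    elif compiled.has_custom:
        rng = _PCG32Py(state=trajectory.checkpoint["rng_state"])
        t_last, j, absorbed = _ssa_python(compiled, counts, t0, float(new_t_end),
                                          float(dt), j0, samples, rng)
        rng_state = rng.state
    else:
        state = np.zeros(1, dtype=np.uint64)
        state[0] = np.uint64(trajectory.checkpoint["rng_state"])
        t_last, j, absorbed = _ssa_mass_action(
            counts, compiled.order, compiled.r0, compiled.r1,
            compiled.rate_eff, compiled.net, t0, float(new_t_end),
            float(dt), j0, samples, state)
        rng_state = int(state[0])
    times = np.arange(n_samples) * dt
    return Trajectory(
        sample_times=times, counts=samples, species=trajectory.species,
        seed=trajectory.seed, sample_dt=dt, t_end=float(new_t_end),
        network=trajectory.network, absorbed=absorbed,
        checkpoint={"counts": counts.copy(), "t": float(t_last),
                    "rng_state": rng_state, "next_sample": int(j)})
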