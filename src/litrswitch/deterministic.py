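"""Mass-action ODE counterpart of a reaction network.

The deterministic limit of any :class:`~litrswitch.network.ReactionNetwork`
is dc/dt = S^T v(c) with classical mass-action fluxes (the large-volume
limit of the stochastic propensities: A+A fluxes go as c^2 rather than
n(n-1)).  State is carried in molecule-number units (counts per cell), so
the stochastic and deterministic descriptions share rate constants exactly;
conversions to nM go through the cell volume.

Steady states of the LacI-TetR circuit are found by long stiff integration
from an excess-LacI4 and an excess-TetR2 start (400 molecules each) plus a
multistart set, refined by Newton on the conservation-reduced system, and
classified by the eigenvalues of the reduced Jacobian.  Bistability of the
full circuit over the inducer plane ([IPTG] x [DOX]) gives the deterministic
counterpart of the stochastic stability maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .grid import PhaseGrid
from .network import (LITRConfig, ReactionNetwork, build_litr_network,
                      count_to_concentration)

__all__ = [
    "SteadyState",
    "network_to_odes",
    "find_steady_states",
    "find_litr_steady_states",
    "scan_litr_deterministic",
    "bistable_boundary_segments",
]


def network_to_odes(network: ReactionNetwork
                    ) -> tuple[Callable[[float, np.ndarray], np.ndarray],
                               Callable[[float, np.ndarray], np.ndarray]]:
    """Deterministic rate function and analytic Jacobian for a network.

    Returns ``(rhs, jac)`` over molecule-number state vectors; constant
    (chemostatted) species have zero derivative and enter fluxes at their
    fixed value.  Custom-propensity reactions are not supported here.
    """
    compiled = network.compile()
    if compiled.has_custom:
        raise ValueError("deterministic limit requires pure mass-action reactions")
    order = compiled.order
    r0, r1 = compiled.r0, compiled.r1
    k = compiled.rate_eff.copy()
    # stochastic A+A rate includes the 1/2 pair factor; the classical flux
    # (c/2V) c^2 uses the same effective constant with c^2
    net = compiled.net.astype(float)
    n_rxn = len(order)

    def flux(c: np.ndarray) -> np.ndarray:
        v = np.empty(n_rxn)
        for m in range(n_rxn):
            if order[m] == 0:
                v[m] = k[m]
            elif order[m] == 1:
                v[m] = k[m] * c[r0[m]]
            else:
                v[m] = k[m] * c[r0[m]] * c[r1[m]]
        return v

    def rhs(t: float, c: np.ndarray) -> np.ndarray:
        return flux(c) @ net

    def jac(t: float, c: np.ndarray) -> np.ndarray:
        S = len(c)
        dv = np.zeros((n_rxn, S))
        for m in range(n_rxn):
            if order[m] == 1:
                dv[m, r0[m]] += k[m]
            elif order[m] == 2:
                dv[m, r0[m]] += k[m] * c[r1[m]]
                dv[m, r1[m]] += k[m] * c[r0[m]]
        return net.T @ dv

    return rhs, jac


@dataclass
class SteadyState:
    """A steady state of the deterministic network in nM units."""

    species: list[str]
    concentrations_nm: np.ndarray
    counts: np.ndarray              # same state in molecule numbers
    stable: bool
    basin: str                      # which initial condition reached it
    residual: float                 # max |dc/dt| in molecules/s after refinement

    def __getitem__(self, name: str) -> float:
        return float(self.concentrations_nm[self.species.index(name)])

    def count(self, name: str) -> float:
        return float(self.counts[self.species.index(name)])


def _reduce_conservation(compiled):
    """Pick one eliminated species per conservation law (unit coefficient)."""
    eliminated = []
    for i in range(compiled.cons_matrix.shape[0]):
        idx = np.flatnonzero(compiled.cons_matrix[i] == 1)
        choice = next(int(j) for j in idx if j not in eliminated)
        eliminated.append(choice)
    return eliminated


def find_steady_states(network: ReactionNetwork,
                       initial_states: Sequence[tuple[str, np.ndarray]],
                       t_relax: float = 1e8,
                       dedup_rtol: float = 0.01,
                       distinct_key: tuple[str, str] | None = None,
                       residual_tol: float = 1e-6) -> list[SteadyState]:
    """Relax each initial state to a steady state and classify stability.

    Integration uses a stiff (BDF) solver with the analytic Jacobian; the end
    point is refined by Newton on the conservation-reduced system so that
    conserved totals stay pinned.  States are deduplicated at relative
    distance ``dedup_rtol``; if ``distinct_key`` names two species, states
    whose count difference for that pair differs in sign are always kept
    distinct.  Non-convergent starts are dropped with a warning.
    """
    compiled = network.compile()
    rhs, jac = network_to_odes(network)
    eliminated = _reduce_conservation(compiled)
    free_idx = np.array([i for i in range(len(compiled.species))
                         if i not in eliminated and not compiled.is_constant[i]],
                        dtype=int)
    cons = compiled.cons_matrix
    totals = compiled.cons_totals

    def expand(y: np.ndarray, template: np.ndarray) -> np.ndarray:
        c = template.copy()
        c[free_idx] = y
        for law_i, el in enumerate(eliminated):
            other = cons[law_i].copy()
            other[el] = 0
            c[el] = totals[law_i] - float(other @ c)
        return c

    def reduced_rhs_fn(y: np.ndarray, template: np.ndarray) -> np.ndarray:
        return rhs(0.0, expand(y, template))[free_idx]

    results: list[SteadyState] = []
    for basin, c0 in initial_states:
        c0 = np.asarray(c0, dtype=float)
        sol = solve_ivp(rhs, (0.0, t_relax), c0, method="BDF", jac=jac,
                        rtol=1e-8, atol=1e-8)
        if not sol.success:
            warnings.warn(f"integration from start {basin!r} failed: {sol.message}",
                          RuntimeWarning, stacklevel=2)
            continue
        c_end = np.clip(sol.y[:, -1], 0.0, None)
        template = c_end.copy()
        res = root(lambda y: reduced_rhs_fn(y, template), c_end[free_idx],
                   method="hybr", tol=1e-12)
        c_star = expand(res.x, template) if res.success else c_end
        c_star = np.clip(c_star, 0.0, None)
        residual = float(np.max(np.abs(rhs(0.0, c_star))))
        if residual > residual_tol:
            warnings.warn(f"start {basin!r} did not reach a steady state "
                          f"(residual {residual:.2e})", RuntimeWarning,
                          stacklevel=2)
            continue
        # stability from the conservation-reduced Jacobian
        J_full = jac(0.0, c_star)
        # chain rule through the eliminated coordinates
        S_free = len(free_idx)
        dc_dy = np.zeros((len(c_star), S_free))
        dc_dy[free_idx, np.arange(S_free)] = 1.0
        for law_i, el in enumerate(eliminated):
            other = cons[law_i].astype(float)
            other[el] = 0.0
            dc_dy[el] = -other[free_idx]
        J_red = (J_full @ dc_dy)[free_idx, :]
        eig = np.linalg.eigvals(J_red)
        stable = bool(np.max(eig.real) < 0.0)
        conc = np.array([count_to_concentration(c_star[i], network.volume)
                         for i in range(len(c_star))])
        results.append(SteadyState(species=list(compiled.species),
                                   concentrations_nm=conc, counts=c_star,
                                   stable=stable, basin=basin,
                                   residual=residual))
    # deduplicate
    kept: list[SteadyState] = []
    for st in results:
        dup = False
        for other in kept:
            if distinct_key is not None:
                d1 = st.count(distinct_key[0]) - st.count(distinct_key[1])
                d2 = other.count(distinct_key[0]) - other.count(distinct_key[1])
                if np.sign(d1) != np.sign(d2) and (abs(d1) > 1 or abs(d2) > 1):
                    continue
            num = np.linalg.norm(st.counts - other.counts)
            den = 1.0 + np.linalg.norm(other.counts)
            if num / den < dedup_rtol:
                dup = True
                break
        if not dup:
            kept.append(st)
    return kept


def _litr_starts(network: ReactionNetwork, n_random: int, seed: int):
    """The two excess-repressor starts plus log-uniform random protein states."""
    base = network.initial_state().astype(float)
    i_laci4 = network.species_index("LacI4")
    i_tetr2 = network.species_index("TetR2")
    a = base.copy(); a[i_laci4] += 400.0
    b = base.copy(); b[i_tetr2] += 400.0
    starts = [("laci_high", a), ("tetr_high", b)]
    if n_random > 0:
        rng = np.random.default_rng(seed)
        protein_idx = [network.species_index(s) for s in
                       ("LacI", "LacI2", "LacI4", "TetR", "TetR2", "M_l", "M_t")]
        for m in range(n_random):
            c = base.copy()
            c[protein_idx] = 10 ** rng.uniform(-1.0, 3.0, size=len(protein_idx))
            starts.append((f"random_{m}", c))
    return starts


def find_litr_steady_states(config: LITRConfig,
                            n_random: int = 20,
                            seed: int = 20160606,
                            **kw) -> list[SteadyState]:
    """Deterministic steady states of the LacI-TetR circuit.

    Two states are reported as distinct when they differ in the sign of
    LacI4 - TetR2 or by more than 1 % relative distance; >= 2 stable states
    means the configuration is deterministically bistable.
    """
    network = build_litr_network(config)
    starts = _litr_starts(network, n_random, seed)
    return find_steady_states(network, starts,
                              distinct_key=("LacI4", "TetR2"), **kw)


def scan_litr_deterministic(iptg_values: Sequence[float],
                            dox_values: Sequence[float],
                            config: LITRConfig,
                            n_random: int = 4,
                            seed: int = 20160606) -> PhaseGrid:
    """Monostable/bistable classification over the inducer plane."""
    iptg_values = np.asarray(list(iptg_values), dtype=float)
    dox_values = np.asarray(list(dox_values), dtype=float)
    if np.any(iptg_values < 0) or np.any(dox_values < 0):
        raise ValueError("inducer concentrations must be non-negative")
    classes = np.empty((len(iptg_values), len(dox_values)), dtype=object)
    n_stable = np.zeros(classes.shape, dtype=int)
    from dataclasses import replace as _replace
    for i, iptg in enumerate(iptg_values):
        for j, dox in enumerate(dox_values):
            cfg = _replace(config, iptg=float(iptg), dox=float(dox))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    states = find_litr_steady_states(cfg, n_random=n_random,
                                                     seed=seed)
                ns = sum(s.stable for s in states)
                n_stable[i, j] = ns
                classes[i, j] = "bistable" if ns >= 2 else (
                    "monostable" if ns == 1 else "unknown")
            except Exception:
                classes[i, j] = "unknown"
    return PhaseGrid(axis1_name="iptg_nM", axis1_values=iptg_values,
                     axis2_name="dox_nM", axis2_values=dox_values,
                     classes=classes, n_stable=n_stable)


def bistable_boundary_segments(grid: PhaseGrid) -> list[dict]:
    """Grid-resolved boundary of the bistable region as edge-midpoint segments.

    Each segment separates a bistable cell from a non-bistable neighbour;
    coordinates are midpoints between adjacent grid values (suitable for a
    polyline overlay at the grid's resolution).
    """
    bi = grid.classes == "bistable"
    segs = []
    v1, v2 = grid.axis1_values, grid.axis2_values

    def mid(vals, k):
        return float(np.sqrt(vals[k] * vals[k + 1]) if vals[k] > 0
                     else 0.5 * (vals[k] + vals[k + 1]))

    for i in range(bi.shape[0]):
        for j in range(bi.shape[1]):
            if i + 1 < bi.shape[0] and bi[i, j] != bi[i + 1, j]:
                segs.append({"axis1": mid(v1, i), "axis2": float(v2[j]),
                             "orientation": "axis1"})
            if j + 1 < bi.shape[1] and bi[i, j] != bi[i, j + 1]:
                segs.append({"axis1": float(v1[i]), "axis2": mid(v2, j),
                             "orientation": "axis2"})
    return segs
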