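"""Reduced two-variable model of the asymmetric genetic toggle switch.

Under the adiabatic approximation (DNA binding, dimerization and transcript
elongation equilibrate fast relative to protein turnover) the full two-gene
mutual-repression circuit collapses to two coupled ODEs for the
dimensionless active-repressor (homodimer) levels T_1, T_2:

    dT_l/dtau = 2*sqrt(theta_l*T_l) * lambda_l *
                (1 + nu_l / (1 + mu_l*T_e*(1 + r_l*T_e)))
                - 2*(T_l + (2/(kappa_l*sqrt(theta_l))) * T_l^{3/2})

with e the opposing gene and tau = t*gamma_p the time in units of the
protein dilution rate.  The first (synthesis) term is proportional to
sqrt(T) because dimers form from monomers in fast equilibrium; the second
(decay) term collects dimer and monomer degradation.  The gene-level inputs
are the promoter leakage s, the scaled RNAp-promoter dissociation u, the
expression efficiency beta (1/nM), the operator cooperativity r, the
monomer/dimer lifetime ratio sigma and the dissociation constants K1
(dimerization) and K2 (repressor-operator), which map onto the composite
parameters

    mu = (s+u)/(1+u),   nu = u(1-s)/(s(1+u)),   lambda = beta/(1+u/s),
    theta = K2/K1,      kappa = sigma/theta.

This module provides that parameterization, deterministic fixed-point and
stability analysis, phase-plane scans over (s, beta), and a birth-death
stochastic discretization of the reduced dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .derive import ReducedParamTable
from .grid import PhaseGrid
from .network import ReactionDef, ReactionNetwork, SpeciesDef

__all__ = [
    "ReducedGeneParams",
    "ReducedDerivedParams",
    "FixedPoint",
    "derive_dimensionless",
    "reduced_rhs",
    "reduced_jacobian",
    "find_fixed_points",
    "classify_reduced",
    "scan_phase_plane",
    "reduced_birth_death_network",
]

#: states with max(T1, T2) below this are the degenerate origin and excluded
ORIGIN_TOL = 1e-6


@dataclass(frozen=True)
class ReducedGeneParams:
    """Raw per-gene parameters of the reduced model."""

    s: float        # promoter leakage (fraction of full-activity binding)
    u: float        # RNAp-promoter dissociation scaled by [R]
    beta: float     # gene expression efficiency, 1/nM
    r: float        # repressor-operator binding cooperativity
    sigma: float    # monomer-to-dimer lifetime ratio
    K1: float       # dimerization dissociation constant, nM
    K2: float       # repressor-operator dissociation constant, nM

    def __post_init__(self):
        for name in ("s", "u", "beta", "r", "sigma", "K1", "K2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, "
                                 f"got {getattr(self, name)}")
        if self.s > 1:
            raise ValueError(f"leakage s must be <= 1, got {self.s}")

    def replace(self, **kw) -> "ReducedGeneParams":
        from dataclasses import replace as _replace
        return _replace(self, **kw)

    @classmethod
    def reference(cls) -> "ReducedGeneParams":
        """Bistable reference parameter point (lambda-CI based table)."""
        t = ReducedParamTable.default()
        return cls(s=t["s"], u=t["u"], beta=t["beta"], r=t["r"],
                   sigma=t["sigma"], K1=t["K1"], K2=t["K2"])


@dataclass(frozen=True)
class ReducedDerivedParams:
    """Composite dimensionless parameters entering the reduced ODEs.

    ``r`` is carried through unchanged because the repression denominator
    needs it alongside mu and nu.
    """

    mu: float       # repression saturation, in (0, 1] for s <= 1
    nu: float       # repression depth; 0 iff s = 1
    lam: float      # constitutive synthesis at full repression
    theta: float    # K2/K1
    kappa: float    # sigma/theta
    r: float        # cooperativity, passed through


def derive_dimensionless(gene: ReducedGeneParams) -> ReducedDerivedParams:
    """Map raw gene parameters to the composite parameters of the ODEs."""
    s, u = gene.s, gene.u
    mu = (s + u) / (1.0 + u)
    nu = u * (1.0 - s) / (s * (1.0 + u))
    lam = gene.beta / (1.0 + u / s)
    theta = gene.K2 / gene.K1
    kappa = gene.sigma / theta
    return ReducedDerivedParams(mu=mu, nu=nu, lam=lam, theta=theta,
                                kappa=kappa, r=gene.r)


def _as_derived(p) -> ReducedDerivedParams:
    if isinstance(p, ReducedGeneParams):
        return derive_dimensionless(p)
    return p


def _synthesis(T_self: float, T_other: float, p: ReducedDerivedParams) -> float:
    den = 1.0 + p.mu * T_other * (1.0 + p.r * T_other)
    return 2.0 * math.sqrt(p.theta * T_self) * p.lam * (1.0 + p.nu / den)


def _decay(T_self: float, p: ReducedDerivedParams) -> float:
    return 2.0 * (T_self + (2.0 / (p.kappa * math.sqrt(p.theta))) * T_self ** 1.5)


def reduced_rhs(state: Sequence[float], p1, p2) -> tuple[float, float]:
    """Right-hand side (dT1/dtau, dT2/dtau) of the reduced model."""
    T1, T2 = float(state[0]), float(state[1])
    if T1 < 0 or T2 < 0:
        raise ValueError(f"repressor levels must be non-negative, got {state!r}")
    p1, p2 = _as_derived(p1), _as_derived(p2)
    f1 = _synthesis(T1, T2, p1) - _decay(T1, p1)
    f2 = _synthesis(T2, T1, p2) - _decay(T2, p2)
    return f1, f2


def reduced_jacobian(state: Sequence[float], p1, p2) -> np.ndarray:
    """Analytic Jacobian of the reduced ODEs (undefined at T = 0)."""
    T1, T2 = float(state[0]), float(state[1])
    p1, p2 = _as_derived(p1), _as_derived(p2)

    def diag(T_self, T_other, p):
        den = 1.0 + p.mu * T_other * (1.0 + p.r * T_other)
        g = p.lam * (1.0 + p.nu / den)
        return (math.sqrt(p.theta) * g / math.sqrt(T_self)
                - 2.0 - (6.0 / (p.kappa * math.sqrt(p.theta))) * math.sqrt(T_self))

    def cross(T_self, T_other, p):
        den = 1.0 + p.mu * T_other * (1.0 + p.r * T_other)
        return (-2.0 * math.sqrt(p.theta * T_self) * p.lam * p.nu
                * p.mu * (1.0 + 2.0 * p.r * T_other) / (den * den))

    return np.array([[diag(T1, T2, p1), cross(T1, T2, p1)],
                     [cross(T2, T1, p2), diag(T2, T1, p2)]])


@dataclass(frozen=True)
class FixedPoint:
    """A positive fixed point of the reduced ODEs with linear stability."""

    state: tuple[float, float]
    stable: bool
    eigenvalues: tuple[complex, complex]
    residual: float
    marginal: bool = False  # zero real part: reported unstable, flagged


def _newton_2d(T1, T2, p1, p2, tol=1e-13, max_iter=80):
    """Damped Newton refinement with a symmetric update (2x2 Cramer solve).

    Using an explicit component-wise solve keeps the iteration exactly
    equivariant under the gene-swap symmetry (T1,T2) <-> (T2,T1), so
    symmetric parameter sets yield mirror-symmetric fixed points to the bit.
    """
    for _ in range(max_iter):
        if T1 <= 0 or T2 <= 0:
            return None
        f1, f2 = reduced_rhs((T1, T2), p1, p2)
        J = reduced_jacobian((T1, T2), p1, p2)
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        if det == 0 or not math.isfinite(det):
            return None
        d1 = (f1 * J[1, 1] - f2 * J[0, 1]) / det
        d2 = (J[0, 0] * f2 - J[1, 0] * f1) / det
        # damp steps that would leave the positive quadrant
        scale = 1.0
        if d1 > 0 and T1 - scale * d1 <= 0:
            scale = min(scale, 0.5 * T1 / d1)
        if d2 > 0 and T2 - scale * d2 <= 0:
            scale = min(scale, 0.5 * T2 / d2)
        T1 -= scale * d1
        T2 -= scale * d2
        if abs(f1) < tol and abs(f2) < tol and scale == 1.0 \
                and abs(d1) < 1e-12 * (1 + abs(T1)) \
                and abs(d2) < 1e-12 * (1 + abs(T2)):
            return T1, T2
    # accept if the residual is tiny even without step convergence
    try:
        f1, f2 = reduced_rhs((max(T1, 0.0), max(T2, 0.0)), p1, p2)
    except ValueError:
        return None
    if abs(f1) < 1e-10 and abs(f2) < 1e-10 and T1 > 0 and T2 > 0:
        return T1, T2
    return None


def find_fixed_points(p1, p2,
                      search_bounds: tuple[float, float] = (1e-4, 1e4),
                      n_starts: int = 12,
                      dedup_rtol: float = 1e-6,
                      residual_tol: float = 1e-9) -> list[FixedPoint]:
    """Locate all positive fixed points by logarithmic multistart Newton.

    Fixed points span orders of magnitude in T, hence the log-spaced start
    grid over ``search_bounds`` squared.  The degenerate origin (a
    non-hyperbolic fixed point of the square-root kinetics) is excluded.
    Returns points sorted by (T1, T2); if no start converges an empty list
    is returned and a warning is issued.
    """
    p1, p2 = _as_derived(p1), _as_derived(p2)
    grid = np.geomspace(search_bounds[0], search_bounds[1], n_starts)
    converged: list[tuple[float, float]] = []
    for a in grid:
        for b in grid:
            res = _newton_2d(float(a), float(b), p1, p2)
            if res is None:
                continue
            T1, T2 = res
            if max(T1, T2) < ORIGIN_TOL:
                continue
            f1, f2 = reduced_rhs((T1, T2), p1, p2)
            if max(abs(f1), abs(f2)) > residual_tol:
                continue
            converged.append((T1, T2))
    if not converged:
        warnings.warn("no Newton start converged to a positive fixed point",
                      RuntimeWarning, stacklevel=2)
        return []
    converged.sort()
    reps: list[tuple[float, float]] = []
    for pt in converged:
        dup = False
        for rp in reps:
            num = math.hypot(pt[0] - rp[0], pt[1] - rp[1])
            den = 1.0 + math.hypot(rp[0], rp[1])
            if num / den < dedup_rtol:
                dup = True
                break
        if not dup:
            reps.append(pt)
    out = []
    for T1, T2 in reps:
        J = reduced_jacobian((T1, T2), p1, p2)
        tr = J[0, 0] + J[1, 1]
        det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        disc = tr * tr - 4.0 * det
        if disc >= 0:
            rt = math.sqrt(disc)
            eig = (complex((tr + rt) / 2.0), complex((tr - rt) / 2.0))
        else:
            rt = math.sqrt(-disc)
            eig = (complex(tr / 2.0, rt / 2.0), complex(tr / 2.0, -rt / 2.0))
        max_re = max(e.real for e in eig)
        f1, f2 = reduced_rhs((T1, T2), p1, p2)
        out.append(FixedPoint(state=(T1, T2), stable=bool(max_re < 0.0),
                              eigenvalues=eig,
                              residual=max(abs(f1), abs(f2)),
                              marginal=bool(max_re == 0.0)))
    return out


def classify_reduced(gene1, gene2, **search_kw) -> str:
    """``bistable`` if the reduced ODEs have >= 2 stable fixed points."""
    fps = find_fixed_points(gene1, gene2, **search_kw)
    n_stable = sum(fp.stable for fp in fps)
    return "bistable" if n_stable >= 2 else "monostable"


_AXIS_NAMES = {"s1": (0, "s"), "s2": (1, "s"),
               "beta1": (0, "beta"), "beta2": (1, "beta")}


def scan_phase_plane(axis1: tuple[str, Iterable[float]],
                     axis2: tuple[str, Iterable[float]],
                     gene1: ReducedGeneParams | None = None,
                     gene2: ReducedGeneParams | None = None,
                     **search_kw) -> PhaseGrid:
    """Deterministic stability map over two of {s1, s2, beta1, beta2}.

    Remaining parameters are held at ``gene1``/``gene2`` (reference values
    by default).  Classification is per-cell and order-independent.
    """
    name1, vals1 = axis1[0], np.asarray(list(axis1[1]), dtype=float)
    name2, vals2 = axis2[0], np.asarray(list(axis2[1]), dtype=float)
    for name in (name1, name2):
        if name not in _AXIS_NAMES:
            raise ValueError(f"unknown axis {name!r}; "
                             f"expected one of {sorted(_AXIS_NAMES)}")
    if name1 == name2:
        raise ValueError("the two axes must differ")
    if np.any(vals1 <= 0) or np.any(vals2 <= 0):
        raise ValueError("axis grids must be strictly positive")
    base = (gene1 if gene1 is not None else ReducedGeneParams.reference(),
            gene2 if gene2 is not None else ReducedGeneParams.reference())
    classes = np.empty((len(vals1), len(vals2)), dtype=object)
    n_stable = np.zeros((len(vals1), len(vals2)), dtype=int)
    for i, v1 in enumerate(vals1):
        for j, v2 in enumerate(vals2):
            genes = list(base)
            for name, v in ((name1, v1), (name2, v2)):
                gi, attr = _AXIS_NAMES[name]
                genes[gi] = genes[gi].replace(**{attr: float(v)})
            fps = find_fixed_points(genes[0], genes[1], **search_kw)
            ns = sum(fp.stable for fp in fps)
            n_stable[i, j] = ns
            classes[i, j] = "bistable" if ns >= 2 else "monostable"
    return PhaseGrid(axis1_name=name1, axis1_values=vals1,
                     axis2_name=name2, axis2_values=vals2,
                     classes=classes, n_stable=n_stable)


def reduced_birth_death_network(gene1, gene2, omega: float = 100.0) -> ReactionNetwork:
    """Birth-death stochastic discretization of the reduced dynamics.

    Each gene becomes one species with copy number n_l = omega * T_l; the
    birth propensity is omega times the synthesis term of the reduced ODEs
    evaluated at T = n/omega, the death propensity omega times the decay
    term.  Time is dimensionless (units of 1/gamma_p).  ``omega`` sets the
    molecule count corresponding to one unit of T.
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    p1, p2 = _as_derived(gene1), _as_derived(gene2)

    def birth(p, self_idx, other_idx):
        def prop(counts):
            return omega * _synthesis(counts[self_idx] / omega,
                                      counts[other_idx] / omega, p)
        return prop

    def death(p, self_idx):
        def prop(counts):
            return omega * _decay(counts[self_idx] / omega, p)
        return prop

    species = [SpeciesDef("T1", 0), SpeciesDef("T2", 0)]
    reactions = [
        ReactionDef({}, {"T1": 1}, 1.0, "per_second", "gene1 effective synthesis",
                    propensity=birth(p1, 0, 1)),
        ReactionDef({"T1": 1}, {}, 1.0, "per_second", "gene1 effective decay",
                    propensity=death(p1, 0)),
        ReactionDef({}, {"T2": 1}, 1.0, "per_second", "gene2 effective synthesis",
                    propensity=birth(p2, 1, 0)),
        ReactionDef({"T2": 1}, {}, 1.0, "per_second", "gene2 effective decay",
                    propensity=death(p2, 1)),
    ]
    return ReactionNetwork(species, reactions, volume=1.0,
                           metadata={"circuit": "reduced_birth_death",
                                     "omega": omega,
                                     "time_unit": "1/gamma_p"})
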