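"""Small analytic reaction networks with closed-form behavior.

These fixtures exercise the simulation engine against independent
mathematics: exponential decay, the Poisson stationary law of a birth-death
process, exact conservation under dimerization, and a two-state toggling
caricature.
"""

from __future__ import annotations

from .network import ConservationLaw, ReactionDef, ReactionNetwork, SpeciesDef

__all__ = ["generate_fixture", "FIXTURES"]


def _pure_death(n0: int = 100, gamma: float = 1.0) -> ReactionNetwork:
    """M -> 0 at rate gamma: E[n(t)] = n0 * exp(-gamma t)."""
    return ReactionNetwork(
        [SpeciesDef("M", n0)],
        [ReactionDef({"M": 1}, {}, gamma, "per_second", "death")],
        metadata={"fixture": "pure_death", "n0": n0, "gamma": gamma})


def _birth_death(k: float = 10.0, gamma: float = 1.0) -> ReactionNetwork:
    """0 -> A at k, A -> 0 at gamma: stationary law Poisson(k/gamma)."""
    return ReactionNetwork(
        [SpeciesDef("A", 0)],
        [ReactionDef({}, {"A": 1}, k, "per_second", "birth"),
         ReactionDef({"A": 1}, {}, gamma, "per_second", "death")],
        metadata={"fixture": "birth_death", "k": k, "gamma": gamma,
                  "stationary_mean": k / gamma})


def _dimerization(n0: int = 200, kf: float = 0.01, kr: float = 1.0
                  ) -> ReactionNetwork:
    """2P <-> P2 closed system: n_P + 2 n_P2 is conserved."""
    return ReactionNetwork(
        [SpeciesDef("P", n0), SpeciesDef("P2", 0)],
        [ReactionDef({"P": 2}, {"P2": 1}, kf, "um3_per_second", "dimerize"),
         ReactionDef({"P2": 1}, {"P": 2}, kr, "per_second", "dissociate")],
        conservation_laws=[ConservationLaw("monomer_total",
                                           {"P": 1, "P2": 2}, n0)],
        metadata={"fixture": "dimerization"})


def _toy_toggle(k: float = 5.0, gamma: float = 0.05, kb: float = 1.0
                ) -> ReactionNetwork:
    """Two mutually exclusive promoter states driving opposing reporters.

    A single promoter flips between states GA and GB (rate kb each way);
    the active state produces its reporter at k, reporters decay at gamma.
    Produces a two-state toggling copy-number pattern with exchange
    timescale 1/kb.
    """
    return ReactionNetwork(
        [SpeciesDef("GA", 1), SpeciesDef("GB", 0),
         SpeciesDef("A", 0), SpeciesDef("B", 0)],
        [ReactionDef({"GA": 1}, {"GB": 1}, kb, "per_second", "flip A->B"),
         ReactionDef({"GB": 1}, {"GA": 1}, kb, "per_second", "flip B->A"),
         ReactionDef({"GA": 1}, {"GA": 1, "A": 1}, k, "per_second", "make A"),
         ReactionDef({"GB": 1}, {"GB": 1, "B": 1}, k, "per_second", "make B"),
         ReactionDef({"A": 1}, {}, gamma, "per_second", "decay A"),
         ReactionDef({"B": 1}, {}, gamma, "per_second", "decay B")],
        conservation_laws=[ConservationLaw("promoter", {"GA": 1, "GB": 1}, 1)],
        metadata={"fixture": "toy_toggle"})


FIXTURES = {
    "pure_death": _pure_death,
    "birth_death": _birth_death,
    "dimerization": _dimerization,
    "toy_toggle": _toy_toggle,
}


def generate_fixture(name: str, **kw) -> ReactionNetwork:
    """Build a named fixture network; unknown names list the options."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"available: {sorted(FIXTURES)}") from None
    return builder(**kw)
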