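"""Mass-action stochastic reaction networks for toggle-switch circuits.

A :class:`ReactionNetwork` is a list of species and elementary reactions
(order <= 2) with stochastic rate constants, a cell volume, and optional
conservation laws.  Two builders are provided:

* :func:`build_generic_network` - the generic two-gene mutual-repression
  circuit (HOM2): each promoter carries two operator sites for the opposing
  homodimer, explicit RNA-polymerase binding, transcription initiation,
  elongation, translation, dimerization and degradation.
* :func:`build_litr_network` - the full LacI-TetR (LITR) switch, in which
  LacI is active as a tetramer able to occupy both operator sites of the
  tetR promoter at once, TetR as a dimer, and the inducers IPTG and
  doxycycline bind the repressors both free and DNA-bound.

Rate constants come from :class:`~litrswitch.derive.DerivedRateSet`, so every
number carries provenance.  Bimolecular constants are denominated in
um^3 s^-1 and divided by the cell volume to obtain per-molecule propensities;
chemostatted species (RNA polymerase, inducers) hold a fixed copy number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .derive import DerivedRateSet

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ConservationLaw",
    "ReactionNetwork",
    "CompiledNetwork",
    "LITRConfig",
    "GenericGeneRates",
    "mass_action_propensity",
    "concentration_to_count",
    "count_to_concentration",
    "build_generic_network",
    "build_litr_network",
]

#: molecules per um^3 at 1 nM (N_A * 1e-9 mol/L * 1e-15 L/um^3)
NM_TO_MOLECULES_PER_UM3 = 0.6022


def concentration_to_count(conc_nm: float, volume_um3: float) -> int:
    """Molecule count for a concentration in nM in a cell of given volume."""
    if conc_nm < 0:
        raise ValueError(f"concentration must be non-negative, got {conc_nm}")
    if volume_um3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_um3}")
    return int(round(conc_nm * NM_TO_MOLECULES_PER_UM3 * volume_um3))


def count_to_concentration(count: float, volume_um3: float) -> float:
    """Concentration in nM for a molecule count in a cell of given volume."""
    if volume_um3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_um3}")
    return count / (NM_TO_MOLECULES_PER_UM3 * volume_um3)


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    initial_count: int = 0
    constant: bool = False

    def __post_init__(self):
        if self.initial_count < 0:
            raise ValueError(f"{self.name}: initial count must be >= 0")


@dataclass(frozen=True)
class ReactionDef:
    """One elementary reaction.

    ``unit`` declares how the rate constant converts to a per-molecule
    stochastic rate: ``per_second`` for zero/first-order constants used as
    is, ``um3_per_second`` for volume-denominated constants divided by the
    cell volume (bimolecular reactions, and the intramolecular second-site
    binding step whose printed constant carries volume units).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    unit: str = "per_second"
    label: str = ""
    source_row: str = ""
    propensity: Callable[[np.ndarray], float] | None = None

    def __post_init__(self):
        if self.rate_constant <= 0:
            raise ValueError(f"{self.label or self.reactants}: rate must be positive")
        if self.unit not in ("per_second", "um3_per_second"):
            raise ValueError(f"unknown unit kind {self.unit!r}")
        if self.order > 2 and self.propensity is None:
            raise ValueError(
                f"{self.label or dict(self.reactants)}: reactant order "
                f"{self.order} > 2 is unsupported")

    @property
    def order(self) -> int:
        return sum(self.reactants.values())


@dataclass(frozen=True)
class ConservationLaw:
    """sum_i coeff_i * n_i = total, preserved by every reaction."""

    name: str
    coefficients: Mapping[str, int]
    total: int


def mass_action_propensity(reaction: ReactionDef,
                           state: Mapping[str, int],
                           volume: float) -> float:
    """Stochastic mass-action propensity (events per second) of a reaction.

    Zero order: c.  First order: c*n (c/V*n for a volume-denominated
    constant).  A+B: (c/V)*n_A*n_B.  A+A: (c/V)*n_A*(n_A-1)/2.
    """
    if any(n < 0 for n in state.values()):
        raise ValueError("negative copy numbers are not a valid state")
    c = reaction.rate_constant
    if reaction.unit == "um3_per_second":
        c = c / volume
    species = [s for s, m in reaction.reactants.items() for _ in range(m)]
    if len(species) == 0:
        return c
    if len(species) == 1:
        return c * state[species[0]]
    a, b = species
    if a == b:
        n = state[a]
        return c * n * (n - 1) / 2.0
    return c * state[a] * state[b]


@dataclass
class CompiledNetwork:
    """Array form of a network consumed by the simulation engines."""

    species: list[str]
    initial: np.ndarray            # int64 counts
    is_constant: np.ndarray        # bool
    order: np.ndarray              # int64, 0..2
    r0: np.ndarray                 # first reactant index or -1
    r1: np.ndarray                 # second reactant index or -1
    rate_eff: np.ndarray           # per-molecule(-pair) rate; A+A includes /2
    net: np.ndarray                # (R, S) net stoichiometry, constants zeroed
    custom: list[Callable | None]
    has_custom: bool
    cons_matrix: np.ndarray        # (L, S) conservation-law coefficients
    cons_totals: np.ndarray        # (L,)


@dataclass
class ReactionNetwork:
    species: list[SpeciesDef]
    reactions: list[ReactionDef]
    volume: float = 1.0
    conservation_laws: list[ConservationLaw] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        index = set(names)
        for rxn in self.reactions:
            for s in list(rxn.reactants) + list(rxn.products):
                if s not in index:
                    raise ValueError(f"reaction {rxn.label!r} references "
                                     f"undeclared species {s!r}")

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=np.int64)

    def n_dynamic_species(self) -> int:
        return sum(not s.constant for s in self.species)

    def with_initial_counts(self, counts: Mapping[str, int]) -> "ReactionNetwork":
        """Copy of the network with some initial counts replaced."""
        unknown = set(counts) - set(self.species_names)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        new_species = [
            replace(s, initial_count=int(counts.get(s.name, s.initial_count)))
            for s in self.species
        ]
        net = ReactionNetwork(new_species, self.reactions, self.volume,
                              self.conservation_laws, dict(self.metadata))
        # conservation totals follow the new initial condition
        net.conservation_laws = [
            ConservationLaw(
                law.name, law.coefficients,
                int(sum(c * net.initial_state()[net.species_index(s)]
                        for s, c in law.coefficients.items())))
            for law in self.conservation_laws
        ]
        return net

    def compile(self) -> CompiledNetwork:
        names = self.species_names
        idx = {n: i for i, n in enumerate(names)}
        S, R = len(names), len(self.reactions)
        initial = self.initial_state()
        is_const = np.array([s.constant for s in self.species], dtype=bool)
        order = np.zeros(R, dtype=np.int64)
        r0 = np.full(R, -1, dtype=np.int64)
        r1 = np.full(R, -1, dtype=np.int64)
        rate_eff = np.zeros(R, dtype=np.float64)
        net = np.zeros((R, S), dtype=np.int64)
        custom: list[Callable | None] = []
        for j, rxn in enumerate(self.reactions):
            custom.append(rxn.propensity)
            for s, m in rxn.reactants.items():
                net[j, idx[s]] -= m
            for s, m in rxn.products.items():
                net[j, idx[s]] += m
            if rxn.propensity is not None:
                order[j] = -1
                rate_eff[j] = 0.0
            else:
                species = [s for s, m in rxn.reactants.items()
                           for _ in range(m)]
                order[j] = len(species)
                c = rxn.rate_constant
                if rxn.unit == "um3_per_second":
                    c = c / self.volume
                if len(species) >= 1:
                    r0[j] = idx[species[0]]
                if len(species) == 2:
                    r1[j] = idx[species[1]]
                    if species[0] == species[1]:
                        c = c / 2.0
                rate_eff[j] = c
        net[:, is_const] = 0
        L = len(self.conservation_laws)
        cons = np.zeros((L, S), dtype=np.int64)
        totals = np.zeros(L, dtype=np.int64)
        for i, law in enumerate(self.conservation_laws):
            for s, c in law.coefficients.items():
                cons[i, idx[s]] = c
            totals[i] = law.total
        return CompiledNetwork(
            species=names, initial=initial, is_constant=is_const, order=order,
            r0=r0, r1=r1, rate_eff=rate_eff, net=net, custom=custom,
            has_custom=any(c is not None for c in custom),
            cons_matrix=cons, cons_totals=totals)

    # ------------------------------------------------------------------ io

    def to_dict(self) -> dict:
        if any(r.propensity is not None for r in self.reactions):
            raise ValueError("networks with custom propensities are not serializable")
        return {
            "volume": self.volume,
            "species": [
                {"name": s.name, "initial_count": s.initial_count,
                 "constant": s.constant} for s in self.species],
            "reactions": [
                {"reactants": dict(r.reactants), "products": dict(r.products),
                 "rate_constant": r.rate_constant, "unit": r.unit,
                 "label": r.label, "source_row": r.source_row}
                for r in self.reactions],
            "conservation_laws": [
                {"name": law.name, "coefficients": dict(law.coefficients),
                 "total": law.total} for law in self.conservation_laws],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        return cls(
            species=[SpeciesDef(**s) for s in d["species"]],
            reactions=[ReactionDef(**r) for r in d["reactions"]],
            volume=d["volume"],
            conservation_laws=[ConservationLaw(**l)
                               for l in d.get("conservation_laws", [])],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(json.loads(text))

    def to_text(self) -> str:
        """One reaction per line: reactants -> products ; rate ; unit."""
        def side(m):
            return " + ".join(f"{v} {k}" if v != 1 else k
                              for k, v in sorted(m.items())) or "0"
        lines = [f"# volume_um3 {self.volume!r}"]
        for s in self.species:
            flag = " const" if s.constant else ""
            lines.append(f"@species {s.name} {s.initial_count}{flag}")
        for r in self.reactions:
            if r.propensity is not None:
                raise ValueError("custom-propensity reactions are not serializable")
            lines.append(f"{side(r.reactants)} -> {side(r.products)} ; "
                         f"{r.rate_constant!r} ; {r.unit} ; {r.label}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ReactionNetwork":
        species, reactions, volume = [], [], 1.0

        def parse_side(expr):
            out: dict[str, int] = {}
            expr = expr.strip()
            if expr == "0":
                return out
            for term in expr.split("+"):
                parts = term.split()
                if len(parts) == 2:
                    out[parts[1]] = out.get(parts[1], 0) + int(parts[0])
                else:
                    out[parts[0]] = out.get(parts[0], 0) + 1
            return out

        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("# volume_um3"):
                volume = float(line.split()[-1])
            elif line.startswith("@species"):
                parts = line.split()
                species.append(SpeciesDef(parts[1], int(parts[2]),
                                          constant=len(parts) > 3))
            elif not line.startswith("#"):
                lhs, rest = line.split("->")
                rhs, rate, unit, label = (p.strip() for p in rest.split(";"))
                reactions.append(ReactionDef(parse_side(lhs), parse_side(rhs),
                                             float(rate), unit, label))
        return cls(species, reactions, volume=volume)


# ---------------------------------------------------------------------------
# Generic two-gene circuit (HOM2)
# ---------------------------------------------------------------------------

_GENERIC_ROWS = {
    "k2": "repressor binding, first operator site",
    "q2": "repressor unbinding, first operator site",
    "k4": "repressor binding, second operator site",
    "q4": "repressor unbinding, second operator site",
    "k3": "RNAp binding, free promoter",
    "q3": "RNAp unbinding, free promoter",
    "k5": "RNAp binding, singly repressed promoter",
    "q5": "RNAp unbinding, singly repressed promoter",
    "k7": "RNAp binding, doubly repressed promoter",
    "q7": "RNAp unbinding, doubly repressed promoter",
    "alpha_m": "transcription initiation",
    "alpha_m_el": "transcript elongation",
    "alpha_p": "translation",
    "k1": "dimerization",
    "q1": "dimer dissociation",
    "gamma_m": "mRNA degradation",
    "gamma_p": "monomer degradation",
    "sigma": "monomer-to-dimer lifetime ratio (dimer decay = gamma_p/sigma)",
}


@dataclass(frozen=True)
class GenericGeneRates:
    """Raw per-gene kinetic constants of the generic circuit.

    Bimolecular constants (k1, k2, k3, k4, k5, k7) are in um^3 s^-1; all
    others in s^-1 except the dimensionless lifetime ratio sigma.
    """

    k1: float; q1: float
    k2: float; q2: float
    k3: float; q3: float
    k4: float; q4: float
    k5: float; q5: float
    k7: float; q7: float
    alpha_m: float
    alpha_m_el: float
    alpha_p: float
    gamma_m: float
    gamma_p: float
    sigma: float

    def __post_init__(self):
        for name in _GENERIC_ROWS:
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValueError(
                    f"missing/non-positive rate constant {name!r} "
                    f"({_GENERIC_ROWS[name]})")

    @classmethod
    def example(cls) -> "GenericGeneRates":
        """Plausible bacterial-scale magnitudes, for tests and fixtures."""
        return cls(k1=0.015, q1=8.8e-5, k2=3.0e-3, q2=5.4e-5,
                   k3=4.3e-3, q3=0.45, k4=3.0e-3, q4=2.1e-6,
                   k5=4.3e-4, q5=0.45, k7=4.3e-4, q7=0.45,
                   alpha_m=0.66, alpha_m_el=0.065, alpha_p=0.01,
                   gamma_m=3.0e-3, gamma_p=3.9e-4, sigma=10.0)


def build_generic_network(gene1: GenericGeneRates,
                          gene2: GenericGeneRates,
                          volume: float = 1.0,
                          rnap_count: int = 18) -> ReactionNetwork:
    """Generic mutually repressing two-gene circuit with explicit promoters.

    Each gene has one promoter copy with six occupancy states D_ij (i = 0..2
    repressors of the opposing gene bound, j = 0/1 RNAp bound), an elongation
    intermediate E, mRNA M, monomer P and homodimer P2; RNA polymerase R is
    chemostatted.  20 dynamic species in total.
    """
    species = []
    for l in (1, 2):
        for st in ("D00", "D10", "D20", "D01", "D11", "D21"):
            species.append(SpeciesDef(f"{st}_{l}", 1 if st == "D00" else 0))
        for st in ("E", "M", "P", "P2"):
            species.append(SpeciesDef(f"{st}_{l}", 0))
    species.append(SpeciesDef("R", rnap_count, constant=True))

    reactions = []
    for l, g in ((1, gene1), (2, gene2)):
        e = 3 - l  # opposing gene supplies the repressor
        rev = [
            (f"D00_{l}", f"P2_{e}", f"D10_{l}", g.k2, g.q2, "k2"),
            (f"D10_{l}", f"P2_{e}", f"D20_{l}", g.k4, g.q4, "k4"),
            (f"D00_{l}", "R", f"D01_{l}", g.k3, g.q3, "k3"),
            (f"D10_{l}", "R", f"D11_{l}", g.k5, g.q5, "k5"),
            (f"D20_{l}", "R", f"D21_{l}", g.k7, g.q7, "k7"),
        ]
        for a, b, ab, kf, kr, row in rev:
            reactions.append(ReactionDef({a: 1, b: 1}, {ab: 1}, kf,
                                         "um3_per_second",
                                         f"gene{l} {_GENERIC_ROWS[row]}",
                                         source_row=row))
            reactions.append(ReactionDef({ab: 1}, {a: 1, b: 1}, kr,
                                         "per_second",
                                         f"gene{l} {_GENERIC_ROWS['q' + row[1]]}",
                                         source_row="q" + row[1]))
        for st in ("D01", "D11", "D21"):
            free = "D" + st[1] + "0"
            reactions.append(ReactionDef(
                {f"{st}_{l}": 1}, {f"E_{l}": 1, f"{free}_{l}": 1}, g.alpha_m,
                "per_second", f"gene{l} transcription initiation from {st}",
                source_row="alpha_m"))
        reactions.append(ReactionDef({f"E_{l}": 1}, {f"M_{l}": 1, "R": 1},
                                     g.alpha_m_el, "per_second",
                                     f"gene{l} elongation", source_row="alpha_m_el"))
        reactions.append(ReactionDef({f"M_{l}": 1}, {f"P_{l}": 1, f"M_{l}": 1},
                                     g.alpha_p, "per_second",
                                     f"gene{l} translation", source_row="alpha_p"))
        reactions.append(ReactionDef({f"P_{l}": 2}, {f"P2_{l}": 1}, g.k1,
                                     "um3_per_second", f"gene{l} dimerization",
                                     source_row="k1"))
        reactions.append(ReactionDef({f"P2_{l}": 1}, {f"P_{l}": 2}, g.q1,
                                     "per_second", f"gene{l} dimer dissociation",
                                     source_row="q1"))
        reactions.append(ReactionDef({f"M_{l}": 1}, {}, g.gamma_m,
                                     "per_second", f"gene{l} mRNA degradation",
                                     source_row="gamma_m"))
        reactions.append(ReactionDef({f"P_{l}": 1}, {}, g.gamma_p,
                                     "per_second", f"gene{l} monomer degradation",
                                     source_row="gamma_p"))
        reactions.append(ReactionDef({f"P2_{l}": 1}, {}, g.gamma_p / g.sigma,
                                     "per_second", f"gene{l} dimer degradation",
                                     source_row="gamma_p/sigma"))

    laws = [
        ConservationLaw(f"promoter_gene{l}",
                        {f"{st}_{l}": 1 for st in
                         ("D00", "D10", "D20", "D01", "D11", "D21")}, 1)
        for l in (1, 2)
    ]
    return ReactionNetwork(species, reactions, volume=volume,
                           conservation_laws=laws,
                           metadata={"circuit": "generic"})


# ---------------------------------------------------------------------------
# LITR circuit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LITRConfig:
    """Circuit configuration for the LacI-TetR switch.

    ``n_lacI``/``n_tetR`` are promoter (gene) copy numbers; inducer
    concentrations are in nM and held constant (chemostatted reservoir);
    ``rnap_count`` defaults to 30 nM of free polymerase in ``volume``.
    """

    n_lacI: int = 1
    n_tetR: int = 1
    iptg: float = 0.0
    dox: float = 0.0
    volume: float = 1.0
    rnap_count: int | None = None

    def __post_init__(self):
        if self.n_lacI < 0 or self.n_tetR < 0:
            raise ValueError("copy numbers must be non-negative integers")
        if int(self.n_lacI) != self.n_lacI or int(self.n_tetR) != self.n_tetR:
            raise ValueError("copy numbers must be integers")
        if self.iptg < 0 or self.dox < 0:
            raise ValueError("inducer concentrations must be non-negative")
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    def resolved_rnap_count(self) -> int:
        if self.rnap_count is not None:
            return self.rnap_count
        return concentration_to_count(30.0, self.volume)


#: tetR-promoter (P_lac) occupancy states, all containing one D_t copy
LACI_PROMOTER_STATES = ("D_t", "d1LacI4", "d2LacI4", "d1LacI4i",
                        "D_t_R", "d1LacI4_R", "d2LacI4_R", "d1LacI4i_R")
#: lacI-promoter (P_tet) occupancy states, all containing one D_l copy
TETR_PROMOTER_STATES = ("D_l", "d1TetR2", "d2TetR2",
                        "D_l_R", "d1TetR2_R", "d2TetR2_R")

#: documented reading corrections applied to the printed LITR reaction list
LITR_CORRECTIONS = [
    "second TetR operator-site binding read as TetR2 + d1TetR2 -> d2TetR2 "
    "(promoter bookkeeping: a promoter state cannot bind a second promoter)",
    "RNAp binding to the singly TetR2-bound promoter read as producing "
    "d1TetR2_R (mass balance with its dissociation and initiation partners)",
    "initiation from D_t_R read as E_t + D_t (conservation of the tetR "
    "promoter copy)",
    "initiation from d1TetR2_R -> E_l + d1TetR2 restored by symmetry with "
    "the other TetR2-bound promoter states (the printed list duplicates the "
    "d2TetR2_R row instead)",
    "elongation intermediates: the promoter of the lacI gene (P_tet, "
    "TetR2-repressed) produces E_l -> M_l -> LacI, and the tetR promoter "
    "(P_lac, LacI4-repressed) produces E_t -> M_t -> TetR",
]


def build_litr_network(config: LITRConfig,
                       rates: DerivedRateSet | None = None,
                       laci_operator_q_l3: float | None = None) -> ReactionNetwork:
    """Build the full LacI-TetR reaction network.

    ``laci_operator_q_l3`` optionally replaces the O^sym LacI-DNA
    dissociation rate with a user-supplied (weaker-operator) value.
    """
    k = rates if rates is not None else DerivedRateSet.default()
    V = config.volume
    q_l3 = laci_operator_q_l3 if laci_operator_q_l3 is not None else k["q_l3"]

    species = [
        # tetR promoter (P_lac) states
        SpeciesDef("D_t", int(config.n_tetR)),
        SpeciesDef("d1LacI4"), SpeciesDef("d2LacI4"), SpeciesDef("d1LacI4i"),
        SpeciesDef("D_t_R"), SpeciesDef("d1LacI4_R"), SpeciesDef("d2LacI4_R"),
        SpeciesDef("d1LacI4i_R"),
        # lacI promoter (P_tet) states
        SpeciesDef("D_l", int(config.n_lacI)),
        SpeciesDef("d1TetR2"), SpeciesDef("d2TetR2"),
        SpeciesDef("D_l_R"), SpeciesDef("d1TetR2_R"), SpeciesDef("d2TetR2_R"),
        # transcription / translation intermediates
        SpeciesDef("E_l"), SpeciesDef("E_t"),
        SpeciesDef("M_l"), SpeciesDef("M_t"),
        # proteins
        SpeciesDef("LacI"), SpeciesDef("LacI2"), SpeciesDef("LacI4"),
        SpeciesDef("LacI4i"), SpeciesDef("LacI4ii"),
        SpeciesDef("TetR"), SpeciesDef("TetR2"),
        SpeciesDef("TetR2i"), SpeciesDef("TetR2ii"),
        # chemostatted species
        SpeciesDef("R", config.resolved_rnap_count(), constant=True),
        SpeciesDef("I_l", concentration_to_count(config.iptg, V), constant=True),
        SpeciesDef("I_t", concentration_to_count(config.dox, V), constant=True),
    ]

    rxns: list[ReactionDef] = []

    def rx(reactants, products, rate, unit, label, row):
        rxns.append(ReactionDef(reactants, products, rate, unit, label, row))

    def rev(reactants, products, kf, qr, label, row_f, row_r):
        rx(reactants, products, kf, "um3_per_second", label, row_f)
        rx(products, reactants, qr, "per_second", label + " (reverse)", row_r)

    # --- repressor-operator binding: TetR2 on the lacI promoter -----------
    rev({"TetR2": 1, "D_l": 1}, {"d1TetR2": 1}, k["k_t3"], k["q_t3"],
        "TetR2 binds free lacI promoter", "k_t3", "q_t3")
    rev({"TetR2": 1, "d1TetR2": 1}, {"d2TetR2": 1}, k["k_t3"], k["q_t3"],
        "TetR2 binds second lacI operator site", "k_t3", "q_t3")
    rx({"d1TetR2": 1, "I_t": 1}, {"TetR2i": 1, "D_l": 1}, k["k_t2"],
       "um3_per_second", "DOX displaces singly bound TetR2", "k_t2")
    rx({"d2TetR2": 1, "I_t": 1}, {"TetR2i": 1, "d1TetR2": 1}, k["k_t2"],
       "um3_per_second", "DOX displaces one of two bound TetR2", "k_t2")

    # --- repressor-operator binding: LacI4 on the tetR promoter -----------
    rev({"LacI4": 1, "D_t": 1}, {"d1LacI4": 1}, k["k_l3"], q_l3,
        "LacI4 binds free tetR promoter", "k_l3", "q_l3")
    rev({"LacI4i": 1, "D_t": 1}, {"d1LacI4i": 1}, 0.5 * k["k_l3"], q_l3,
        "IPTG-bound LacI4 binds tetR promoter (one free dimer)",
        "0.5*k_l3", "q_l3")
    # intramolecular second-site binding; the printed constant carries
    # volume units, so it is volume-scaled like the bimolecular steps
    rx({"d1LacI4": 1}, {"d2LacI4": 1}, 200.0 * k["k_l3"], "um3_per_second",
       "singly bound LacI4 occupies the second operator site", "200*k_l3")
    rx({"d2LacI4": 1}, {"d1LacI4": 1}, k["q_l4"], "per_second",
       "LacI4 releases the second operator site", "q_l4")
    rx({"d1LacI4i": 1, "I_l": 1}, {"LacI4ii": 1, "D_t": 1}, k["k_l5"],
       "um3_per_second", "second IPTG displaces singly bound LacI4i", "k_l5")
    rx({"d1LacI4": 1, "I_l": 1}, {"LacI4i": 1, "D_t": 1}, 0.5 * k["k_l5"],
       "um3_per_second", "IPTG binds singly bound LacI4, displacing it",
       "0.5*k_l5")
    rev({"d1LacI4": 1, "I_l": 1}, {"d1LacI4i": 1}, 0.5 * k["k_l5"], k["q_l5"],
        "IPTG binds singly bound LacI4, which stays bound", "0.5*k_l5", "q_l5")
    rev({"d2LacI4": 1, "I_l": 1}, {"d1LacI4i": 1}, k["k_l5"], k["q_l5"],
        "IPTG binds doubly bound LacI4, releasing one site", "k_l5", "q_l5")

    # --- RNA polymerase binding ------------------------------------------
    rev({"D_l": 1, "R": 1}, {"D_l_R": 1}, k["k_b1"], k["q_b"],
        "RNAp binds free lacI promoter", "k_b1", "q_b")
    rev({"D_t": 1, "R": 1}, {"D_t_R": 1}, k["k_b1"], k["q_b"],
        "RNAp binds free tetR promoter", "k_b1", "q_b")
    rev({"d1LacI4": 1, "R": 1}, {"d1LacI4_R": 1}, k["k_lb2"], k["q_b"],
        "RNAp binds singly LacI4-bound promoter", "k_lb2", "q_b")
    rev({"d1LacI4i": 1, "R": 1}, {"d1LacI4i_R": 1}, k["k_lb2"], k["q_b"],
        "RNAp binds singly LacI4i-bound promoter", "k_lb2", "q_b")
    rev({"d2LacI4": 1, "R": 1}, {"d2LacI4_R": 1}, k["k_lb3"], k["q_b"],
        "RNAp binds doubly LacI4-bound promoter", "k_lb3", "q_b")
    rev({"d1TetR2": 1, "R": 1}, {"d1TetR2_R": 1}, k["k_tb2"], k["q_b"],
        "RNAp binds singly TetR2-bound promoter", "k_tb2", "q_b")
    rev({"d2TetR2": 1, "R": 1}, {"d2TetR2_R": 1}, k["k_tb3"], k["q_b"],
        "RNAp binds doubly TetR2-bound promoter", "k_tb3", "q_b")

    # --- transcription initiation (rate alpha_i throughout) ---------------
    for bound, free, e in (
        ("D_l_R", "D_l", "E_l"),
        ("d1TetR2_R", "d1TetR2", "E_l"),
        ("d2TetR2_R", "d2TetR2", "E_l"),
        ("D_t_R", "D_t", "E_t"),
        ("d1LacI4_R", "d1LacI4", "E_t"),
        ("d2LacI4_R", "d2LacI4", "E_t"),
        ("d1LacI4i_R", "d1LacI4i", "E_t"),
    ):
        rx({bound: 1}, {e: 1, free: 1}, k["alpha_i"], "per_second",
           f"transcription initiation from {bound}", "alpha_i")

    # --- elongation / translation -----------------------------------------
    rx({"E_l": 1}, {"M_l": 1, "R": 1}, k["alpha_le"], "per_second",
       "lacI transcript elongation", "alpha_le")
    rx({"E_t": 1}, {"M_t": 1, "R": 1}, k["alpha_te"], "per_second",
       "tetR transcript elongation", "alpha_te")
    rx({"M_l": 1}, {"LacI": 1, "M_l": 1}, k["alpha_lt"], "per_second",
       "lacI translation", "alpha_lt")
    rx({"M_t": 1}, {"TetR": 1, "M_t": 1}, k["alpha_tt"], "per_second",
       "tetR translation", "alpha_tt")

    # --- oligomerization ----------------------------------------------------
    rev({"LacI": 2}, {"LacI2": 1}, k["k_1"], k["q_1"],
        "LacI dimerization", "k_1", "q_1")
    rev({"TetR": 2}, {"TetR2": 1}, k["k_1"], k["q_1"],
        "TetR dimerization", "k_1", "q_1")
    rev({"LacI2": 2}, {"LacI4": 1}, k["k_1"], k["q_l2"],
        "LacI tetramerization", "k_1", "q_l2")

    # --- inducer binding to free repressors --------------------------------
    rev({"LacI4": 1, "I_l": 1}, {"LacI4i": 1}, k["k_l5"], k["q_l5"],
        "IPTG binds free LacI4", "k_l5", "q_l5")
    rev({"LacI4i": 1, "I_l": 1}, {"LacI4ii": 1}, k["k_l5"], k["q_l5"],
        "second IPTG binds free LacI4i", "k_l5", "q_l5")
    rev({"TetR2": 1, "I_t": 1}, {"TetR2i": 1}, k["k_t2"], k["q_t2"],
        "DOX binds free TetR2", "k_t2", "q_t2")
    rev({"TetR2i": 1, "I_t": 1}, {"TetR2ii": 1}, k["k_t2"], k["q_t2"],
        "second DOX binds free TetR2i", "k_t2", "q_t2")

    # --- degradation --------------------------------------------------------
    rx({"M_l": 1}, {}, k["gamma_ml"], "per_second", "lacI mRNA degradation",
       "gamma_ml")
    rx({"M_t": 1}, {}, k["gamma_mt"], "per_second", "tetR mRNA degradation",
       "gamma_mt")
    for prot in ("LacI", "LacI2", "LacI4", "LacI4i", "LacI4ii",
                 "TetR", "TetR2", "TetR2i", "TetR2ii"):
        rx({prot: 1}, {}, k["gamma_p"], "per_second",
           f"{prot} degradation/dilution", "gamma_p")

    laws = [
        ConservationLaw("tetR_promoter_copies",
                        {s: 1 for s in LACI_PROMOTER_STATES},
                        int(config.n_tetR)),
        ConservationLaw("lacI_promoter_copies",
                        {s: 1 for s in TETR_PROMOTER_STATES},
                        int(config.n_lacI)),
    ]

    net = ReactionNetwork(species, rxns, volume=V, conservation_laws=laws)
    n_dyn = net.n_dynamic_species()
    net.metadata = {
        "circuit": "litr",
        "config": {"n_lacI": config.n_lacI, "n_tetR": config.n_tetR,
                   "iptg_nM": config.iptg, "dox_nM": config.dox,
                   "volume_um3": V, "rnap_count": config.resolved_rnap_count()},
        "corrections": list(LITR_CORRECTIONS),
        "species_count_dynamic": n_dyn,
        "species_count_total": len(species),
        "manifest": [
            {"label": r.label, "source_row": r.source_row,
             "rate_constant": r.rate_constant, "unit": r.unit}
            for r in rxns],
    }
    return net
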