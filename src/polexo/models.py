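"""Domain types for mass-action kinetic schemes and the mechanism builders.

A :class:`KineticScheme` is a plain container of species, elementary
mass-action reactions, and initial conditions.  Concentrations are in µM,
times in seconds; unimolecular rate constants are s⁻¹ and bimolecular ones
µM⁻¹s⁻¹.  Reversible steps are always represented as two irreversible
:class:`Reaction` records.

Three builders construct the mechanisms used throughout the package:

``build_proofreading_scheme``
    Branched binding of DNA to the polymerase or exonuclease site of the
    enzyme, internal transfer between the two sites, hydrolysis at the exo
    site, and an optional off-pathway inhibited complex.

``build_extension_scheme``
    Two-state collision/primed complex that is pre-equilibrated before an
    irreversible extension step is switched on.

``build_fate_scheme``
    A linear chain of excision-vs-extension competitions used to compute
    the ultimate fate (excised / extended / buried) of a mismatched primer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Species",
    "Reaction",
    "KineticScheme",
    "ProofreadingParams",
    "ExtensionParams",
    "MismatchExtensionKinetics",
    "SchemeError",
    "InvalidParameterError",
    "build_proofreading_scheme",
    "build_extension_scheme",
    "build_fate_scheme",
    "scheme_to_dict",
    "scheme_from_dict",
]

ROLES = ("free-dna", "free-enzyme", "complex", "absorbing-product")


class SchemeError(ValueError):
    """Structural problem in a kinetic scheme."""


class InvalidParameterError(SchemeError):
    """Parameter set violates its own consistency rules."""


@dataclass(frozen=True)
class Species:
    name: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemeError(f"unknown species role {self.role!r} for {self.name!r}")


@dataclass(frozen=True)
class Reaction:
    """One irreversible elementary mass-action reaction.

    ``reactants`` has one entry (unimolecular, k in s⁻¹) or two entries
    (bimolecular, k in µM⁻¹s⁻¹).  ``products`` may be empty, one, or two
    species.  ``label`` names the rate constant (k1, k-1, k2, ...).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    label: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2:
            raise SchemeError(f"reaction {self.label!r}: need 1 or 2 reactants")
        if self.rate_constant < 0:
            raise SchemeError(f"reaction {self.label!r}: negative rate constant")

    @property
    def unit(self) -> str:
        return "uM-1.s-1" if len(self.reactants) == 2 else "s-1"


@dataclass
class KineticScheme:
    """Species + reactions + initial conditions, with moiety bookkeeping.

    ``dna_moiety`` / ``enzyme_moiety`` give the number of DNA / enzyme
    entities carried by each species; they drive the stoichiometry audit
    and the observable definitions.  ``pre_equilibration_disabled`` lists
    reaction labels that must be switched off while the scheme relaxes to
    equilibrium before t = 0 (empty means no pre-equilibration phase).
    """

    species: list[Species]
    reactions: list[Reaction]
    initial_conditions: dict[str, float]
    dna_moiety: dict[str, int] = field(default_factory=dict)
    enzyme_moiety: dict[str, int] = field(default_factory=dict)
    pre_equilibration_disabled: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise SchemeError("duplicate species names")
        known = set(names)
        for rxn in self.reactions:
            for name in (*rxn.reactants, *rxn.products):
                if name not in known:
                    raise SchemeError(
                        f"reaction {rxn.label!r} references undeclared species {name!r}"
                    )
        for name in self.initial_conditions:
            if name not in known:
                raise SchemeError(f"initial condition for undeclared species {name!r}")
        if any(c < 0 for c in self.initial_conditions.values()):
            raise SchemeError("negative initial concentration")
        self.audit_stoichiometry()

    def audit_stoichiometry(self) -> None:
        """Every reaction must conserve DNA and enzyme entity counts."""
        for moiety, table in (("DNA", self.dna_moiety), ("enzyme", self.enzyme_moiety)):
            if not table:
                continue
            for rxn in self.reactions:
                before = sum(table.get(n, 0) for n in rxn.reactants)
                after = sum(table.get(n, 0) for n in rxn.products)
                if before != after:
                    raise SchemeError(
                        f"reaction {rxn.label!r} does not conserve {moiety} "
                        f"({before} -> {after})"
                    )

    # -- convenience -------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_by_role(self, role: str) -> list[str]:
        return [s.name for s in self.species if s.role == role]

    def total_dna(self) -> float:
        return sum(
            self.initial_conditions.get(n, 0.0) * w for n, w in self.dna_moiety.items()
        )

    def with_initial_conditions(self, ic: dict[str, float]) -> "KineticScheme":
        return replace(self, initial_conditions=dict(ic))


# ---------------------------------------------------------------------------
# parameter sets
# ---------------------------------------------------------------------------

# default locked values used across all excision experiments
K1_DEFAULT = 300.0     # µM⁻¹s⁻¹, pol-site binding, near diffusion limit
K_OFF_DEFAULT = 0.2    # s⁻¹, DNA dissociation from either site
K_EXO_DEFAULT = 1000.0  # s⁻¹, hydrolysis at the exo site


@dataclass
class ProofreadingParams:
    """Rate constants of the branched excision mechanism.

    The internal-transfer reverse rate is never set directly: it is derived
    as ``k3 / K3`` where K3 is the pol→exo transfer equilibrium constant.
    ``k4``/``k_minus4`` describe the off-pathway inhibited complex and are
    ``None`` (absent, not zero) when that branch is not part of the model.
    """

    k2: float                       # µM⁻¹s⁻¹, direct exo-site binding
    k3: float                       # s⁻¹, pol→exo transfer
    K3: float | None = None         # unitless, [exo]/[pol] at equilibrium
    k1: float = K1_DEFAULT          # µM⁻¹s⁻¹, pol-site binding
    k_minus1: float = K_OFF_DEFAULT
    k_minus2: float = K_OFF_DEFAULT
    k_exo: float = K_EXO_DEFAULT    # s⁻¹, hydrolysis at exo site
    k4: float | None = None         # s⁻¹, pol-complex → inhibited complex
    k_minus4: float | None = None   # s⁻¹, inhibited complex → pol-complex

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("k1", "k_minus1", "k2", "k_minus2", "k3", "k_exo"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be non-negative")
        if self.k3 > 0:
            if self.K3 is None or self.K3 <= 0:
                raise InvalidParameterError("K3 must be positive when k3 > 0")
        if (self.k4 is None) != (self.k_minus4 is None):
            raise InvalidParameterError("k4 and k_minus4 must be both present or both absent")

    @property
    def ed_i_present(self) -> bool:
        return self.k4 is not None

    @property
    def k_minus3(self) -> float:
        if self.k3 == 0:
            return 0.0
        assert self.K3 is not None
        return self.k3 / self.K3


@dataclass
class ExtensionParams:
    """Two-state collision/primed model with an irreversible extension step.

    ``k_pol`` is the observed extension rate at the experiment's nucleotide
    concentration; ``dntp_conc`` is an annotation only.
    """

    k1_prime: float            # s⁻¹, collision → primed
    k_minus1_prime: float      # s⁻¹, primed → collision
    k_pol: float               # s⁻¹, observed extension rate
    dntp_conc: float | None = None  # µM, annotation

    def __post_init__(self) -> None:
        if min(self.k1_prime, self.k_minus1_prime, self.k_pol) < 0:
            raise InvalidParameterError("extension rate constants must be non-negative")

    @property
    def fraction_primed(self) -> float:
        total = self.k1_prime + self.k_minus1_prime
        if total == 0:
            return 0.0
        return self.k1_prime / total


@dataclass
class MismatchExtensionKinetics:
    """Extension kinetics as either (kcat, Km) or a kcat/Km upper limit.

    Exactly one of the two representations is populated.  The limit is in
    M⁻¹s⁻¹ (the convention in which such bounds are usually quoted); kcat is
    s⁻¹ and Km µM.
    """

    kcat: float | None = None
    Km: float | None = None
    kcat_over_Km_limit: float | None = None
    is_limit: bool = field(init=False)

    def __post_init__(self) -> None:
        has_mm = self.kcat is not None and self.Km is not None
        has_limit = self.kcat_over_Km_limit is not None
        if has_mm == has_limit:
            raise InvalidParameterError(
                "provide exactly one of {kcat & Km} or kcat_over_Km_limit"
            )
        self.is_limit = has_limit

    def first_order_rate(self, dntp_conc_uM: float | None) -> float:
        """Resolve to a first-order extension rate (s⁻¹).

        For Michaelis–Menten parameters, ``None`` means saturating
        nucleotide (rate = kcat).  For a kcat/Km limit a concentration is
        required and the rate is ``limit · [dNTP in M]``.
        """
        if self.is_limit:
            assert self.kcat_over_Km_limit is not None
            if self.kcat_over_Km_limit == 0.0:
                return 0.0
            if dntp_conc_uM is None:
                raise InvalidParameterError(
                    "a dNTP concentration is required to resolve a kcat/Km limit"
                )
            return self.kcat_over_Km_limit * dntp_conc_uM * 1e-6
        assert self.kcat is not None and self.Km is not None
        if dntp_conc_uM is None:
            return self.kcat
        if dntp_conc_uM < 0:
            raise InvalidParameterError("negative dNTP concentration")
        return self.kcat * dntp_conc_uM / (self.Km + dntp_conc_uM)


# ---------------------------------------------------------------------------
# scheme builders
# ---------------------------------------------------------------------------


def build_proofreading_scheme(
    params: ProofreadingParams, conc_E: float, conc_D: float
) -> KineticScheme:
    """Branched-binding excision mechanism.

    Free DNA binds the enzyme either at the pol site (E+D ⇌ ED_p, k1/k-1)
    or directly at the exo site (E+D ⇌ ED_x, k2/k-2); bound DNA transfers
    between sites (ED_p ⇌ ED_x, k3 / k3/K3) and is hydrolyzed at the exo
    site (ED_x → E + P, k_exo).  When the inhibited branch is present,
    ED_p ⇌ ED_I (k4/k-4).  Mixing starts the reaction: all material begins
    as free E and free D.
    """
    if conc_E <= 0 or conc_D <= 0:
        raise SchemeError("concentrations must be positive")
    params.validate()

    species = [
        Species("E", "free-enzyme"),
        Species("D", "free-dna"),
        Species("ED_p", "complex"),
        Species("ED_x", "complex"),
    ]
    reactions = [
        Reaction(("E", "D"), ("ED_p",), params.k1, "k1"),
        Reaction(("ED_p",), ("E", "D"), params.k_minus1, "k-1"),
        Reaction(("E", "D"), ("ED_x",), params.k2, "k2"),
        Reaction(("ED_x",), ("E", "D"), params.k_minus2, "k-2"),
        Reaction(("ED_p",), ("ED_x",), params.k3, "k3"),
        Reaction(("ED_x",), ("ED_p",), params.k_minus3, "k-3"),
    ]
    dna = {"D": 1, "ED_p": 1, "ED_x": 1, "P": 1}
    enz = {"E": 1, "ED_p": 1, "ED_x": 1}
    if params.ed_i_present:
        species.append(Species("ED_I", "complex"))
        assert params.k4 is not None and params.k_minus4 is not None
        reactions.append(Reaction(("ED_p",), ("ED_I",), params.k4, "k4"))
        reactions.append(Reaction(("ED_I",), ("ED_p",), params.k_minus4, "k-4"))
        dna["ED_I"] = 1
        enz["ED_I"] = 1
    species.append(Species("P", "absorbing-product"))
    reactions.append(Reaction(("ED_x",), ("E", "P"), params.k_exo, "k_exo"))

    return KineticScheme(
        species=species,
        reactions=reactions,
        initial_conditions={"E": conc_E, "D": conc_D},
        dna_moiety=dna,
        enzyme_moiety=enz,
    )


def build_extension_scheme(
    params: ExtensionParams, conc_E: float, conc_D: float
) -> KineticScheme:
    """Pre-equilibrated two-state extension mechanism.

    ED is the initial collision complex, ED_p the complex primed for
    extension; XP is the extended product.  The scheme is flagged so the
    engine equilibrates ED ⇌ ED_p with k_pol disabled before t = 0
    (enzyme pre-incubated with DNA, nucleotide added at t = 0).  Enzyme is
    in excess, so all DNA starts bound in the collision complex.
    """
    if conc_D <= 0:
        raise SchemeError("concentrations must be positive")
    species = [
        Species("ED", "complex"),
        Species("ED_p", "complex"),
        Species("XP", "absorbing-product"),
    ]
    reactions = [
        Reaction(("ED",), ("ED_p",), params.k1_prime, "k1'"),
        Reaction(("ED_p",), ("ED",), params.k_minus1_prime, "k-1'"),
        Reaction(("ED_p",), ("XP",), params.k_pol, "k_pol"),
    ]
    return KineticScheme(
        species=species,
        reactions=reactions,
        initial_conditions={"ED": conc_D},
        dna_moiety={"ED": 1, "ED_p": 1, "XP": 1},
        enzyme_moiety={},
        pre_equilibration_disabled=("k_pol",),
    )


def build_fate_scheme(
    excision_n0: ProofreadingParams,
    excision_n1: ProofreadingParams,
    ext_n0: MismatchExtensionKinetics,
    ext_n1: MismatchExtensionKinetics,
    dntp_conc_n0: float | None = None,
    dntp_conc_n1: float | None = 1000.0,
) -> KineticScheme:
    """Chained excision-vs-extension competition for a terminal mismatch.

    Stage 0 (terminal mismatch) and stage 1 (mismatch covered by one
    correct base) each contribute an internal-transfer loop
    M<i>_p ⇌ M<i>_x with hydrolysis M<i>_x → excised; extension moves
    material M0_p → M1_p → buried.  All steps are first order, so absorbing
    probabilities are well defined and scale-invariant; all material starts
    at stage 0 in the pol-site complex.

    ``dntp_conc_n0``/``dntp_conc_n1`` (µM) resolve the extension kinetics
    to first-order rates; ``None`` means saturating for Michaelis–Menten
    parameters and is an error for limit-only kinetics.
    """
    rate0 = ext_n0.first_order_rate(dntp_conc_n0)
    rate1 = ext_n1.first_order_rate(dntp_conc_n1)

    species = [
        Species("M0_p", "complex"),
        Species("M0_x", "complex"),
    ]
    reactions = [
        Reaction(("M0_p",), ("M0_x",), excision_n0.k3, "k3[n0]"),
        Reaction(("M0_x",), ("M0_p",), excision_n0.k_minus3, "k-3[n0]"),
        Reaction(("M0_x",), ("excised",), excision_n0.k_exo, "k_exo[n0]"),
    ]
    dna = {"M0_p": 1, "M0_x": 1, "excised": 1}
    if rate0 > 0:
        species += [Species("M1_p", "complex"), Species("M1_x", "complex")]
        reactions += [
            Reaction(("M0_p",), ("M1_p",), rate0, "k_ext[n0]"),
            Reaction(("M1_p",), ("M1_x",), excision_n1.k3, "k3[n1]"),
            Reaction(("M1_x",), ("M1_p",), excision_n1.k_minus3, "k-3[n1]"),
            Reaction(("M1_x",), ("excised",), excision_n1.k_exo, "k_exo[n1]"),
        ]
        dna.update({"M1_p": 1, "M1_x": 1})
        if rate1 > 0:
            species.append(Species("buried", "absorbing-product"))
            reactions.append(Reaction(("M1_p",), ("buried",), rate1, "k_ext[n1]"))
            dna["buried"] = 1
    species.append(Species("excised", "absorbing-product"))

    return KineticScheme(
        species=species,
        reactions=reactions,
        initial_conditions={"M0_p": 1.0},
        dna_moiety=dna,
        enzyme_moiety={},
    )


# ---------------------------------------------------------------------------
# serialization (lossless round trip)
# ---------------------------------------------------------------------------


def scheme_to_dict(scheme: KineticScheme) -> dict:
    return {
        "species": [{"name": s.name, "role": s.role} for s in scheme.species],
        "reactions": [
            {
                "reactants": list(r.reactants),
                "products": list(r.products),
                "rate_constant": r.rate_constant,
                "label": r.label,
            }
            for r in scheme.reactions
        ],
        "initial_conditions": dict(scheme.initial_conditions),
        "dna_moiety": dict(scheme.dna_moiety),
        "enzyme_moiety": dict(scheme.enzyme_moiety),
        "pre_equilibration_disabled": list(scheme.pre_equilibration_disabled),
    }


def scheme_from_dict(data: dict) -> KineticScheme:
    return KineticScheme(
        species=[Species(d["name"], d["role"]) for d in data["species"]],
        reactions=[
            Reaction(
                tuple(d["reactants"]),
                tuple(d["products"]),
                float(d["rate_constant"]),
                d["label"],
            )
            for d in data["reactions"]
        ],
        initial_conditions={k: float(v) for k, v in data["initial_conditions"].items()},
        dna_moiety={k: int(v) for k, v in data.get("dna_moiety", {}).items()},
        enzyme_moiety={k: int(v) for k, v in data.get("enzyme_moiety", {}).items()},
        pre_equilibration_disabled=tuple(data.get("pre_equilibration_disabled", ())),
    )
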