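"""Network structure: species, compartments, reactions, stoichiometry.

The central object is :class:`NetworkModel`, assembled from a declarative
model-definition document (a YAML mapping with ``compartments``,
``species``, ``reactions``, ``parameters`` and ``equilibrium_pairs``
sections) by :func:`build_network`.  Structural analyses — conserved
moieties via the exact left null space of the stoichiometric matrix, and
a source/sink mass-balance report — operate on the assembled model.

Species are compartment-qualified (``MAL_c`` vs ``MAL_m``): the
stoichiometric matrix has one row per compartment-qualified *dynamic*
species.  Boundary species (protocol-clamped medium concentrations such
as extracellular glucose) are excluded from the ODE state and from ``S``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

import numpy as np
import sympy

from .parameters import ParameterSet
from .ratelaws import canonical_template

PATHWAYS = ("glycolysis", "ppp", "tca", "polyol", "etc", "other", "exchange")


class DefinitionError(ValueError):
    """A model-definition document failed validation."""


@dataclass(frozen=True)
class Compartment:
    id: str
    relative_volume: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.relative_volume <= 0:
            raise DefinitionError(f"compartment {self.id!r}: relative volume must be > 0")


@dataclass
class MetaboliteSpecies:
    """A compartment-qualified metabolite.

    ``initial_concentration`` is either a number (mM) or the string
    ``"sampled"`` marking a species whose initial value is drawn by Latin
    hypercube sampling.  ``boundary`` species are clamped by the
    stimulation protocol and excluded from the ODE state.
    """

    id: str
    name: str
    compartment: str
    initial_concentration: float | str = 0.0
    boundary: bool = False
    pathway: str = "other"

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise DefinitionError(f"species {self.id!r}: unknown pathway tag {self.pathway!r}")
        if not isinstance(self.initial_concentration, str):
            if self.initial_concentration < 0:
                raise DefinitionError(f"species {self.id!r}: negative initial concentration")


@dataclass
class RateLawSpec:
    template: str
    parameter_names: dict[str, str]
    constrained: bool = False  # Vr derived as Vf / Keq


@dataclass
class ReactionSpec:
    id: str
    substrates: dict[str, int]
    products: dict[str, int]
    rate_law: RateLawSpec
    pathway: str = "other"
    compartment: str = "c"  # home compartment in which the rate is expressed
    modifiers: list[dict] = field(default_factory=list)
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates and not self.products:
            raise DefinitionError(f"reaction {self.id!r}: needs at least one substrate or product")
        for side in (self.substrates, self.products):
            for sid, coeff in side.items():
                if not isinstance(coeff, int) or coeff == 0:
                    raise DefinitionError(
                        f"reaction {self.id!r}: stoichiometric coefficient for {sid} must be a nonzero integer"
                    )
        if self.pathway not in PATHWAYS:
            raise DefinitionError(f"reaction {self.id!r}: unknown pathway tag {self.pathway!r}")

    @property
    def species_ids(self) -> list[str]:
        out = list(self.substrates) + [s for s in self.products if s not in self.substrates]
        for mod in self.modifiers:
            if mod["species"] not in out:
                out.append(mod["species"])
        return out


@dataclass
class ConservationRelation:
    """An integer-normalized left-null-space vector of ``S``.

    The amount-weighted total ``sum_i c_i * V_i * C_i`` (coefficients
    times compartment relative volume times concentration) is constant
    along every trajectory of the ODE system.
    """

    coefficients: np.ndarray  # int vector over dynamic species
    species_ids: list[str]

    @property
    def members(self) -> list[str]:
        return [s for s, c in zip(self.species_ids, self.coefficients) if c != 0]

    def total(self, concentrations: np.ndarray, volumes: np.ndarray) -> float:
        return float(np.dot(self.coefficients * volumes, concentrations))


class NetworkModel:
    """Validated metabolic network with assembled stoichiometry."""

    def __init__(self, name: str, compartments: list[Compartment],
                 species: list[MetaboliteSpecies], reactions: list[ReactionSpec],
                 parameters: ParameterSet | None = None,
                 equilibrium_pairs: list[str] | None = None):
        self.name = name
        self.compartments = compartments
        self.species = species
        self.reactions = reactions
        self.parameters = parameters
        self.equilibrium_pairs = list(equilibrium_pairs or [])
        self._validate()
        self.dynamic_species = [s for s in species if not s.boundary]
        self.boundary_species = [s for s in species if s.boundary]
        self.species_by_id = {s.id: s for s in species}
        self.dynamic_index = {s.id: i for i, s in enumerate(self.dynamic_species)}
        self.reaction_index = {r.id: j for j, r in enumerate(reactions)}
        self.compartment_by_id = {c.id: c for c in compartments}
        self.S = self._assemble_stoichiometry()

    # -- assembly ---------------------------------------------------------
    def _validate(self) -> None:
        comp_ids = [c.id for c in self.compartments]
        if len(set(comp_ids)) != len(comp_ids):
            raise DefinitionError("duplicate compartment ids")
        sp_ids = [s.id for s in self.species]
        if len(set(sp_ids)) != len(sp_ids):
            dup = sorted({i for i in sp_ids if sp_ids.count(i) > 1})
            raise DefinitionError(f"duplicate species ids: {dup}")
        rx_ids = [r.id for r in self.reactions]
        if len(set(rx_ids)) != len(rx_ids):
            dup = sorted({i for i in rx_ids if rx_ids.count(i) > 1})
            raise DefinitionError(f"duplicate reaction ids: {dup}")
        known = set(sp_ids)
        for s in self.species:
            if s.compartment not in comp_ids:
                raise DefinitionError(f"species {s.id!r}: unknown compartment {s.compartment!r}")
        for r in self.reactions:
            for sid in r.species_ids:
                if sid not in known:
                    raise DefinitionError(f"reaction {r.id!r}: unknown species {sid!r}")
            if r.compartment not in comp_ids:
                raise DefinitionError(f"reaction {r.id!r}: unknown compartment {r.compartment!r}")
            canonical_template(r.rate_law.template)
            if self.parameters is not None:
                for role, pname in r.rate_law.parameter_names.items():
                    if pname not in self.parameters:
                        raise DefinitionError(
                            f"reaction {r.id!r}: rate-law role {role!r} references missing parameter {pname!r}"
                        )
        for rid in self.equilibrium_pairs:
            if rid not in rx_ids:
                raise DefinitionError(f"equilibrium pair references unknown reaction {rid!r}")

    def _assemble_stoichiometry(self) -> np.ndarray:
        S = np.zeros((len(self.dynamic_species), len(self.reactions)), dtype=int)
        for j, r in enumerate(self.reactions):
            for sid, coeff in r.substrates.items():
                if sid in self.dynamic_index:
                    S[self.dynamic_index[sid], j] -= coeff
            for sid, coeff in r.products.items():
                if sid in self.dynamic_index:
                    S[self.dynamic_index[sid], j] += coeff
        return S

    # -- convenience ------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.dynamic_species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_volumes(self) -> np.ndarray:
        """Relative compartment volume per dynamic species."""
        return np.array(
            [self.compartment_by_id[s.compartment].relative_volume for s in self.dynamic_species]
        )

    def volume_corrected_S(self) -> np.ndarray:
        """S with column j scaled per-row by V(reaction j) / V(species i).

        Reaction rates are expressed in concentration units of the
        reaction's home compartment; dividing by the species compartment
        volume converts to the species' concentration change so that
        *amounts* balance across the cytosol:mitochondria volume ratio.
        """
        vols = self.species_volumes()
        out = self.S.astype(float)
        for j, r in enumerate(self.reactions):
            v_rxn = self.compartment_by_id[r.compartment].relative_volume
            out[:, j] *= v_rxn / vols
        return out

    def pathway_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for p in PATHWAYS:
            ns = sum(1 for s in self.dynamic_species if s.pathway == p)
            nr = sum(1 for r in self.reactions if r.pathway == p)
            if ns or nr:
                out[p] = {"species": ns, "reactions": nr}
        return out

    def metabolite_names(self) -> dict[str, list[str]]:
        """Metabolite name -> compartment-qualified dynamic species ids."""
        out: dict[str, list[str]] = {}
        for s in self.dynamic_species:
            out.setdefault(s.name, []).append(s.id)
        return out


# ---------------------------------------------------------------------------
# operations


def build_network(definition: dict) -> NetworkModel:
    """Assemble and validate a :class:`NetworkModel` from a definition document.

    The document is a mapping with ``compartments``, ``species``,
    ``reactions`` and optional ``parameters`` / ``equilibrium_pairs``
    sections (see the shipped ``models/beta_cell.yml``).  All
    cross-references are resolved here; an unresolved or duplicate id
    raises :class:`DefinitionError` naming the offender.
    """
    try:
        comp = [Compartment(id=c["id"], relative_volume=float(c["relative_volume"]),
                            name=c.get("name", "")) for c in definition["compartments"]]
        species = [
            MetaboliteSpecies(
                id=s["id"], name=s.get("name", s["id"].rsplit("_", 1)[0]),
                compartment=s["compartment"],
                initial_concentration=s.get("init", 0.0),
                boundary=bool(s.get("boundary", False)),
                pathway=s.get("pathway", "other"),
            )
            for s in definition["species"]
        ]
        reactions = []
        for r in definition["reactions"]:
            rl = RateLawSpec(
                template=r["template"],
                parameter_names=dict(r.get("params", {})),
                constrained=bool(r.get("constrained", False)),
            )
            reactions.append(
                ReactionSpec(
                    id=r["id"],
                    substrates={k: int(v) for k, v in r.get("substrates", {}).items()},
                    products={k: int(v) for k, v in r.get("products", {}).items()},
                    rate_law=rl,
                    pathway=r.get("pathway", "other"),
                    compartment=r.get("compartment", "c"),
                    modifiers=[dict(m) for m in r.get("modifiers", [])],
                    reversible=bool(r.get("reversible", False)),
                )
            )
    except KeyError as exc:
        raise DefinitionError(f"definition document missing key: {exc}") from exc

    params = None
    if "parameters" in definition:
        values, classes, bounds = {}, {}, {}
        for name, entry in definition["parameters"].items():
            if isinstance(entry, dict):
                values[name] = float(entry["value"])
                classes[name] = entry.get("class", "michaelis")
                if "bounds" in entry:
                    bounds[name] = tuple(entry["bounds"])
            else:
                values[name] = float(entry)
                classes[name] = "michaelis"
        params = ParameterSet(values, bounds, classes, provenance="nominal")

    return NetworkModel(
        name=definition.get("name", "network"),
        compartments=comp, species=species, reactions=reactions,
        parameters=params,
        equilibrium_pairs=definition.get("equilibrium_pairs", []),
    )


def _integer_normalize(vec: list[Fraction]) -> np.ndarray:
    denom = 1
    for v in vec:
        denom = denom * v.denominator // gcd(denom, v.denominator)
    ints = [int(v * denom) for v in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    first = next((v for v in ints if v != 0), 1)
    if first < 0:
        ints = [-v for v in ints]
    return np.array(ints, dtype=int)


def conserved_moieties(model: NetworkModel) -> list[ConservationRelation]:
    """Integer-normalized basis of the left null space of ``S``.

    Computed with exact rational elimination so that ``c.T @ S == 0``
    holds in integer arithmetic, which in turn guarantees the
    amount-weighted totals are conserved to solver accuracy along
    trajectories.  Returns an empty list when ``S`` has full row rank.
    """
    S = sympy.Matrix(model.S.tolist())
    basis = S.T.nullspace()
    ids = [s.id for s in model.dynamic_species]
    out = []
    for vec in basis:
        fracs = [Fraction(sympy.Rational(x).p, sympy.Rational(x).q) for x in vec]
        coeffs = _integer_normalize(fracs)
        assert not np.any(coeffs @ model.S), "left-null-space vector failed exact check"
        out.append(ConservationRelation(coefficients=coeffs, species_ids=ids))
    return out


@dataclass
class MassBalanceReport:
    """Structural audit of sources, sinks and orphan species.

    ``exchange_reactions`` are the reactions touching the extracellular
    compartment — the model's sources and sinks with respect to the
    medium.  ``internal_sinks`` are lumped drains with no products
    (biosynthetic demand); ``orphans`` are dynamic species lacking a
    producing or consuming reaction.
    """

    exchange_reactions: list[str]
    internal_sinks: list[str]
    orphans: list[str]
    warnings: list[str]

    @property
    def balanced(self) -> bool:
        return not self.orphans


def validate_mass_balance(model: NetworkModel) -> MassBalanceReport:
    ext_comps = {c.id for c in model.compartments if c.id == "e" or c.name == "extracellular"}
    extracellular = {s.id for s in model.species if s.compartment in ext_comps}
    exchange, internal_sinks, warnings = [], [], []
    produced: set[str] = set()
    consumed: set[str] = set()
    for r in model.reactions:
        touched = set(r.substrates) | set(r.products)
        if touched & extracellular:
            exchange.append(r.id)
        if not r.products:
            internal_sinks.append(r.id)
        for sid in r.substrates:
            consumed.add(sid)
            if r.reversible:
                produced.add(sid)
        for sid in r.products:
            produced.add(sid)
            if r.reversible:
                consumed.add(sid)
    orphans = [
        s.id for s in model.dynamic_species
        if s.id not in produced or s.id not in consumed
    ]
    for sid in orphans:
        warnings.append(f"species {sid} lacks a producing and/or consuming reaction")
    return MassBalanceReport(exchange, internal_sinks, orphans, warnings)


@dataclass
class ParameterInventory:
    """Head-count of the kinetic parameter set.

    ``n_free_vmax`` counts maximal velocities that remain free after the
    equilibrium reparameterization (each constrained reaction's reverse
    velocity is derived as ``Vf / Keq`` and drops out).
    """

    n_parameters: int
    n_velocities: int
    n_equilibrium_constants: int
    n_michaelis: int
    n_regulatory: int
    n_constrained_pairs: int
    n_free_vmax: int


def parameter_inventory(model: NetworkModel) -> ParameterInventory:
    if model.parameters is None:
        raise ValueError("model carries no parameter set")
    p = model.parameters
    n_vel = len(p.names_of_class("velocity"))
    n_keq = len(p.names_of_class("equilibrium"))
    n_km = len(p.names_of_class("michaelis"))
    n_reg = len(p.names_of_class("regulatory"))
    constrained = [r for r in model.reactions if r.rate_law.constrained]
    return ParameterInventory(
        n_parameters=len(p.values),
        n_velocities=n_vel,
        n_equilibrium_constants=n_keq,
        n_michaelis=n_km,
        n_regulatory=n_reg,
        n_constrained_pairs=len(constrained),
        n_free_vmax=n_vel - len(constrained),
    )
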