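"""Mass-action reaction networks over protein moieties.

A :class:`NetworkModel` is a small set of species (monomers, complexes and
fused end states) connected by reversible mass-action reactions.  Every
species carries an explicit *moiety composition* — how many copies of each
underlying protein it contains — so that conservation of protein mass and
the fusion readout are structural properties of the model rather than
user-supplied bookkeeping.

Units are micromolar (μM) for concentrations, seconds for time,
s⁻¹ for unimolecular and μM⁻¹ s⁻¹ for bimolecular rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Tuple

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "NetworkModel",
    "RateSet",
    "Violation",
    "ConservationLaw",
    "validate_model",
    "build_mass_action_rhs",
    "stoichiometric_matrices",
    "conservation_laws",
    "remove_reaction",
    "prune_orphan_species",
    "rates_from_model",
    "models_equal",
]

#: map reaction label -> (kf, kr)
RateSet = Dict[str, Tuple[float, float]]

ROLES = ("monomer", "complex", "fused")


@dataclass(frozen=True)
class Species:
    """A molecular entity with an explicit protein-moiety composition."""

    name: str
    moieties: Mapping[str, int]
    role: str = "monomer"

    def moiety_count(self, protein: str) -> int:
        return int(self.moieties.get(protein, 0))


@dataclass(frozen=True)
class Reaction:
    """A (possibly reversible) mass-action reaction.

    ``kr == 0`` encodes an irreversible reaction.  ``kf``/``kr`` stored here
    are the model's default rates; simulation routines take an explicit
    :data:`RateSet` so parameter scans never mutate the model.
    """

    label: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kf: float = 0.0
    kr: float = 0.0

    @property
    def reversible(self) -> bool:
        return self.kr > 0


@dataclass
class NetworkModel:
    name: str
    species: List[Species]
    reactions: List[Reaction]
    initial_concentrations: Dict[str, float]
    readout_moiety: str

    def species_names(self) -> List[str]:
        return [s.name for s in self.species]

    def species_index(self) -> Dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def proteins(self) -> List[str]:
        """Distinct protein moieties, in first-appearance order."""
        seen: Dict[str, None] = {}
        for s in self.species:
            for p in s.moieties:
                seen.setdefault(p, None)
        return list(seen)

    def reaction(self, label: str) -> Reaction:
        for r in self.reactions:
            if r.label == label:
                return r
        raise KeyError(label)

    def initial_vector(self) -> np.ndarray:
        return np.array(
            [float(self.initial_concentrations.get(s.name, 0.0)) for s in self.species]
        )


@dataclass(frozen=True)
class Violation:
    """One broken model invariant; validation returns these as data."""

    kind: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.message}"


@dataclass(frozen=True)
class ConservationLaw:
    """A conserved linear combination Σ coeff_s·[s] with its initial total."""

    protein: str
    coefficients: Mapping[str, int]
    total: float


def validate_model(model: NetworkModel) -> List[Violation]:
    """Check every structural invariant; an empty list means the model is valid."""
    out: List[Violation] = []
    names = [s.name for s in model.species]
    declared = set(names)
    if len(names) != len(declared):
        dupes = sorted({n for n in names if names.count(n) > 1})
        out.append(Violation("duplicate_species", ",".join(dupes), "species names must be unique"))

    for s in model.species:
        if s.role not in ROLES:
            out.append(Violation("bad_role", s.name, f"role {s.role!r} not in {ROLES}"))
        if not s.moieties or all(v <= 0 for v in s.moieties.values()):
            out.append(Violation("empty_moieties", s.name, "at least one positive moiety required"))
        for p, v in s.moieties.items():
            if not float(v).is_integer() or v < 0:
                out.append(Violation("bad_moiety", s.name, f"moiety {p} count {v} not a non-negative integer"))

    labels = [r.label for r in model.reactions]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        out.append(Violation("duplicate_reaction", ",".join(dupes), "reaction labels must be unique"))

    by_name = {s.name: s for s in model.species}
    for r in model.reactions:
        if not r.reactants or not r.products:
            out.append(Violation("empty_side", r.label, "reactant and product maps must be non-empty"))
            continue
        undeclared = [n for n in list(r.reactants) + list(r.products) if n not in declared]
        for n in undeclared:
            out.append(Violation("undeclared_species", r.label, f"species {n!r} not declared"))
        if r.kf < 0 or r.kr < 0:
            out.append(Violation("negative_rate", r.label, f"kf={r.kf}, kr={r.kr}"))
        elif r.kf == 0 and r.kr == 0:
            out.append(Violation("zero_rate", r.label, "at least one of kf, kr must be positive"))
        for c in list(r.reactants.values()) + list(r.products.values()):
            if not float(c).is_integer() or c <= 0:
                out.append(Violation("bad_stoichiometry", r.label, f"coefficient {c} not a positive integer"))
        if not undeclared:
            proteins = set()
            for n in list(r.reactants) + list(r.products):
                proteins.update(by_name[n].moieties)
            for p in sorted(proteins):
                lhs = sum(c * by_name[n].moiety_count(p) for n, c in r.reactants.items())
                rhs = sum(c * by_name[n].moiety_count(p) for n, c in r.products.items())
                if lhs != rhs:
                    out.append(
                        Violation("moiety_imbalance", r.label, f"protein {p}: reactants carry {lhs}, products {rhs}")
                    )

    for n, c in model.initial_concentrations.items():
        if n not in declared:
            out.append(Violation("undeclared_species", "initial_concentrations", f"species {n!r} not declared"))
        if c < 0:
            out.append(Violation("negative_concentration", n, f"initial concentration {c} μM < 0"))

    if not any(s.moiety_count(model.readout_moiety) for s in model.species):
        out.append(
            Violation("missing_readout", model.readout_moiety, "readout moiety appears in no species")
        )
    return out


def stoichiometric_matrices(model: NetworkModel) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (reactant, product, net) stoichiometry as (n_reactions × n_species) arrays."""
    idx = model.species_index()
    n_rx, n_sp = len(model.reactions), len(model.species)
    R = np.zeros((n_rx, n_sp))
    P = np.zeros((n_rx, n_sp))
    for j, r in enumerate(model.reactions):
        for n, c in r.reactants.items():
            R[j, idx[n]] += c
        for n, c in r.products.items():
            P[j, idx[n]] += c
    return R, P, P - R


class MissingRateError(KeyError):
    """A reaction label has no entry in the supplied rate set."""


def _rate_vectors(model: NetworkModel, rates: RateSet) -> Tuple[np.ndarray, np.ndarray]:
    kf = np.empty(len(model.reactions))
    kr = np.empty(len(model.reactions))
    for j, r in enumerate(model.reactions):
        if r.label not in rates:
            raise MissingRateError(f"no rate entry for reaction {r.label!r}")
        f, b = rates[r.label]
        if f < 0 or b < 0:
            raise ValueError(f"negative rate for reaction {r.label!r}: ({f}, {b})")
        kf[j], kr[j] = f, b
    return kf, kr


def build_mass_action_rhs(
    model: NetworkModel, rates: RateSet
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the model into a mass-action ODE right-hand side ``f(t, y)``.

    For each reaction the net flux is
    ``kf·∏ [reactant]^stoich − kr·∏ [product]^stoich``;
    each species' time derivative is the signed stoichiometric sum of fluxes.
    The returned callable is pure and closes over precomputed index arrays.
    """
    R, P, N = stoichiometric_matrices(model)
    kf, kr = _rate_vectors(model, rates)
    NT = N.T

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        yy = y[None, :]
        flux = kf * np.prod(yy**R, axis=1) - kr * np.prod(yy**P, axis=1)
        return NT @ flux

    return rhs


def reaction_fluxes(model: NetworkModel, rates: RateSet, y: np.ndarray) -> np.ndarray:
    """Net flux of every reaction at state ``y`` (μM/s, reaction order)."""
    R, P, _ = stoichiometric_matrices(model)
    kf, kr = _rate_vectors(model, rates)
    yy = np.asarray(y)[None, :]
    return kf * np.prod(yy**R, axis=1) - kr * np.prod(yy**P, axis=1)


def conservation_laws(model: NetworkModel) -> List[ConservationLaw]:
    """One conserved combination per protein moiety.

    Because every reaction balances moieties, the total amount of each
    protein summed over all species containing it (weighted by copy number)
    is a time invariant; the coefficients are exactly the moiety counts.
    """
    laws = []
    for p in model.proteins():
        coeff = {s.name: s.moiety_count(p) for s in model.species if s.moiety_count(p) > 0}
        total = sum(
            c * float(model.initial_concentrations.get(n, 0.0)) for n, c in coeff.items()
        )
        laws.append(ConservationLaw(p, coeff, total))
    return laws


def remove_reaction(model: NetworkModel, label: str) -> NetworkModel:
    """Return a copy of ``model`` without the labelled reaction.

    Species and initial concentrations are untouched (the in-silico mutation
    deletes an interaction, not a protein); use :func:`prune_orphan_species`
    to also drop species that no remaining reaction references.
    """
    if label not in {r.label for r in model.reactions}:
        available = ", ".join(r.label for r in model.reactions)
        raise KeyError(f"no reaction {label!r}; available: {available}")
    return NetworkModel(
        name=model.name,
        species=list(model.species),
        reactions=[r for r in model.reactions if r.label != label],
        initial_concentrations=dict(model.initial_concentrations),
        readout_moiety=model.readout_moiety,
    )


def prune_orphan_species(model: NetworkModel) -> NetworkModel:
    """Drop species that no reaction references and that start at zero."""
    referenced = set()
    for r in model.reactions:
        referenced.update(r.reactants)
        referenced.update(r.products)
    keep = [
        s
        for s in model.species
        if s.name in referenced or model.initial_concentrations.get(s.name, 0.0) > 0
    ]
    kept = {s.name for s in keep}
    return NetworkModel(
        name=model.name,
        species=keep,
        reactions=list(model.reactions),
        initial_concentrations={
            n: c for n, c in model.initial_concentrations.items() if n in kept
        },
        readout_moiety=model.readout_moiety,
    )


def rates_from_model(model: NetworkModel) -> RateSet:
    """The model's own default rate constants as a rate set."""
    return {r.label: (r.kf, r.kr) for r in model.reactions}


def _species_key(s: Species):
    return (s.name, tuple(sorted(s.moieties.items())), s.role)


def models_equal(a: NetworkModel, b: NetworkModel, ignore_names: bool = True) -> bool:
    """Structural equality: same species, reactions, rates, initials and readout."""
    if not ignore_names and a.name != b.name:
        return False
    if sorted(map(_species_key, a.species)) != sorted(map(_species_key, b.species)):
        return False
    ra = {
        r.label: (tuple(sorted(r.reactants.items())), tuple(sorted(r.products.items())), r.kf, r.kr)
        for r in a.reactions
    }
    rb = {
        r.label: (tuple(sorted(r.reactants.items())), tuple(sorted(r.products.items())), r.kf, r.kr)
        for r in b.reactions
    }
    if ra != rb:
        return False
    ia = {n: c for n, c in a.initial_concentrations.items()}
    ib = {n: c for n, c in b.initial_concentrations.items()}
    return ia == ib and a.readout_moiety == b.readout_moiety
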