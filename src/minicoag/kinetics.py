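"""Reaction networks with mixed mass-action and Michaelis–Menten kinetics.

A :class:`ReactionNetwork` is the single source of truth for one kinetic
model: an ordered species roster (the order defines the state-vector layout)
plus an ordered list of reactions.  Two rate laws are supported:

* :class:`MassActionReaction` — law of mass action, optionally reversible;
  net flux ``kf·Π[reactants] − kb·Π[products]``.
* :class:`MichaelisMentenReaction` — saturating enzymatic conversion
  ``v = kcat·[E]·[S]/(KM + [S])``; the enzyme concentration is untouched.

All concentrations are in mM and all times in seconds; rate-constant units
follow from the molecularity (s⁻¹ for first order, mM⁻¹s⁻¹ for second).
:func:`build_rhs` compiles a network into a fast vectorised ODE right-hand
side; :func:`conservation_laws` returns a rational basis of the conserved
linear combinations (left null space of the net stoichiometry matrix), used
as an integration-accuracy oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Mapping, Union

import numpy as np
import sympy
import yaml

__all__ = [
    "SpeciesSpec",
    "MassActionReaction",
    "MichaelisMentenReaction",
    "Reaction",
    "ReactionNetwork",
    "NetworkConfigError",
    "mass_action_flux",
    "michaelis_menten_flux",
    "build_rhs",
    "conservation_laws",
    "network_to_text",
    "network_from_text",
]


class NetworkConfigError(ValueError):
    """A reaction references an undeclared species or violates an invariant."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species.

    Parameters
    ----------
    name : str
        Unique identifier within the network.
    initial_concentration : float
        Initial concentration in mM; must be non-negative.
    diffusion_coefficient : float, optional
        Diffusion coefficient in m²·s⁻¹.  Carried as metadata only: the
        models here are zero-dimensional (well mixed), so it never enters
        the kinetics.
    """

    name: str
    initial_concentration: float = 0.0
    diffusion_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise NetworkConfigError(
                f"species {self.name!r}: initial concentration must be >= 0, "
                f"got {self.initial_concentration}"
            )


def _as_stoich(mapping: Mapping[str, int], what: str, label: str) -> dict[str, int]:
    out = dict(mapping)
    for sp, coeff in out.items():
        if coeff != 1:
            # the built-in models never use coefficients above 1; restricting
            # them keeps flux evaluation and serialization trivially correct
            raise NetworkConfigError(
                f"reaction {label!r}: {what} stoichiometry for {sp!r} must be 1, got {coeff}"
            )
    return out


@dataclass(frozen=True)
class MassActionReaction:
    """Mass-action reaction, optionally reversible (``kb`` given).

    Species appearing with equal coefficients on both sides act as catalysts:
    they enter the forward flux but their net stoichiometry is zero.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    kf: float
    kb: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", _as_stoich(self.reactants, "reactant", self.label))
        object.__setattr__(self, "products", _as_stoich(self.products, "product", self.label))
        if self.kf <= 0:
            raise NetworkConfigError(f"reaction {self.label!r}: kf must be > 0, got {self.kf}")
        if self.kb is not None and self.kb <= 0:
            raise NetworkConfigError(f"reaction {self.label!r}: kb must be > 0 or None, got {self.kb}")
        if not self.reactants:
            raise NetworkConfigError(f"reaction {self.label!r}: needs at least one reactant")

    @property
    def reversible(self) -> bool:
        return self.kb is not None

    def net_stoichiometry(self) -> dict[str, int]:
        """Product minus reactant coefficients; catalysts cancel to zero."""
        net: dict[str, int] = {}
        for sp, c in self.products.items():
            net[sp] = net.get(sp, 0) + c
        for sp, c in self.reactants.items():
            net[sp] = net.get(sp, 0) - c
        return {sp: c for sp, c in net.items() if c != 0}

    def species(self) -> set[str]:
        return set(self.reactants) | set(self.products)


@dataclass(frozen=True)
class MichaelisMentenReaction:
    """Enzymatic conversion with Michaelis–Menten kinetics.

    Flux ``kcat·[enzyme]·[substrate]/(KM + [substrate])``; the substrate is
    consumed, the products formed, and the enzyme concentration unchanged.
    """

    substrate: str
    enzyme: str
    products: Mapping[str, int]
    kcat: float
    KM: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "products", _as_stoich(self.products, "product", self.label))
        if self.kcat <= 0:
            raise NetworkConfigError(f"reaction {self.label!r}: kcat must be > 0, got {self.kcat}")
        if self.KM <= 0:
            raise NetworkConfigError(f"reaction {self.label!r}: KM must be > 0, got {self.KM}")

    def net_stoichiometry(self) -> dict[str, int]:
        net = {self.substrate: -1}
        for sp, c in self.products.items():
            net[sp] = net.get(sp, 0) + c
        return {sp: c for sp, c in net.items() if c != 0}

    def species(self) -> set[str]:
        return {self.substrate, self.enzyme} | set(self.products)


Reaction = Union[MassActionReaction, MichaelisMentenReaction]


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered species roster plus an ordered list of reactions.

    The species order is stable and defines the layout of every state vector
    and trajectory column derived from this network.
    """

    species: tuple[SpeciesSpec, ...]
    reactions: tuple[Reaction, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkConfigError("duplicate species names in network")
        declared = set(names)
        for rxn in self.reactions:
            missing = rxn.species() - declared
            if missing:
                raise NetworkConfigError(
                    f"reaction {rxn.label!r} references undeclared species {sorted(missing)}"
                )

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise NetworkConfigError(f"unknown species {name!r}") from None

    def initial_state(self) -> np.ndarray:
        """Initial concentration vector (mM) in species order."""
        return np.array([s.initial_concentration for s in self.species], dtype=float)

    def with_initial_concentrations(self, overrides: Mapping[str, float]) -> "ReactionNetwork":
        """Copy of the network with some initial concentrations replaced."""
        unknown = set(overrides) - set(self.species_names)
        if unknown:
            raise NetworkConfigError(f"unknown species in overrides: {sorted(unknown)}")
        new_species = tuple(
            SpeciesSpec(s.name, float(overrides.get(s.name, s.initial_concentration)),
                        s.diffusion_coefficient)
            for s in self.species
        )
        return ReactionNetwork(new_species, self.reactions, self.name)

    def net_stoichiometry_matrix(self) -> np.ndarray:
        """Dense (n_species × n_reactions) matrix of net integer coefficients."""
        mat = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for sp, c in rxn.net_stoichiometry().items():
                mat[self.index(sp), j] = c
        return mat


# --------------------------------------------------------------------------
# flux laws


def mass_action_flux(reaction: MassActionReaction, state: np.ndarray,
                     network: ReactionNetwork) -> float:
    """Net flux (mM·s⁻¹) of one mass-action reaction at the given state."""
    fwd = reaction.kf
    for sp, c in reaction.reactants.items():
        fwd *= state[network.index(sp)] ** c
    bwd = 0.0
    if reaction.kb is not None:
        bwd = reaction.kb
        for sp, c in reaction.products.items():
            bwd *= state[network.index(sp)] ** c
    return fwd - bwd


def michaelis_menten_flux(reaction: MichaelisMentenReaction, state: np.ndarray,
                          network: ReactionNetwork) -> float:
    """Flux (mM·s⁻¹) of one Michaelis–Menten reaction at the given state."""
    s = state[network.index(reaction.substrate)]
    e = state[network.index(reaction.enzyme)]
    denom = reaction.KM + s
    if denom <= 0:
        raise FloatingPointError(
            f"reaction {reaction.label!r}: KM + [substrate] = {denom} <= 0"
        )
    return reaction.kcat * e * s / denom


# --------------------------------------------------------------------------
# compiled right-hand side


def build_rhs(network: ReactionNetwork) -> Callable[[np.ndarray], np.ndarray]:
    """Compile the network into a vectorised ODE right-hand side.

    Returns ``f(state) -> dstate/dt`` with both vectors in species order.
    Forward and backward molecularities are limited to 2 (the built-in
    models never exceed bimolecular steps); a padded state slot holding a
    constant 1.0 stands in for missing second participants so every flux is
    a plain two-factor product.
    """
    n = network.n_species
    pad = n  # index of the constant-1.0 slot

    ma = [r for r in network.reactions if isinstance(r, MassActionReaction)]
    mm = [r for r in network.reactions if isinstance(r, MichaelisMentenReaction)]

    def pair(stoich: Mapping[str, int], label: str) -> tuple[int, int]:
        idx = [network.index(sp) for sp in stoich]
        if len(idx) > 2:
            raise NetworkConfigError(
                f"reaction {label!r}: molecularity {len(idx)} > 2 unsupported"
            )
        while len(idx) < 2:
            idx.append(pad)
        return idx[0], idx[1]

    kf = np.array([r.kf for r in ma])
    kb = np.array([r.kb if r.kb is not None else 0.0 for r in ma])
    ra = np.empty((2, len(ma)), dtype=np.intp)
    pa = np.empty((2, len(ma)), dtype=np.intp)
    for j, r in enumerate(ma):
        ra[:, j] = pair(r.reactants, r.label)
        # irreversible reactions may have >2 products; their backward flux is
        # zero, so point the product pair at the pad slot
        pa[:, j] = pair(r.products, r.label) if r.kb is not None else (pad, pad)

    kcat = np.array([r.kcat for r in mm])
    km = np.array([r.KM for r in mm])
    sub = np.array([network.index(r.substrate) for r in mm], dtype=np.intp)
    enz = np.array([network.index(r.enzyme) for r in mm], dtype=np.intp)

    s_ma = np.zeros((n, len(ma)))
    for j, r in enumerate(ma):
        for sp, c in r.net_stoichiometry().items():
            s_ma[network.index(sp), j] = c
    s_mm = np.zeros((n, len(mm)))
    for j, r in enumerate(mm):
        for sp, c in r.net_stoichiometry().items():
            s_mm[network.index(sp), j] = c

    ra0, ra1 = ra[0], ra[1]
    pa0, pa1 = pa[0], pa[1]

    def rhs(state: np.ndarray) -> np.ndarray:
        x = np.empty(n + 1)
        x[:n] = state
        x[pad] = 1.0
        dy = np.zeros(n)
        if kf.size:
            flux = kf * x[ra0] * x[ra1] - kb * x[pa0] * x[pa1]
            dy += s_ma @ flux
        if kcat.size:
            flux = kcat * x[enz] * x[sub] / (km + x[sub])
            dy += s_mm @ flux
        return dy

    return rhs


def conservation_laws(network: ReactionNetwork) -> list[np.ndarray]:
    """Rational basis of the conserved linear combinations of concentrations.

    Each returned weight vector ``w`` (species order) satisfies
    ``w·(d state/dt) = 0`` identically, because ``w`` lies in the left null
    space of the net stoichiometry matrix.  Computed exactly over the
    rationals with sympy, then returned as float arrays.
    """
    mat = sympy.Matrix(
        [[sympy.Rational(int(v)) for v in row] for row in network.net_stoichiometry_matrix()]
    )
    basis = mat.T.nullspace()
    out = []
    for vec in basis:
        denominators = [Fraction(sympy.Rational(v)).denominator for v in vec]
        scale = int(sympy.ilcm(*denominators)) if denominators else 1
        out.append(np.array([float(v * scale) for v in vec]))
    return out


# --------------------------------------------------------------------------
# plain-text serialization (lossless round trip)


def _reaction_to_dict(rxn: Reaction) -> dict:
    if isinstance(rxn, MassActionReaction):
        d = {
            "type": "mass_action",
            "label": rxn.label,
            "reactants": dict(rxn.reactants),
            "products": dict(rxn.products),
            "kf": float(rxn.kf),
        }
        if rxn.kb is not None:
            d["kb"] = float(rxn.kb)
        return d
    return {
        "type": "michaelis_menten",
        "label": rxn.label,
        "substrate": rxn.substrate,
        "enzyme": rxn.enzyme,
        "products": dict(rxn.products),
        "kcat": float(rxn.kcat),
        "KM": float(rxn.KM),
    }


def _reaction_from_dict(d: Mapping) -> Reaction:
    kind = d.get("type")
    if kind == "mass_action":
        return MassActionReaction(
            reactants=d["reactants"], products=d["products"],
            kf=d["kf"], kb=d.get("kb"), label=d.get("label", ""),
        )
    if kind == "michaelis_menten":
        return MichaelisMentenReaction(
            substrate=d["substrate"], enzyme=d["enzyme"], products=d["products"],
            kcat=d["kcat"], KM=d["KM"], label=d.get("label", ""),
        )
    raise NetworkConfigError(f"unknown reaction type {kind!r}")


def network_to_text(network: ReactionNetwork) -> str:
    """Serialize a network to a YAML document (lossless for float64)."""
    doc = {
        "name": network.name,
        "species": [
            {
                "name": s.name,
                "initial_concentration": float(s.initial_concentration),
                **(
                    {"diffusion_coefficient": float(s.diffusion_coefficient)}
                    if s.diffusion_coefficient is not None else {}
                ),
            }
            for s in network.species
        ],
        "reactions": [_reaction_to_dict(r) for r in network.reactions],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def network_from_text(text: str) -> ReactionNetwork:
    """Parse a network from the YAML form produced by :func:`network_to_text`."""
    doc = yaml.safe_load(text)
    species = tuple(
        SpeciesSpec(
            name=s["name"],
            initial_concentration=s.get("initial_concentration", 0.0),
            diffusion_coefficient=s.get("diffusion_coefficient"),
        )
        for s in doc["species"]
    )
    reactions = tuple(_reaction_from_dict(r) for r in doc["reactions"])
    return ReactionNetwork(species, reactions, name=doc.get("name", ""))
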