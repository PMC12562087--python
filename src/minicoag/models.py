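"""Built-in coagulation models and perturbation scenarios.

Two fixed networks are provided:

* :func:`reference_model` — a detailed extrinsic-pathway cascade with 30
  species and 31 mass-action reactions (12 of them reversible), in which all
  antithrombin-neutralised complexes are lumped into a single inactive
  product ``INACT``.  It is the study's gold standard: its thrombin
  generation curve is the synthetic "data" every downstream stage fits.
* :func:`minimal_model` — an 8-species, 4-reaction skeleton of thrombin
  generation: tissue factor (TF) activates factor X into the Xa–Va complex
  (three Michaelis–Menten conversions with an autocatalytic thrombin loop)
  and antithrombin removes thrombin by mass action.  Its 7 rate constants
  form the calibration design vector.

Units are mM and seconds throughout; picomolar concentrations convert as
1 pM = 1e-9 mM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .kinetics import (
    MassActionReaction,
    MichaelisMentenReaction,
    NetworkConfigError,
    ReactionNetwork,
    SpeciesSpec,
)

__all__ = [
    "MinimalModelParameters",
    "DEFAULT_PARAMETERS",
    "OPTIMAL_PARAMETERS",
    "ParameterBounds",
    "parameter_bounds",
    "reference_model",
    "minimal_model",
    "tf_variant_model",
    "Scenario",
    "apply_scenario",
    "resolve_species",
]

PM_TO_MM = 1e-9  # 1 pM in mM

PARAMETER_NAMES = ("kcat1", "KM1", "kcat2", "KM2", "kcat3", "KM3", "kf4")


@dataclass(frozen=True)
class MinimalModelParameters:
    """The 7 rate constants of the minimal model.

    ``kcat1``/``KM1`` govern TF-catalysed activation of factor X, ``kcat2``/
    ``KM2`` the Xa–Va-catalysed cleavage of prothrombin, ``kcat3``/``KM3``
    the thrombin-catalysed activation of factor V, and ``kf4`` the
    bimolecular inactivation of thrombin by antithrombin.  kcat in s⁻¹,
    KM in mM, kf4 in mM⁻¹s⁻¹.
    """

    kcat1: float
    KM1: float
    kcat2: float
    KM2: float
    kcat3: float
    KM3: float
    kf4: float

    def __post_init__(self) -> None:
        for name in PARAMETER_NAMES:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {getattr(self, name)}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "MinimalModelParameters":
        vals = list(map(float, values))
        if len(vals) != len(PARAMETER_NAMES):
            raise ValueError(f"expected {len(PARAMETER_NAMES)} values, got {len(vals)}")
        return cls(*vals)


#: Literature values of the minimal model's rate constants.
DEFAULT_PARAMETERS = MinimalModelParameters(
    kcat1=5.00e-2, KM1=1.00e-4,
    kcat2=8.00e-2, KM2=1.00e-3,
    kcat3=2.50e1, KM3=5.50e-2,
    kf4=5.00e0,
)

#: Calibrated values published for the fit against the reference model.
OPTIMAL_PARAMETERS = MinimalModelParameters(
    kcat1=8.16e-3, KM1=5.31e-1,
    kcat2=4.55e1, KM2=4.77e-2,
    kcat3=6.38e3, KM3=2.52e1,
    kf4=1.56e1,
)


@dataclass(frozen=True)
class ParameterBounds:
    """Box constraints for the calibration search space."""

    lower: MinimalModelParameters
    upper: MinimalModelParameters

    def contains(self, params: MinimalModelParameters, strict: bool = False) -> bool:
        lo, hi, x = self.lower.as_array(), self.upper.as_array(), params.as_array()
        if strict:
            return bool(np.all(x > lo) and np.all(x < hi))
        return bool(np.all(x >= lo) and np.all(x <= hi))


def parameter_bounds() -> ParameterBounds:
    """Search box for the 7 rate constants.

    Spans at least two orders of magnitude around each literature value,
    slightly widened on some axes so no calibrated optimum sits on a
    boundary.
    """
    lower = MinimalModelParameters(
        kcat1=5.00e-4, KM1=1.00e-6,
        kcat2=8.00e-4, KM2=1.00e-5,
        kcat3=2.50e-1, KM3=5.50e-4,
        kf4=5.00e-2,
    )
    upper = MinimalModelParameters(
        kcat1=5.00e0, KM1=1.00e0,
        kcat2=8.00e1, KM2=1.00e-1,
        kcat3=1.50e4, KM3=4.00e1,
        kf4=5.00e2,
    )
    return ParameterBounds(lower, upper)


# --------------------------------------------------------------------------
# reference model

# species name, initial concentration [mM], diffusion coefficient [m^2/s]
_REFERENCE_SPECIES = (
    ("TF", 2.5e-8, 1.0e-11),
    ("TH", 0.0, 6.7e-11),
    ("PT", 1.4e-3, 5.0e-11),
    ("FVII", 1e-5, 5.8e-11),
    ("FVIIa", 1e-7, 5.8e-11),
    ("TF-FVII", 0.0, 1.0e-11),
    ("TF-FVIIa", 0.0, 1.0e-11),
    ("TF-FVIIa-FXa", 0.0, 1.0e-11),
    ("TF-FVIIa-FXa-TFPI", 0.0, 1.0e-11),
    ("TF-FVIIa-FX", 0.0, 1.0e-11),
    ("FX", 1.6e-4, 5.5e-11),
    ("FXa", 0.0, 6.2e-11),
    ("TFPI", 2.5e-6, 6.5e-11),
    ("FXa-TFPI", 0.0, 4.5e-11),
    ("FIX", 9.0e-5, 5.5e-11),
    ("FIXa", 0.0, 6.2e-11),
    ("FVIII", 7.0e-7, 4.4e-12),
    ("FVIIIa", 0.0, 3.5e-11),
    ("FVIIIa1L", 0.0, 3.5e-11),
    ("FVIIIa2", 0.0, 3.5e-11),
    ("TF-FVIIa-FIX", 0.0, 1.0e-11),
    ("FIXa-FVIIIa", 0.0, 3.2e-11),
    ("FIXa-FVIIIa-FX", 0.0, 2.9e-11),
    ("FV", 2.0e-5, 2.7e-11),
    ("FVa", 0.0, 3.7e-11),
    ("FXa-FVa", 0.0, 3.3e-11),
    ("mTH", 0.0, 6.7e-11),
    ("AT", 3.4e-3, 5.5e-11),
    ("INACT", 0.0, 4.5e-11),
    ("FXa-FVa-PT", 0.0, 1.0e-11),
)

# step, reactants, products, kf, kb (None = irreversible).  Printed rate
# units follow molecularity: bimolecular steps in mM^-1 s^-1, unimolecular
# in s^-1 (so apply the first-order reading to the catalytic conversions in
# steps 7, 18 and 22, and a bimolecular one to the re-association in the
# backward direction of step 16).
_REFERENCE_REACTIONS = (
    (1, ("TF", "FVII"), ("TF-FVII",), 3.20e3, 3.10e-3),
    (2, ("TF", "FVIIa"), ("TF-FVIIa",), 2.30e4, 3.10e-3),
    (3, ("TF-FVIIa", "FVII"), ("TF-FVIIa", "FVIIa"), 4.40e2, None),
    (4, ("FXa", "FVII"), ("FXa", "FVIIa"), 1.30e4, None),
    (5, ("TH", "FVII"), ("TH", "FVIIa"), 23.0, None),
    (6, ("TF-FVIIa", "FX"), ("TF-FVIIa-FX",), 2.50e4, 1.05),
    (7, ("TF-FVIIa-FX",), ("TF-FVIIa-FXa",), 6.0, None),
    (8, ("TF-FVIIa", "FXa"), ("TF-FVIIa-FXa",), 2.20e4, 19.0),
    (9, ("TF-FVIIa", "FIX"), ("TF-FVIIa-FIX",), 1.0e4, 2.4),
    (10, ("TF-FVIIa-FIX",), ("TF-FVIIa", "FIXa"), 1.8, None),
    (11, ("FXa", "PT"), ("FXa", "TH"), 7.5, None),
    (12, ("TH", "FVIII"), ("TH", "FVIIIa"), 2.0e4, None),
    (13, ("FVIIIa", "FIXa"), ("FIXa-FVIIIa",), 1.0e4, 5.0e-3),
    (14, ("FIXa-FVIIIa", "FX"), ("FIXa-FVIIIa-FX",), 1.0e5, 1.0e-3),
    (15, ("FIXa-FVIIIa-FX",), ("FIXa-FVIIIa", "FXa"), 8.20, None),
    (16, ("FVIIIa",), ("FVIIIa1L", "FVIIIa2"), 6.0e-3, 22.0),
    (17, ("FIXa-FVIIIa-FX",), ("FVIIIa1L", "FVIIIa2", "FX", "FIXa"), 1.0e-3, None),
    (18, ("FIXa-FVIIIa",), ("FVIIIa1L", "FVIIIa2", "FIXa"), 1.0e-3, None),
    (19, ("TH", "FV"), ("TH", "FVa"), 2.0e4, None),
    (20, ("FXa", "FVa"), ("FXa-FVa",), 4.0e5, 0.2),
    (21, ("FXa-FVa", "PT"), ("FXa-FVa-PT",), 1.0e5, 103.0),
    (22, ("FXa-FVa-PT",), ("FXa-FVa", "mTH"), 63.5, None),
    (23, ("mTH", "FXa-FVa"), ("TH", "FXa-FVa"), 1.50e4, None),
    (24, ("FXa", "TFPI"), ("FXa-TFPI",), 9.0e2, 3.60e-4),
    (25, ("TF-FVIIa-FXa", "TFPI"), ("TF-FVIIa-FXa-TFPI",), 3.20e5, 1.10e-4),
    (26, ("TF-FVIIa", "FXa-TFPI"), ("TF-FVIIa-FXa-TFPI",), 5.0e4, None),
    (27, ("FXa", "AT"), ("INACT",), 1.5, None),
    (28, ("mTH", "AT"), ("INACT",), 7.1, None),
    (29, ("FIXa", "AT"), ("INACT",), 0.49, None),
    (30, ("TH", "AT"), ("INACT",), 7.1, None),
    (31, ("TF-FVIIa", "AT"), ("INACT",), 0.23, None),
)


def reference_model() -> ReactionNetwork:
    """The detailed 30-species, 31-reaction reference cascade.

    Serves as the study's synthetic-data generator: its thrombin curve is
    the target every calibration run fits.
    """
    species = tuple(SpeciesSpec(n, c0, d) for n, c0, d in _REFERENCE_SPECIES)
    reactions = tuple(
        MassActionReaction(
            reactants={sp: 1 for sp in reactants},
            products={sp: 1 for sp in products},
            kf=kf, kb=kb, label=f"step{step}",
        )
        for step, reactants, products, kf, kb in _REFERENCE_REACTIONS
    )
    return ReactionNetwork(species, reactions, name="reference")


# --------------------------------------------------------------------------
# minimal model

_MINIMAL_INITIAL = {
    "X": 1.6e-4,     # factor X, same pool as the reference's FX
    "TF": 2.5e-8,
    "Xa-Va": 0.0,
    "PT": 1.4e-3,
    "TH": 0.0,
    "V": 2.0e-5,
    "AT": 3.4e-3,
    "INACT": 0.0,
}

_MINIMAL_DIFFUSION = {
    "X": 5.5e-11, "TF": 1.0e-11, "Xa-Va": 3.3e-11, "PT": 5.0e-11,
    "TH": 6.7e-11, "V": 2.7e-11, "AT": 5.5e-11, "INACT": 4.5e-11,
}


def minimal_model(params: MinimalModelParameters = DEFAULT_PARAMETERS) -> ReactionNetwork:
    """The 8-species, 4-reaction minimal thrombin-generation model.

    Reactions (TF acts purely as an enzyme, so its concentration is exactly
    constant in time):

    1. X → Xa-Va, catalysed by TF (kcat1, KM1)
    2. PT → TH, catalysed by Xa-Va (kcat2, KM2)
    3. V → Xa-Va, catalysed by TH (kcat3, KM3) — the autocatalytic loop
    4. TH + AT → INACT, irreversible mass action (kf4)
    """
    species = tuple(
        SpeciesSpec(n, _MINIMAL_INITIAL[n], _MINIMAL_DIFFUSION[n]) for n in _MINIMAL_INITIAL
    )
    reactions = (
        MichaelisMentenReaction(substrate="X", enzyme="TF", products={"Xa-Va": 1},
                                kcat=params.kcat1, KM=params.KM1, label="activation_X"),
        MichaelisMentenReaction(substrate="PT", enzyme="Xa-Va", products={"TH": 1},
                                kcat=params.kcat2, KM=params.KM2, label="thrombin_generation"),
        MichaelisMentenReaction(substrate="V", enzyme="TH", products={"Xa-Va": 1},
                                kcat=params.kcat3, KM=params.KM3, label="autocatalysis_V"),
        MassActionReaction(reactants={"TH": 1, "AT": 1}, products={"INACT": 1},
                           kf=params.kf4, label="inhibition_AT"),
    )
    return ReactionNetwork(species, reactions, name="minimal")


def tf_variant_model(
    variant: str,
    params: MinimalModelParameters = OPTIMAL_PARAMETERS,
    *,
    vii_kf: float = 3.20e3,
    vii_kb: float = 3.10e-3,
    at_kf: float = 0.23,
) -> ReactionNetwork:
    """Minimal model extended with a TF-consuming side reaction.

    In the plain minimal model TF is a pure catalyst and never depletes,
    which is the main structural reason its response to the initial TF level
    is poor.  Three candidate remedies add a TF sink:

    ``vii_sink``
        TF binds factor VII reversibly into a dead-end TF–VII complex, with
        the reference model's step-1 constants and a VII pool initialised to
        the reference's plasma level (1e-5 mM).
    ``at_sink``
        TF is inactivated by antithrombin, defaulting to the reference
        model's TF–VIIa + AT rate (0.23 mM⁻¹s⁻¹) for lack of a measured
        value.
    ``both``
        Both additions.
    """
    if variant not in ("vii_sink", "at_sink", "both"):
        raise NetworkConfigError(
            f"unknown variant {variant!r}; expected vii_sink, at_sink or both"
        )
    if vii_kf < 0 or vii_kb < 0 or at_kf < 0:
        raise NetworkConfigError("variant rate constants must be >= 0")
    base = minimal_model(params)
    species = list(base.species)
    reactions = list(base.reactions)
    # a zero rate disables the corresponding sink, reducing the variant to
    # the unmodified minimal model
    if variant in ("vii_sink", "both") and vii_kf > 0:
        species.append(SpeciesSpec("VII", 1e-5, 5.8e-11))
        species.append(SpeciesSpec("TF-VII", 0.0, 1.0e-11))
        reactions.append(
            MassActionReaction(reactants={"TF": 1, "VII": 1}, products={"TF-VII": 1},
                               kf=vii_kf, kb=vii_kb if vii_kb > 0 else None,
                               label="tf_vii_dead_end")
        )
    if variant in ("at_sink", "both") and at_kf > 0:
        reactions.append(
            MassActionReaction(reactants={"TF": 1, "AT": 1}, products={"INACT": 1},
                               kf=at_kf, label="tf_at_inactivation")
        )
    return ReactionNetwork(tuple(species), tuple(reactions), name=f"minimal+{variant}")


# --------------------------------------------------------------------------
# scenarios

# canonical factor names → per-network species names tried in order
_ALIASES = {
    "X": ("X", "FX"),
    "V": ("V", "FV"),
    "VII": ("VII", "FVII"),
    "VIII": ("VIII", "FVIII"),
    "IX": ("IX", "FIX"),
}


def resolve_species(network: ReactionNetwork, name: str) -> str:
    """Map a canonical factor name (e.g. ``X``) to this network's species name."""
    for candidate in _ALIASES.get(name, (name,)):
        if candidate in network.species_names:
            return candidate
    raise NetworkConfigError(f"species {name!r} not found in network {network.name!r}")


@dataclass(frozen=True)
class Scenario:
    """A perturbed-initial-condition experiment.

    ``species_scalings`` multiplies selected initial concentrations (e.g.
    ``{"AT": 4.0}`` for a four-fold antithrombin increase); ``tf_initial``
    replaces the initial TF concentration outright (mM).  Rate constants are
    never touched.
    """

    species_scalings: Mapping[str, float] = None
    tf_initial: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_scalings", dict(self.species_scalings or {}))
        for sp, f in self.species_scalings.items():
            if f <= 0:
                raise ValueError(f"scaling factor for {sp!r} must be > 0, got {f}")
        if self.tf_initial is not None and self.tf_initial <= 0:
            raise ValueError("tf_initial must be > 0")


def apply_scenario(network: ReactionNetwork, scenario: Scenario) -> ReactionNetwork:
    """Return the network with the scenario's initial-condition changes applied."""
    overrides: dict[str, float] = {}
    for name, factor in scenario.species_scalings.items():
        sp = resolve_species(network, name)
        overrides[sp] = network.species[network.index(sp)].initial_concentration * factor
    if scenario.tf_initial is not None:
        overrides[resolve_species(network, "TF")] = scenario.tf_initial
    if not overrides:
        return network
    return network.with_initial_concentrations(overrides)
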