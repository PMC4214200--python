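"""Gibbs free energy engine for the three catabolic reactions.

The consortium converts acetate to methane by two routes:

* aceticlastic methanogenesis
  (CH3COO- + H2O -> CH4 + HCO3-, dG0' = -31.0 kJ/mol),
* syntrophic acetate oxidation
  (CH3COO- + 4 H2O -> 2 HCO3- + 4 H2 + H+, dG0' = +104.6 kJ/mol)
  coupled to hydrogenotrophic methanogenesis
  (4 H2 + HCO3- + H+ -> CH4 + 3 H2O, dG0' = -135.6 kJ/mol).

In-situ free energies are dG = dG0' + R*T*ln Q with Q built from measured
activities: aqueous species in mol/L against a 1 M standard state, gases
in atm against 1 atm, water at activity 1, and the proton under the
primed (pH-7) convention, i.e. activity 10**(7 - pH).  dG0' values are
the 25 degC standard values; the R*T*ln Q term uses the culture
temperature.  An optional Gibbs-Helmholtz correction of dG0' to the
culture temperature is available but off by default, because the
uncorrected convention reproduces the worked H2-shift arithmetic used in
the field (nu*R*T*ln(p'/p)).

Feasibility is judged against a configurable threshold, by default
-20 kJ per mol of reaction -- the approximate minimum free-energy yield
for microbial energy conservation (roughly one third of ATP hydrolysis
under physiological conditions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

from .units import ATM_PA, R_KJ

__all__ = [
    "Species",
    "Reaction",
    "CultureState",
    "DeltaGValue",
    "SpeciesLookupError",
    "ActivityError",
    "ReactionMisuseError",
    "load_formation_table",
    "SPECIES",
    "ACETICLASTIC",
    "ACETATE_OXIDATION",
    "HYDROGENOTROPHIC",
    "REACTIONS",
    "FEASIBILITY_THRESHOLD",
    "delta_g_standard",
    "ln_reaction_quotient",
    "delta_g",
    "shift_h2",
    "solve_h2_for_target",
    "feasibility_window",
    "FeasibilityWindow",
]

#: Default feasibility threshold, kJ per mol of reaction.
FEASIBILITY_THRESHOLD = -20.0

LN10 = math.log(10.0)


class SpeciesLookupError(KeyError):
    """A reaction references a species absent from the formation table."""


class ActivityError(ValueError):
    """A species with nonzero stoichiometry has zero or negative activity."""


class ReactionMisuseError(ValueError):
    """An H2-specific operation was applied to a reaction without H2."""


@dataclass(frozen=True)
class Species:
    """A chemical species with its phase and formation energetics.

    ``phase`` fixes the activity convention: ``aqueous`` (mol/L vs 1 M),
    ``gas`` (atm vs 1 atm), ``water`` (activity 1), ``proton``
    (activity 10**(7-pH), unity at pH 7).  ``formula`` is (C, H, O,
    charge) for integer balance checking.
    """

    name: str
    phase: str
    formation_energy: float  # kJ/mol, dG0f' at 25 degC
    formula: tuple[int, int, int, int] = (0, 0, 0, 0)
    enthalpy: float = 0.0  # kJ/mol, dH0f at 25 degC

    def __post_init__(self) -> None:
        if self.phase not in {"aqueous", "gas", "water", "proton"}:
            raise ValueError(f"unknown phase {self.phase!r} for {self.name}")


def load_formation_table(path=None) -> dict[str, Species]:
    """Load a species/formation-energy table from TSV.

    Columns: species, phase, dgf_kj_mol, dhf_kj_mol, carbon, hydrogen,
    oxygen, charge.  Lines starting with ``#`` are comments.  With no
    path the table shipped with the package is used.
    """
    if path is None:
        text = (
            resources.files("syntherm.data")
            .joinpath("formation_energies.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, Species] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        row = dict(zip(header, fields))
        table[row["species"]] = Species(
            name=row["species"],
            phase=row["phase"],
            formation_energy=float(row["dgf_kj_mol"]),
            enthalpy=float(row["dhf_kj_mol"]),
            formula=(
                int(row["carbon"]),
                int(row["hydrogen"]),
                int(row["oxygen"]),
                int(row["charge"]),
            ),
        )
    return table


SPECIES: dict[str, Species] = load_formation_table()


@dataclass(frozen=True)
class Reaction:
    """A signed stoichiometry over species names (products positive).

    Elemental (C, H, O) and charge balance is enforced exactly with
    integer arithmetic at construction, using the formulas of the
    species table.
    """

    name: str
    stoichiometry: Mapping[str, int]
    species_table: Mapping[str, Species] = field(default_factory=lambda: SPECIES)

    def __post_init__(self) -> None:
        totals = [0, 0, 0, 0]
        for sp_name, coeff in self.stoichiometry.items():
            sp = self._species(sp_name)
            for i, n_atoms in enumerate(sp.formula):
                totals[i] += coeff * n_atoms
        if any(totals):
            raise ValueError(
                f"reaction {self.name!r} is unbalanced: net (C, H, O, charge) "
                f"= {tuple(totals)}"
            )

    def _species(self, name: str) -> Species:
        try:
            return self.species_table[name]
        except KeyError:
            raise SpeciesLookupError(
                f"species {name!r} (reaction {self.name!r}) is not in the "
                f"formation table"
            ) from None

    @property
    def species(self) -> Iterable[tuple[Species, int]]:
        for name, coeff in self.stoichiometry.items():
            yield self._species(name), coeff

    def h2_coefficient(self) -> int:
        """Signed stoichiometric coefficient of H2, 0 if absent."""
        return self.stoichiometry.get("hydrogen", 0)


ACETICLASTIC = Reaction(
    "aceticlastic",
    {"acetate": -1, "water": -1, "methane": 1, "bicarbonate": 1},
)
ACETATE_OXIDATION = Reaction(
    "acetate_oxidation",
    {"acetate": -1, "water": -4, "bicarbonate": 2, "hydrogen": 4, "proton": 1},
)
HYDROGENOTROPHIC = Reaction(
    "hydrogenotrophic",
    {"hydrogen": -4, "bicarbonate": -1, "proton": -1, "methane": 1, "water": 3},
)

REACTIONS: dict[str, Reaction] = {
    r.name: r for r in (ACETICLASTIC, ACETATE_OXIDATION, HYDROGENOTROPHIC)
}


@dataclass(frozen=True)
class CultureState:
    """One time point of a batch culture: the argument of every dG call.

    Gas pressures are stored in atm; use :meth:`from_pa` when the source
    reports Pa (trace H2 readings usually do).
    """

    temperature: float = 328.15  # K
    pH: float = 7.0
    acetate: float = 0.0  # mol/L
    bicarbonate: float = 0.0  # mol/L
    p_ch4: float = 0.0  # atm
    p_h2: float = 0.0  # atm
    day: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive (kelvin)")
        for name in ("acetate", "bicarbonate", "p_ch4", "p_h2"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_pa(
        cls,
        *,
        p_ch4_pa: float = 0.0,
        p_h2_pa: float = 0.0,
        **kwargs,
    ) -> "CultureState":
        return cls(p_ch4=p_ch4_pa / ATM_PA, p_h2=p_h2_pa / ATM_PA, **kwargs)

    def activity(self, species: Species) -> float:
        """Activity of ``species`` under the phase conventions."""
        if species.phase == "water":
            return 1.0
        if species.phase == "proton":
            return 10.0 ** (7.0 - self.pH)
        lookup = {
            "acetate": self.acetate,
            "bicarbonate": self.bicarbonate,
            "methane": self.p_ch4,
            "hydrogen": self.p_h2,
        }
        try:
            return lookup[species.name]
        except KeyError:
            raise SpeciesLookupError(
                f"no culture-state field holds the activity of {species.name!r}"
            ) from None


@dataclass(frozen=True)
class DeltaGValue:
    """An in-situ free energy with its feasibility classification."""

    reaction: str
    value: float  # kJ per mol of reaction as written
    feasible: bool
    threshold: float = FEASIBILITY_THRESHOLD


def delta_g_standard(
    reaction: Reaction,
    formation_table: Mapping[str, Species] | None = None,
    temperature: float | None = None,
) -> float:
    """Standard transformed free energy dG0' = sum coeff * dG0f'.

    With ``temperature`` set, applies the Gibbs-Helmholtz correction
    dG0'(T) = dG0'(T0)*T/T0 + dH0*(1 - T/T0) from T0 = 298.15 K using
    the table's formation enthalpies (constant-dH0 approximation).
    """
    table = formation_table if formation_table is not None else SPECIES
    rxn = (
        reaction
        if formation_table is None
        else Reaction(reaction.name, reaction.stoichiometry, table)
    )
    dg0 = sum(sp.formation_energy * coeff for sp, coeff in rxn.species)
    if temperature is None:
        return dg0
    t0 = 298.15
    dh0 = sum(sp.enthalpy * coeff for sp, coeff in rxn.species)
    return dg0 * temperature / t0 + dh0 * (1.0 - temperature / t0)


def ln_reaction_quotient(reaction: Reaction, state: CultureState) -> float:
    """ln Q = sum coeff * ln(activity) under the phase conventions.

    Water contributes nothing; the proton contributes
    coeff * (7 - pH) * ln 10.  A zero or negative activity on a species
    with nonzero coefficient is a domain error naming the species.
    """
    total = 0.0
    for sp, coeff in reaction.species:
        if coeff == 0:
            continue
        if sp.phase == "water":
            continue
        if sp.phase == "proton":
            total += coeff * (7.0 - state.pH) * LN10
            continue
        a = state.activity(sp)
        if a <= 0.0:
            raise ActivityError(
                f"species {sp.name!r} has activity {a} in reaction "
                f"{reaction.name!r} (day={state.day}); ln Q is undefined"
            )
        total += coeff * math.log(a)
    return total


def delta_g(
    reaction: Reaction,
    state: CultureState,
    threshold: float = FEASIBILITY_THRESHOLD,
    temperature_correction: bool = False,
) -> DeltaGValue:
    """In-situ dG = dG0' + R*T*ln Q, classified against ``threshold``.

    R = 8.3145e-3 kJ mol-1 K-1; T is the state's temperature.  By
    default dG0' is the 25 degC table value (see module docstring);
    ``temperature_correction=True`` applies Gibbs-Helmholtz to dG0'.
    """
    dg0 = delta_g_standard(
        reaction,
        temperature=state.temperature if temperature_correction else None,
    )
    value = dg0 + R_KJ * state.temperature * ln_reaction_quotient(reaction, state)
    return DeltaGValue(
        reaction=reaction.name,
        value=value,
        feasible=value <= threshold,
        threshold=threshold,
    )


def shift_h2(
    dg: float,
    reaction: Reaction,
    p_h2_from: float,
    p_h2_to: float,
    temperature: float = 328.15,
) -> float:
    """Adjust an observed dG for a counterfactual H2 partial pressure.

    Returns dg + nu_H2 * R * T * ln(p_to / p_from) with both pressures
    in Pa (the ratio makes the unit irrelevant) and nu_H2 the signed H2
    coefficient (+4 for acetate oxidation, -4 for hydrogenotrophic
    methanogenesis).
    """
    nu = reaction.h2_coefficient()
    if nu == 0:
        raise ReactionMisuseError(
            f"reaction {reaction.name!r} has no H2 term; shift_h2 does not apply"
        )
    if p_h2_from <= 0.0 or p_h2_to <= 0.0:
        raise ActivityError("H2 partial pressures must be > 0 for shift_h2")
    return dg + nu * R_KJ * temperature * math.log(p_h2_to / p_h2_from)


def solve_h2_for_target(
    reaction: Reaction,
    state: CultureState,
    target_dg: float = FEASIBILITY_THRESHOLD,
    temperature_correction: bool = False,
) -> float:
    """H2 partial pressure (Pa) at which the reaction's dG equals target.

    All other activities are held at the state's values.  Closed form:
    with Q split as Q_rest * p_H2**nu,
    ln p_H2 = (target - dG0' - R*T*ln Q_rest) / (nu * R * T).
    """
    nu = reaction.h2_coefficient()
    if nu == 0:
        raise ReactionMisuseError(
            f"reaction {reaction.name!r} has no H2 term; there is no H2 "
            "pressure to solve for"
        )
    # At p_h2 = 1 atm the H2 term of ln Q vanishes, leaving ln Q_rest.
    rest = replace(state, p_h2=1.0)
    ln_q_rest = ln_reaction_quotient(reaction, rest)
    dg0 = delta_g_standard(
        reaction,
        temperature=state.temperature if temperature_correction else None,
    )
    rt = R_KJ * state.temperature
    ln_p_atm = (target_dg - dg0 - rt * ln_q_rest) / (nu * rt)
    return math.exp(ln_p_atm) * ATM_PA


@dataclass(frozen=True)
class FeasibilityWindow:
    """The H2 range over which syntrophic acetate oxidation can operate.

    ``h2_low`` is the draw-down limit of the hydrogenotrophic methanogen
    (below it H2 consumption yields less than the threshold); ``h2_high``
    is the ceiling above which acetate oxidation yields less than the
    threshold.  An empty window (h2_low > h2_high) means syntrophy is
    thermodynamically infeasible at this state.
    """

    h2_low: float  # Pa
    h2_high: float  # Pa
    threshold: float = FEASIBILITY_THRESHOLD

    @property
    def is_empty(self) -> bool:
        return self.h2_low > self.h2_high

    @property
    def log_width(self) -> float:
        """ln(h2_high / h2_low); negative when the window is empty."""
        return math.log(self.h2_high / self.h2_low)


def feasibility_window(
    state: CultureState, threshold: float = FEASIBILITY_THRESHOLD
) -> FeasibilityWindow:
    """H2 interval where both syntrophic partners clear the threshold."""
    h2_low = solve_h2_for_target(HYDROGENOTROPHIC, state, threshold)
    h2_high = solve_h2_for_target(ACETATE_OXIDATION, state, threshold)
    return FeasibilityWindow(h2_low=h2_low, h2_high=h2_high, threshold=threshold)
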