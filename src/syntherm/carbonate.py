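"""Carbonate system speciation for closed serum-vial cultures.

A bicarbonate-buffered medium in a sealed vial holds inorganic carbon in
three pools: gaseous CO2 in the headspace, dissolved CO2 in the liquid,
and bicarbonate.  At a fixed pH the three pools are linked by Henry's law
(c_aq = k * p_CO2) and the first carbonic-acid dissociation
(H2CO3 <=> H+ + HCO3-, [HCO3-] = K1 * c_aq / [H+]).  Given the sodium
bicarbonate added to the medium and the CO2 fraction of the headspace gas
at filling, :func:`speciate_closed_vial` redistributes the total carbon
so that both equilibria hold simultaneously and reports the per-liter-of-
medium total inorganic carbon ([sigma-CO2]).

Carbonate ion (CO3 2-) is neglected: at pH 7 its share is below 0.5% and
the two-species equilibrium is the convention used for these media.
Activity coefficients are unity and the pH is an input (media are
adjusted to pH 7.0 and drift less than 0.2 during cultivation), so
every pool is linear in the CO2 partial pressure and the balance has a
direct solution; conservation is verified after the fact and a failure
raises with diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import R_L_ATM

__all__ = [
    "VialSpec",
    "MediumSpec",
    "SpeciationResult",
    "SpeciationError",
    "dissolved_co2",
    "bicarbonate_at_equilibrium",
    "speciate_closed_vial",
]

#: Henry's-law constant for CO2 at 55 degC, mol L-1 atm-1.
HENRY_CO2_55C = 0.019

#: First carbonic-acid dissociation constant near 55 degC (pK1 ~ 6.35), mol/L.
K1_CARBONIC = 4.47e-7


class SpeciationError(RuntimeError):
    """Raised when the closed-vial carbon balance cannot be solved."""


@dataclass(frozen=True)
class VialSpec:
    """Geometry and temperature of a sealed culture vial.

    Defaults are the 68-ml serum vial holding 20 ml of medium at 55 degC
    used for thermophilic batch cultures.
    """

    total_volume: float = 0.068  # L
    liquid_volume: float = 0.020  # L
    temperature: float = 328.15  # K

    def __post_init__(self) -> None:
        if not 0.0 < self.liquid_volume < self.total_volume:
            raise ValueError(
                "liquid_volume must lie strictly between 0 and total_volume "
                f"(got {self.liquid_volume} of {self.total_volume} L)"
            )
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def headspace_volume(self) -> float:
        """Gas volume above the liquid, L."""
        return self.total_volume - self.liquid_volume


@dataclass(frozen=True)
class MediumSpec:
    """Inorganic-carbon makeup of a bicarbonate-buffered medium.

    Parameters
    ----------
    bicarbonate_added
        NaHCO3 dissolved in the medium, mol per liter of medium.
    co2_headspace_fraction
        CO2 volume fraction of the (1 atm total) gas used to flush the
        headspace, 0-1.
    pH
        Medium pH; held fixed during speciation.
    henry_constant
        Henry's-law constant for CO2, mol L-1 atm-1.
    k1_equilibrium
        First carbonic-acid dissociation constant, mol/L.
    """

    bicarbonate_added: float = 0.0
    co2_headspace_fraction: float = 0.0
    pH: float = 7.0
    henry_constant: float = HENRY_CO2_55C
    k1_equilibrium: float = K1_CARBONIC

    def __post_init__(self) -> None:
        if self.bicarbonate_added < 0.0:
            raise ValueError("bicarbonate_added must be >= 0")
        if not 0.0 <= self.co2_headspace_fraction <= 1.0:
            raise ValueError("co2_headspace_fraction must be within [0, 1]")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError("pH must be within [0, 14]")
        if self.henry_constant <= 0.0:
            raise ValueError("henry_constant must be > 0")
        if self.k1_equilibrium <= 0.0:
            raise ValueError("k1_equilibrium must be > 0")


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium partition of inorganic carbon in a closed vial."""

    co2_aq: float  # mol/L of liquid
    bicarbonate: float  # mol/L of liquid
    co2_gas_amount: float  # mol in the headspace
    p_co2: float  # atm, equilibrium headspace CO2 partial pressure
    total_inorganic_carbon: float  # mmol per liter of medium ([sigma-CO2])


def dissolved_co2(p_co2: float, henry_constant: float = HENRY_CO2_55C) -> float:
    """Dissolved CO2 from Henry's law, c_aq = k * p.

    Parameters are the CO2 partial pressure in atm and the Henry constant
    in mol L-1 atm-1; returns mol/L.
    """
    if p_co2 < 0.0:
        raise ValueError(f"partial pressure must be >= 0, got {p_co2}")
    if henry_constant <= 0.0:
        raise ValueError("henry_constant must be > 0")
    return henry_constant * p_co2


def bicarbonate_at_equilibrium(
    co2_aq: float, pH: float, k1: float = K1_CARBONIC
) -> float:
    """Bicarbonate in equilibrium with dissolved CO2 at a given pH.

    [HCO3-] = K1 * [CO2(aq)] / [H+] with [H+] = 10**(-pH); mol/L.
    """
    if co2_aq < 0.0:
        raise ValueError(f"co2_aq must be >= 0, got {co2_aq}")
    if k1 <= 0.0:
        raise ValueError("k1 must be > 0")
    return k1 * co2_aq / 10.0 ** (-pH)


def total_carbon_mol(
    vial: VialSpec, medium: MediumSpec, extra_inorganic_carbon: float = 0.0
) -> float:
    """Total inorganic carbon charged into the vial, mol.

    Sum of NaHCO3 in the liquid and CO2 gas in the headspace at filling
    (ideal gas at the vial temperature), plus any biogenic carbon already
    released into the system (mol).
    """
    n_liquid = medium.bicarbonate_added * vial.liquid_volume
    p_fill = medium.co2_headspace_fraction * 1.0  # atm, of 1 atm total
    n_gas = p_fill * vial.headspace_volume / (R_L_ATM * vial.temperature)
    return n_liquid + n_gas + extra_inorganic_carbon


def speciate_closed_vial(
    vial: VialSpec, medium: MediumSpec, extra_inorganic_carbon: float = 0.0
) -> SpeciationResult:
    """Partition the vial's inorganic carbon across gas, CO2(aq) and HCO3-.

    Finds the headspace CO2 partial pressure p at which the carbon
    balance closes with Henry's law and the K1 equilibrium both holding
    at the medium pH.  ``extra_inorganic_carbon`` (mol) adds biogenic
    CO2/HCO3- released during growth to the initially charged pool.

    Returns a :class:`SpeciationResult`; total_inorganic_carbon is
    expressed in mmol per liter of medium, the [sigma-CO2] convention.

    Raises
    ------
    SpeciationError
        If the bracketed root find fails to converge.
    """
    n_total = total_carbon_mol(vial, medium, extra_inorganic_carbon)
    if n_total == 0.0:
        return SpeciationResult(0.0, 0.0, 0.0, 0.0, 0.0)

    rt = R_L_ATM * vial.temperature
    h_plus = 10.0 ** (-medium.pH)
    # mol of carbon held per atm of CO2: headspace + aqueous (CO2 + HCO3-);
    # at fixed pH every pool is linear in p, so the balance solves directly
    k_aq = medium.henry_constant * (1.0 + medium.k1_equilibrium / h_plus)
    capacity = vial.headspace_volume / rt + k_aq * vial.liquid_volume
    p_eq = n_total / capacity

    residual = p_eq * capacity - n_total
    if not abs(residual) <= 1e-9 * n_total:
        raise SpeciationError(
            f"carbon balance failed to close: n_total={n_total:.6e} mol, "
            f"p_eq={p_eq:.6e} atm, residual={residual:.3e} mol"
        )

    co2_aq = dissolved_co2(p_eq, medium.henry_constant)
    hco3 = bicarbonate_at_equilibrium(co2_aq, medium.pH, medium.k1_equilibrium)
    n_gas = p_eq * vial.headspace_volume / rt
    total_mmol_per_l = (
        (co2_aq + hco3) + n_gas / vial.liquid_volume
    ) * 1e3
    return SpeciationResult(
        co2_aq=co2_aq,
        bicarbonate=hco3,
        co2_gas_amount=n_gas,
        p_co2=p_eq,
        total_inorganic_carbon=total_mmol_per_l,
    )
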