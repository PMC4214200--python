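"""Physical constants and unit conversions used across the package.

Internal conventions: concentrations in mol/L, gas partial pressures in
atm, temperature in kelvin, energies in kJ/mol.  H2 is reported in Pa at
the user-facing interfaces because that is how trace-gas analyzers (and
the literature on interspecies hydrogen transfer) report it.
"""

#: Gas constant, kJ mol-1 K-1 (used in R*T*ln Q terms).
R_KJ = 8.3145e-3

#: Gas constant, L atm mol-1 K-1 (ideal-gas headspace accounting).
R_L_ATM = 0.082057

#: 1 atm in Pa.
ATM_PA = 101_325.0

#: Cultivation temperature of the thermophilic consortium (55 degC).
T_CULTURE = 328.15


def pa_to_atm(p_pa: float) -> float:
    return p_pa / ATM_PA


def atm_to_pa(p_atm: float) -> float:
    return p_atm * ATM_PA
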