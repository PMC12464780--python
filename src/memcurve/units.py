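"""Unit conversion constants.

The package keeps monolayer quantities in trough units (mN/m, Å² per
molecule) and membrane-normal quantities in MD units (nm, bar) end to end;
SI appears only at the few points where an energy or force is reported.
All factors below are exact scale conversions.
"""

#: Avogadro's constant, 1/mol (2019 SI exact value).
N_AVOGADRO = 6.02214076e23

#: Boltzmann constant, J/K (2019 SI exact value).
K_BOLTZMANN = 1.380649e-23

#: One Å²·mN/m per molecule expressed per mole: 1e-20 m² × 1e-3 N/m × N_A.
#: Converts a pressure integral of molecular area directly to J/mol.
A2_MNM_TO_J_PER_MOL = 6.02214076

#: 1 bar·nm² = 1e5 Pa × 1e-18 m² = 1e-13 N = 0.1 pN.
BAR_NM2_TO_PN = 0.1

#: 1 bar·nm³ = 1e5 Pa × 1e-27 m³ = 1e-22 J.
BAR_NM3_TO_J = 1e-22

#: nm² → Å².
NM2_TO_A2 = 100.0

#: Default absolute temperature for thermal-energy scaling, K.
DEFAULT_TEMPERATURE = 303.15


def kbt_joules(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B·T in joules at the given temperature [K]."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return K_BOLTZMANN * temperature


def bar_nm3_to_kbt(value: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy in bar·nm³ to multiples of k_B·T."""
    return value * BAR_NM3_TO_J / kbt_joules(temperature)


def kbt_to_bar_nm3(value: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy in k_B·T to bar·nm³ (inverse of :func:`bar_nm3_to_kbt`)."""
    return value * kbt_joules(temperature) / BAR_NM3_TO_J
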