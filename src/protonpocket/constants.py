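"""Physical constants and unit conversions, centralised so every module agrees.

Note on precision quotes in the literature: k_B T at 310 K is 2.577 kJ/mol
= 0.616 kcal/mol. Free-energy precisions are sometimes quoted as 0.8 kcal/mol
"equivalent to k_B T"; this table always uses the physical value.
"""

KB_KJ_PER_MOL_K: float = 0.008314462618  # Boltzmann constant, kJ/(mol K)
DEFAULT_TEMPERATURE_K: float = 310.0
KJ_PER_KCAL: float = 4.184


def kt_kj_per_mol(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy k_B T in kJ/mol."""
    return KB_KJ_PER_MOL_K * temperature_k


def kj_to_kt(energy_kj_per_mol, temperature_k: float = DEFAULT_TEMPERATURE_K):
    """Convert an energy in kJ/mol to units of k_B T."""
    return energy_kj_per_mol / kt_kj_per_mol(temperature_k)
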