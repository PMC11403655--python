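"""Physical constants and unit conventions.

All quantities in the package use a fixed unit system: lengths in nm,
times in ps, energies in kJ/mol, temperatures in K, masses in u.
No unit inference is performed on input files.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant / 1000).
KB = 0.0083144621

#: Default simulation temperature (K) for the deoxy-HbS dimer setup.
DEFAULT_TEMPERATURE = 310.0


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature
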