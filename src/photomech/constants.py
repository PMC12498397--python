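"""Physical constants and unit conventions.

Internal unit system: distances in Å, time in ps, energies in kJ/mol,
temperature in K.  Masses are user-facing in amu; internally a mass is
converted to kJ/mol·ps²/Å² (1 amu = 0.01 kJ/mol·ps²/Å²) so that
force = -dV/dx (kJ/mol/Å) divided by mass gives an acceleration in Å/ps².
"""

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144626

#: 1 amu expressed in kJ/mol·ps²/Å².
AMU_TO_INTERNAL = 0.01


def beta(temperature: float) -> float:
    """Inverse temperature 1/(k_B T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    return 1.0 / (KB * temperature)
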