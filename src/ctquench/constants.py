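"""Physical constants in wavenumber units.

All energies in this package are expressed in cm⁻¹ and all temperatures in
kelvin, so the Boltzmann constant is carried in cm⁻¹/K and the reduced
Planck constant in cm⁻¹·s.  The values are fixed to the precision below to
keep results bit-reproducible across platforms.
"""

#: Boltzmann constant, cm⁻¹ per kelvin.
KB_CM: float = 0.695035

#: Reduced Planck constant, cm⁻¹ · s.
HBAR_CM_S: float = 5.30886e-12

#: Default temperature (K): room temperature.
ROOM_T: float = 300.0


def thermal_energy(temperature: float = ROOM_T) -> float:
    """k_B·T in cm⁻¹."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_CM * temperature
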