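"""Physical constants and canonical internal units.

Canonical units used throughout the package: distances in Angstrom (gate and
ion-site distances) or nm (gate-opening reaction coordinate), time in
microseconds, concentrations in mM (bulk in M where stated), energies in
kJ/mol, temperature in K, charge in elementary charges e0, voltage in mV.
Converters live at module boundaries only.
"""

#: Boltzmann constant in kJ/mol/K (CODATA).
KB_KJMOL: float = 0.008314462618

#: Default simulation temperature (K); kT = 2.577 kJ/mol.
DEFAULT_TEMPERATURE: float = 310.0


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kJ/mol at the given temperature."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KJMOL * temperature
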