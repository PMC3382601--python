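"""Physical constants and unit conventions.

Energies are handled internally in units of kT at the reference temperature
(298 K); lengths in Angstrom, angles in degrees, DEER times in microseconds.
"""

#: Boltzmann constant, kcal / (mol K)
KB_KCAL_MOL_K = 1.987204259e-3

#: Reference temperature for the internal energy unit, K
T_REF = 298.0

#: 1 kT at the reference temperature, kcal/mol
KT_REF_KCAL_MOL = KB_KCAL_MOL_K * T_REF

#: Dipolar coupling constant for two free electrons, MHz * nm^3
DIPOLAR_CONSTANT_MHZ_NM3 = 52.04

#: Foerster-radius prefactor: R0 [A] = C * (kappa2 * n^-4 * Phi_D * J)^(1/6)
#: with the overlap integral J in M^-1 cm^-1 nm^4.
FORSTER_PREFACTOR = 0.2108


def kt_units_to_kcal(e_kt: float) -> float:
    """Convert an energy in internal kT(298 K) units to kcal/mol."""
    return e_kt * KT_REF_KCAL_MOL


def kcal_to_kt_units(e_kcal: float) -> float:
    """Convert an energy in kcal/mol to internal kT(298 K) units."""
    return e_kcal / KT_REF_KCAL_MOL


def beta_factor(temperature: float) -> float:
    """Multiplier turning an internal-unit energy into E/kT at `temperature`.

    exp(-beta_factor(T) * E_internal) is the Boltzmann factor at T kelvin.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return T_REF / temperature
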