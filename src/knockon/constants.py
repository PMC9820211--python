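"""Physical constants and unit conventions.

Internal units: length nm, time ps, energy in units of k_B * 300 K
(the reference thermal energy; landscapes, tilts and Coulomb energies are
all expressed on this fixed scale so the zero-temperature limit keeps a
finite drift while the noise vanishes).
"""
import math

KB = 1.380649e-23            # J/K
T_REF = 300.0                # K, reference temperature for reduced energies
KT_REF_J = KB * T_REF        # J
E_CHARGE = 1.602176634e-19   # C
C_LIGHT = 299_792_458.0      # m/s
AMU = 1.66053906660e-27      # kg
EPS0 = 8.8541878128e-12      # F/m

# e^2 / (4 pi eps0) in kT_ref * nm  (~55.7): screened-Coulomb prefactor
COULOMB_KT_NM = E_CHARGE**2 / (4.0 * math.pi * EPS0) / KT_REF_J * 1e9

# species registry: masses in amu, monopole charge in e
SPECIES = ("K", "W", "O", "CL")
SPECIES_MASS_AMU = {"K": 39.0983, "W": 18.015, "O": 15.999, "CL": 35.45}
SPECIES_CHARGE_E = {"K": 1.0, "W": 0.0, "O": 0.0, "CL": -1.0}

# current carried by one elementary charge per ns, in pA
PA_PER_EVENT_PER_NS = E_CHARGE / 1e-9 * 1e12  # = 160.2176634 pA


def diffusion_nm2_ps(mass_amu: float, friction_per_ps: float,
                     temperature: float = T_REF) -> float:
    """Einstein diffusion constant D = kT / (m*gamma) in nm^2/ps."""
    d_si = KB * temperature / (mass_amu * AMU * friction_per_ps * 1e12)  # m^2/s
    return d_si * 1e18 / 1e12  # nm^2/ps


def voltage_mv_to_kt(voltage_mv: float) -> float:
    """Energy drop q*U of one elementary charge over voltage_mv, in kT_ref."""
    return voltage_mv * 1e-3 * E_CHARGE / KT_REF_J
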