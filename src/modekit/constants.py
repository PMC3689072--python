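"""Physical constants and unit bridges.

Internal unit system: lengths in Å, masses in Da, energies in kcal/mol.
ENM Hessian eigenvalues therefore carry kcal mol⁻¹ Å⁻² Da⁻¹; PCA covariance
eigenvalues carry Da Å².  Thermodynamic output uses molar SI (J/mol, J/mol/K)
with the molar Boltzmann constant, and ℏ is promoted to a molar constant
(ℏ·N_A) so that ℏω/kT is dimensionless without leaving molar units.
"""

import math

AVOGADRO = 6.02214076e23  # 1/mol
KCAL_TO_J = 4184.0  # J per kcal, thermochemical calorie

BOLTZMANN_J_MOL = 8.314  # J mol⁻¹ K⁻¹
BOLTZMANN_KCAL_MOL = BOLTZMANN_J_MOL / KCAL_TO_J  # kcal mol⁻¹ K⁻¹

HBAR_SI = 1.05457148e-34  # J s (per particle)
HBAR_MOLAR = HBAR_SI * AVOGADRO  # J s mol⁻¹

# kcal mol⁻¹ Å⁻² Da⁻¹  →  s⁻² :
#   kcal/mol → J (÷N_A, ×4184); Å⁻² → m⁻² (×1e20); Da⁻¹ → kg⁻¹ (÷1.66054e-27)
# which collapses to ×4.184e26 because Da·N_A = 1 g/mol exactly in this
# convention.
ENM_EIGVAL_TO_S2 = KCAL_TO_J * 1.0e20 * 1.0e3  # = 4.184e26

EIGHT_PI2_OVER_3 = 8.0 * math.pi**2 / 3.0


def kT_kcal(temperature: float) -> float:
    """Thermal energy kT in kcal/mol at the given temperature (K)."""
    return BOLTZMANN_KCAL_MOL * temperature


def kT_J(temperature: float) -> float:
    """Thermal energy kT in J/mol at the given temperature (K)."""
    return BOLTZMANN_J_MOL * temperature
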