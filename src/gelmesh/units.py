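"""Unit conventions and conversion constants.

Internal units: lengths in Å, times in ps, masses in g/mol (Da).
Diffusion coefficients are reported in 10^-7 cm^2 s^-1, the unit used
throughout nanogel drug-transport work.

Derivation of the diffusion conversion:
    1 Å^2/ps = (1e-8 cm)^2 / (1e-12 s) = 1e-4 cm^2/s = 1e3 × 1e-7 cm^2/s
"""

# multiply a slope in Å^2/ps by this to get a D contribution in 1e-7 cm^2/s
A2_PER_PS_TO_1E7_CM2_S: float = 1.0e3

# inverse: D given in 1e-7 cm^2/s expressed in Å^2/ps
D_1E7_CM2_S_TO_A2_PER_PS: float = 1.0 / A2_PER_PS_TO_1E7_CM2_S

NM_TO_ANGSTROM: float = 10.0

AVOGADRO: float = 6.02214076e23

# g/mol and Å^3 to g/cm^3:  (m/N_A) g / (V * 1e-24 cm^3)
GMOL_PER_A3_TO_G_CM3: float = 1.0e24 / AVOGADRO


def mass_density(total_mass_gmol: float, volume_a3: float) -> float:
    """Density in g/cm^3 of ``total_mass_gmol`` Daltons in ``volume_a3`` Å^3."""
    return total_mass_gmol / volume_a3 * GMOL_PER_A3_TO_G_CM3


def box_edge_for_density(total_mass_gmol: float, density_g_cm3: float) -> float:
    """Cubic box edge (Å) holding ``total_mass_gmol`` at ``density_g_cm3``."""
    volume = total_mass_gmol / density_g_cm3 * GMOL_PER_A3_TO_G_CM3
    return volume ** (1.0 / 3.0)
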