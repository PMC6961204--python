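"""Physical constants and unit conversions.

Internal convention: lengths in Å, times in ps, temperatures in K,
spring constants in pN/nm, energies in kJ/mol.  Conversions between the
Å-based geometry world and the pN/nm mechanics world are explicit and
live here so no other module hard-codes a factor.
"""

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K = 1.380649e-2 pN·nm/K).
KB_PN_NM_PER_K = 0.0138065

#: Default bath temperature (K) for all fluctuation analyses.
DEFAULT_TEMPERATURE_K = 298.0

#: 1 nm = 10 Å.
ANGSTROM_PER_NM = 10.0

#: pN·nm per molecule → kJ/mol  (1 pN·nm = 1e-21 J; × N_A / 1000).
KJ_PER_MOL_PER_PN_NM = 0.60221


def thermal_variance_A2(k_pn_per_nm: float, temperature_K: float) -> float:
    """Stationary variance (Å²) of a harmonic mode of stiffness ``k`` (pN/nm).

    Equipartition: Var[x] = k_B·T / k, computed in nm² and converted to Å².
    """
    var_nm2 = KB_PN_NM_PER_K * temperature_K / k_pn_per_nm
    return var_nm2 * ANGSTROM_PER_NM**2
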