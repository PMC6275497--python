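"""Internal unit system and physical constants.

Energies are kJ/mol, lengths nm, times ps (simulation-internal) or s
(kinetic model), temperatures K.  Forces are kept in kJ/mol/nm internally
and converted to pN only at reporting boundaries.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083145

#: 1 kJ mol^-1 nm^-1 expressed in pN
PN_PER_KJ_MOL_NM = 1.66054

#: 1 kcal in kJ
KJ_PER_KCAL = 4.184


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at ``temperature`` (K)."""
    return KB * temperature


def force_to_pn(f_kj_mol_nm: float) -> float:
    """Convert a force from kJ/mol/nm to pN."""
    return f_kj_mol_nm * PN_PER_KJ_MOL_NM


def force_from_pn(f_pn: float) -> float:
    """Convert a force from pN to kJ/mol/nm."""
    return f_pn / PN_PER_KJ_MOL_NM
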