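"""Physical unit-conversion constants.

Internal units follow the conventions of the analysis: lengths in Å, times
in ns (ps for pulling traces), charges in elementary charges e, forces in pN,
angles in degrees.
"""

#: Dipole conversion: 1 e·Å in Debye.
EA_TO_DEBYE = 4.8032

#: 1 kcal/mol in Joule (thermochemical calorie, CODATA Avogadro constant).
_KCAL_PER_MOL_J = 4184.0 / 6.02214076e23

#: 1 pN·Å in Joule.
_PN_A_J = 1e-12 * 1e-10

#: Spring constants: 1 kcal mol⁻¹ Å⁻¹ expressed in pN/Å (= 69.477).
KCAL_MOL_A_TO_PN_A = _KCAL_PER_MOL_J / _PN_A_J

#: Energies: 1 pN·Å in eV.
PN_A_TO_EV = _PN_A_J / 1.602176634e-19

#: Energies: 1 pN·Å in kcal/mol.
PN_A_TO_KCAL_MOL = 1.0 / KCAL_MOL_A_TO_PN_A

#: 1 eV in kcal/mol (for reporting pulling energies).
EV_TO_KCAL_MOL = (1.602176634e-19) / _KCAL_PER_MOL_J
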