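"""Package-wide unit conventions.

Everything follows GROMACS conventions: lengths in nm, times in ps,
energies in kJ/mol, temperatures in K, angles in degrees at API
boundaries (radians internally where noted), masses in g/mol.
"""

#: Boltzmann constant, kJ/(mol K).
KB = 0.0083144626

#: Default molar masses, g/mol.
MW_DISACCHARIDE = 342.30
MW_WATER = 18.015

#: Reference temperature used throughout, K.
T_REF = 298.0
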