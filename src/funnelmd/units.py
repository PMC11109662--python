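"""Physical constants and the package-wide unit policy.

Internal units follow the GROMACS convention: length nm, energy kJ/mol,
time ps, mass amu, temperature K.  PDB ingestion converts Å -> nm at the
boundary; binding free energies are reported in kcal/mol and dissociation
constants in nM (the units the field prints); RAMD parameters keep their
conventional kcal mol^-1 Å^-1 / fs / Å units and are converted on use.
"""

KB = 0.0083144626  # Boltzmann constant, kJ mol^-1 K^-1 (= molar gas constant R)
N_AVOGADRO = 6.02214076e23  # mol^-1
KJ_PER_KCAL = 4.184
ANGSTROM_PER_NM = 10.0
FS_PER_PS = 1000.0

#: molecules per nm^3 at a 1 M reference concentration
MOLAR_PER_NM3 = N_AVOGADRO * 1e-24


def kT(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol."""
    return KB * temperature


def kcal(x_kj: float) -> float:
    """Convert kJ/mol to kcal/mol."""
    return x_kj / KJ_PER_KCAL
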