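"""Physical constants used across the package.

All CODATA 2018 values. Kept in one table so unit conversions are auditable:
every module that turns charges into Debye, barriers into timescales, or
box volumes into concentrations imports from here rather than embedding
its own literals.
"""

#: Elementary charge, C
ELEMENTARY_CHARGE = 1.602176634e-19

#: Vacuum permittivity, F/m
EPSILON_0 = 8.8541878128e-12

#: Avogadro constant, 1/mol
AVOGADRO = 6.02214076e23

#: Boltzmann constant, J/K
BOLTZMANN = 1.380649e-23

#: Gas constant, kcal/(mol K)
R_KCAL = 1.987204259e-3

#: 1 Debye in C·m
DEBYE = 3.33564e-30

#: Dipole of 1 e separated by 1 Å, in Debye (e·Å → D)
E_ANGSTROM_TO_DEBYE = ELEMENTARY_CHARGE * 1e-10 / DEBYE  # ≈ 4.80320

#: 1 Å in m
ANGSTROM = 1e-10

#: 1 ns in s
NANOSECOND = 1e-9

#: 1 kcal in J
KCAL = 4184.0

#: Å²/ns → m²/s
ANG2_PER_NS_TO_M2_PER_S = ANGSTROM**2 / NANOSECOND  # 1e-11

#: Standard atomic masses (amu) for elements the readers and the synthetic
#: template emit. Unknown elements fall back to 12.0.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "FE": 55.845,
    "ZN": 65.38,
    "MG": 24.305,
    "K": 39.098,
    "CA": 40.078,
}

DEFAULT_MASS = 12.0
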