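"""Physical constants and unit conventions.

Internal units follow the GROMACS convention throughout the package:
lengths in nm, energies in kJ/mol, times in ps/ns, charges in units of the
elementary charge, temperatures in K.
"""

import math

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_COULOMB = 138.935458

#: Molar gas constant in kJ mol^-1 K^-1.
R_GAS = 8.314462618e-3

#: Default physiological temperature (K).
T_DEFAULT = 310.0

# SI values used only inside the Schlitter entropy prefactor.
KB_SI = 1.380649e-23          # J/K
HBAR_SI = 1.054571817e-34     # J s
AMU_SI = 1.66053906660e-27    # kg
NM_SI = 1.0e-9                # m
E_SQUARED = math.e ** 2

#: Ion Lennard-Jones parameters (sigma nm, epsilon kJ/mol) of the CM-type
#: divalent-cation model used for Zn2+ and Ca2+, and formal charges.
ION_LJ = {
    "ZN": (0.226466454151, 0.01381916624),
    "CA": (0.293818397243, 0.44320568080),
}
ION_CHARGE = {"ZN": 2.0, "CA": 2.0, "MG": 2.0, "NA": 1.0, "CL": -1.0, "K": 1.0}

#: Default continuum-solvation parameters: solute/water dielectric constants,
#: SASA surface-tension gamma (kJ mol^-1 nm^-2) and offset b (kJ/mol).
EPS_SOLUTE = 4.0
EPS_WATER = 80.0
SASA_GAMMA = 2.27
SASA_B = 3.85

#: Default probe radius for solvent-accessible surface area (nm).
SASA_PROBE = 0.14
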