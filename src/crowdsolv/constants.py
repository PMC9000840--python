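"""Physical constants and the single unit-conversion table.

Internal units everywhere: length nm, time ps, temperature K, charge e,
energy kJ/mol, mass g/mol.  Reported units follow the conventions of the
solution-MD literature: viscosity in mPa·s, diffusion in 1e-5 cm²/s.

Every unit conversion in the package goes through this module; the
constants below are defined exactly once.
"""

# Boltzmann constant, J/K (exact, SI 2019)
K_B = 1.380649e-23

# Avogadro constant, 1/mol (exact, SI 2019)
N_A = 6.02214076e23

# Coulomb conversion factor f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_KJMOL_NM_E2 = 138.935458

# Yeh–Hummer lattice constant for a cubic periodic box
XI_CUBIC = 2.837297

# --- length ---
ANGSTROM_PER_NM = 10.0
NM_PER_ANGSTROM = 0.1
M_PER_NM = 1e-9
CM_PER_NM = 1e-7

# --- time ---
S_PER_PS = 1e-12

# --- pressure ---
PA_PER_BAR = 1e5

# --- volume ---
M3_PER_NM3 = 1e-27
ML_PER_NM3 = 1e-21  # 1 mL = 1 cm^3 = 1e21 nm^3

# --- diffusion ---
# 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s = 1000 x 1e-5 cm^2/s
D_NM2_PS_TO_1E5_CM2_S = 1000.0

# --- viscosity ---
PAS_PER_MPAS = 1e-3
MPAS_PER_PAS = 1e3

# --- density ---
KG_M3_PER_G_ML = 1000.0
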