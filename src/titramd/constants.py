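"""Project-wide physical constants and unit conventions.

Units are fixed across the package: lengths in Angstrom, energies in
kcal/mol, charges in elementary charge units, dipoles in e*Angstrom,
quadrupoles in e*Angstrom^2, polarizabilities in Angstrom^3, time in
femtoseconds, temperature in Kelvin, masses in amu.
"""

# Coulomb constant in kcal*Angstrom/(mol*e^2)
COULOMB = 332.063713

# Boltzmann constant in kcal/(mol*K)
KB = 0.0019872041

# ln(10), used by the pH bias and replica-exchange criterion
import math

LN10 = math.log(10.0)

# Bohr radius in Angstrom: Tinker-style parameter files give dipoles in
# e*Bohr and quadrupoles in e*Bohr^2; both are converted on load.
BOHR = 0.52917721067

# Velocity/time unit bookkeeping for Langevin dynamics:
# with x in Angstrom, t in fs, m in amu, kinetic energy (1/2) m v^2 carries
# a factor converting amu*A^2/fs^2 -> kcal/mol.
# 1 amu*A^2/fs^2 = 1e10 J/kg * amu = 1.66054e-27*1e10 J = ... expressed per
# mole: 1 amu*(A/fs)^2 * N_A = 2390.057 kcal/mol.
AMU_A2_FS2_TO_KCAL = 2390.05736
# Force conversion: acceleration (A/fs^2) = force(kcal/mol/A) / m(amu) / this
KCAL_TO_AMU_A2_FS2 = 1.0 / AMU_A2_FS2_TO_KCAL
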