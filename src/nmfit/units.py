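"""Internal unit system and physical constants.

All quantities in the package use the AKMA-like system:
length in Å, time in fs, mass in atomic mass units (g/mol),
energy in kcal/mol, temperature in K.
"""

# 1 amu * (Å/fs)^2 expressed in kcal/mol:
#   1 g/mol * (1e-10 m / 1e-15 s)^2 = 1e7 J/mol = 1e7/4184 kcal/mol
KCAL_PER_AMU_A2_FS2 = 1.0e7 / 4184.0

# Boltzmann constant in kcal/mol/K
KB = 0.0019872041


def kinetic_energy(masses, velocities):
    """Kinetic energy in kcal/mol of velocities in Å/fs, masses in amu."""
    import numpy as np

    v = np.asarray(velocities, dtype=float).reshape(-1, 3)
    m = np.asarray(masses, dtype=float)
    return 0.5 * float(np.sum(m * np.sum(v * v, axis=1))) * KCAL_PER_AMU_A2_FS2


def kinetic_temperature(masses, velocities):
    """Instantaneous kinetic temperature in K (3N degrees of freedom)."""
    import numpy as np

    n = np.asarray(masses).size
    ke = kinetic_energy(masses, velocities)
    return 2.0 * ke / (3.0 * n * KB)
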