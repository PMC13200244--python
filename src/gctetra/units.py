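"""Unit system used throughout the package.

Internal model units: energy in eV, time in fs, distances in Å.
Mass-weighted nuclear coordinates absorb the mass, so kinetic energy is
``p**2 / 2`` and a harmonic mode contributes ``omega**2 * x**2 / 2`` with
``omega`` in rad/fs.  In these units the Wigner widths of a ground-state
harmonic mode are ``std(x) = sqrt(hbar / (2 omega))`` and
``std(p) = sqrt(hbar omega / 2)``.
"""

# hbar in eV*fs
HBAR = 0.6582119569

# 1 hartree in eV (CODATA)
EV_PER_HARTREE = 27.211386245988

# cm^-1 -> rad/fs angular frequency
CM1_TO_RADFS = 2.99792458e10 * 2.0 * 3.141592653589793 * 1e-15
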