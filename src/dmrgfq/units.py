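"""Physical constants and unit conversions.

All internal quantities are in Hartree atomic units; Ångström is accepted
at I/O boundaries and converted on entry.
"""

BOHR_PER_ANGSTROM = 1.8897261254578281
ANGSTROM_PER_BOHR = 1.0 / BOHR_PER_ANGSTROM
EV_PER_HARTREE = 27.211386245988


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR
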