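"""Unit system: energies in wavenumbers (cm^-1), time in femtoseconds.

All Hamiltonian and bath quantities are specified in cm^-1, the standard
spectroscopic unit for pigment-protein complexes.  Dynamical quantities
(Liouvillian, rates) are expressed in angular frequency, rad fs^-1, via

    1 cm^-1  =  2*pi*c  rad fs^-1,   c in cm fs^-1.

Temperatures are in kelvin; the Boltzmann constant is carried in
cm^-1 K^-1 so thermal occupation factors are computed directly from
wavenumber energy gaps.
"""

from __future__ import annotations

import numpy as np

#: speed of light in cm fs^-1 (exact, CODATA c = 2.99792458e10 cm s^-1)
C_CM_PER_FS: float = 2.99792458e-5

#: conversion factor: multiply an energy in cm^-1 to get rad fs^-1
CM1_TO_RAD_PER_FS: float = 2.0 * np.pi * C_CM_PER_FS

#: Boltzmann constant in cm^-1 K^-1
KB_CM1_PER_K: float = 0.695034800


#: cm^-1 -> rad ps^-1 conversion (used by the reference rate convention)
CM1_TO_RAD_PER_PS: float = CM1_TO_RAD_PER_FS * 1000.0


def cm1_to_angfreq(energy_cm1):
    """Convert an energy/wavenumber in cm^-1 to angular frequency in rad fs^-1."""
    return np.asarray(energy_cm1, dtype=float) * CM1_TO_RAD_PER_FS


def angfreq_to_cm1(omega_rad_fs):
    """Convert an angular frequency in rad fs^-1 back to cm^-1."""
    return np.asarray(omega_rad_fs, dtype=float) / CM1_TO_RAD_PER_FS


def thermal_energy_cm1(temperature_k: float) -> float:
    """k_B * T in cm^-1."""
    return KB_CM1_PER_K * float(temperature_k)
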