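"""Frenkel exciton model of the seven-site FMO complex.

The system Hamiltonian is the Adolphs-Renger seven-site Hamiltonian for one
subunit of the Fenna-Matthews-Olson pigment-protein complex: diagonal entries
are site energies eps_i of the seven bacteriochlorophyll pigments, off-diagonal
entries the inter-site electronic couplings J_ij, all in cm^-1.

Each site couples to its own, statistically independent harmonic environment.
The microscopic bath modes are summarised by a Drude-Lorentz (overdamped
Brownian oscillator) spectral density

    J_env(omega) = 2 * lam * omega * gamma / (omega**2 + gamma**2)

with reorganization energy ``lam`` and bath relaxation rate (characteristic
frequency) ``gamma``.  The reorganization energy is recovered from the
spectral density through lam = (1/pi) * int_0^inf J(omega)/omega domega,
which for the Drude-Lorentz form integrates to lam exactly - implemented
here by numerical quadrature as a self-consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "SiteHamiltonian",
    "BathParameters",
    "build_fmo_hamiltonian",
    "spectral_density",
    "reorganization_energy",
    "reorganization_shift",
]

N_SITES = 7

# Adolphs-Renger seven-site Hamiltonian, cm^-1.  The (4,7)/(7,4) coupling is
# -63.3 cm^-1 (the Adolphs-Renger value); the matrix is symmetric by
# construction.
_FMO_HAMILTONIAN_CM1 = np.array(
    [
        [12410.0, -87.7, 5.5, -5.9, 6.7, -13.7, -9.9],
        [-87.7, 12530.0, 30.8, 8.2, 0.7, 11.8, 4.3],
        [5.5, 30.8, 12210.0, -53.5, -2.2, -9.6, 6.0],
        [-5.9, 8.2, -53.5, 12320.0, -70.7, -17.0, -63.3],
        [6.7, 0.7, -2.2, -70.7, 12480.0, 81.1, -1.3],
        [-13.7, 11.8, -9.6, -17.0, 81.1, 12630.0, 39.7],
        [-9.9, 4.3, 6.0, -63.3, -1.3, 39.7, 12440.0],
    ]
)


@dataclass(frozen=True)
class SiteHamiltonian:
    """Seven-site system Hamiltonian in the site (pigment) basis, cm^-1.

    Storage is 0-based; site labels reported to users are 1-based
    (``site_labels`` maps row/column index -> pigment number).
    """

    matrix: np.ndarray
    site_labels: tuple = tuple(range(1, N_SITES + 1))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_SITES, N_SITES):
            raise ValueError(f"expected a {N_SITES}x{N_SITES} matrix, got {m.shape}")
        if not np.array_equal(m, m.T):
            raise ValueError("site Hamiltonian must be exactly symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def site_energies(self) -> np.ndarray:
        """Diagonal site energies eps_i, cm^-1."""
        return np.diag(self.matrix)

    def eigenbasis(self):
        """Exciton energies and (real, orthonormal) eigenvectors.

        Returns (energies_cm1, vectors) with vectors[:, a] the exciton
        state |a> expanded in the site basis.
        """
        return np.linalg.eigh(self.matrix)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "SiteHamiltonian":
        m = np.loadtxt(path, delimiter=",", dtype=float)
        # symmetrize exactly against decimal round-trip noise
        m = (m + m.T) / 2.0
        return cls(matrix=m)


@dataclass(frozen=True)
class BathParameters:
    """Drude-Lorentz bath: one identical, independent bath per site.

    lam
        reorganization energy, cm^-1 (system-bath coupling strength).
    gamma
        bath relaxation rate / characteristic frequency, cm^-1.
    temperature
        bath temperature, K.
    """

    lam: float
    gamma: float
    temperature: float

    def __post_init__(self):
        for name in ("lam", "gamma", "temperature"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")


def build_fmo_hamiltonian() -> SiteHamiltonian:
    """Return the seven-site FMO Hamiltonian (cm^-1), symmetric by construction."""
    return SiteHamiltonian(matrix=_FMO_HAMILTONIAN_CM1.copy())


def spectral_density(omega, bath: BathParameters):
    """Drude-Lorentz spectral density J_env(omega), cm^-1, for omega >= 0 in cm^-1.

    J vanishes at omega = 0 and peaks at J(gamma) = lam.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("spectral density is defined for omega >= 0")
    return 2.0 * bath.lam * omega * bath.gamma / (omega**2 + bath.gamma**2)


def reorganization_energy(bath: BathParameters, *, limit: float = np.inf) -> float:
    """Recover lambda by quadrature of (1/pi) * int_0^inf J(omega)/omega domega.

    For the Drude-Lorentz density the integral is analytic and equals
    ``bath.lam``; the quadrature serves as a self-consistency check of the
    spectral-density implementation.
    """
    integrand = lambda w: 2.0 * bath.lam * bath.gamma / (w**2 + bath.gamma**2)
    value, abserr = integrate.quad(integrand, 0.0, limit, limit=200)
    value /= np.pi
    if abserr / max(abs(value), 1e-300) > 1e-6:
        raise ArithmeticError(
            f"reorganization-energy quadrature did not converge: "
            f"value={value}, abserr={abserr}"
        )
    return value


def reorganization_shift(bath: BathParameters, n_sites: int = N_SITES) -> np.ndarray:
    """Diagonal reorganization counter term lam_i * |i><i| as an array, cm^-1.

    Computed and exposed for completeness; by default it is *not* added to
    the coherent Hamiltonian used by the Lindblad propagator (the convention
    that reproduces the reference dynamics - see lindblad module).
    """
    return np.full(n_sites, bath.lam, dtype=float)
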