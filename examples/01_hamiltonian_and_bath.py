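"""Build the seven-site FMO exciton Hamiltonian and its Drude-Lorentz bath.

Prints the site energies, the exciton (eigen) energies, and two sanity
checks on the bath spectral density: its peak value equals the
reorganization energy, and the reorganization integral recovers lambda.
"""

import numpy as np

from lindnet import BathParameters, build_fmo_hamiltonian
from lindnet.exciton import reorganization_energy, spectral_density

H = build_fmo_hamiltonian()
print("site energies (cm^-1):", np.diag(H.matrix).astype(int))

energies, vectors = H.eigenbasis()
print("exciton energies (cm^-1):", np.round(energies, 1))
# the lowest exciton is dominated by pigment 3, the gateway to the
# reaction center:
weights = vectors[:, 0] ** 2
print("site weights of the lowest exciton:", np.round(weights, 3))

bath = BathParameters(lam=70.0, gamma=175.0, temperature=70.0)
print(f"J(gamma) = {spectral_density(bath.gamma, bath):.1f} cm^-1 "
      f"(= lambda = {bath.lam})")
print(f"(1/pi) int J(w)/w dw = {reorganization_energy(bath):.6f} cm^-1")
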