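"""lindnet: non-recursive neural surrogate for FMO excitation-energy transfer.

Reference dynamics come from a local-thermalising Lindblad master equation
for the seven-site Fenna-Matthews-Olson exciton Hamiltonian; the surrogate
is a 1D convolutional network that maps (bath parameters, initial site,
density-matrix row, logistic time encoding) directly to the reduced density
matrix at that time - any time, including the t -> infinity asymptote,
without step-wise propagation.
"""

from .exciton import (
    BathParameters,
    SiteHamiltonian,
    build_fmo_hamiltonian,
    reorganization_energy,
    spectral_density,
)
from .lindblad import (
    DensityTrajectory,
    LindbladGenerator,
    build_generator,
    propagate,
    site_excitation,
    states_at_times,
    stationary_state,
)

__version__ = "0.1.0"


def __getattr__(name):
    # lazy imports to keep `import lindnet` light for physics-only use
    if name in ("SurrogateSpec", "SurrogateCNN", "TrainedSurrogate"):
        from . import surrogate

        return getattr(surrogate, name)
    if name in ("predict_state", "predict_trajectory", "scan_site3", "ErrorReport"):
        from . import predictor

        return getattr(predictor, name)
    if name in ("RunConfig", "run_config", "make_fixtures"):
        from . import pipeline

        return getattr(pipeline, name)
    raise AttributeError(f"module 'lindnet' has no attribute {name!r}")
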