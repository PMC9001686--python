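# lindnet

**Non-recursive neural surrogate for excitation-energy transfer in the
FMO light-harvesting complex, with an exact local-thermalising Lindblad
reference propagator.**

Simulating how an exciton migrates through the Fenna–Matthews–Olson (FMO)
pigment–protein complex is an open-quantum-system problem: the reduced
density matrix ρ(t) of the seven bacteriochlorophyll sites evolves under the
system Hamiltonian while each site is damped by its own protein environment.
Conventional dissipative propagators are *recursive* — every step needs the
previous one — so long horizons are expensive and errors accumulate.

`lindnet` implements the alternative: a convolutional network that learns
the map

```
(m, n, γ/γ_max, λ/λ_max, T/T_max, f_0(t) … f_99(t))  ─→  row n of ρ(t)
```

where `m ∈ {0, 1}` encodes the initially excited site (1 or 6),
`n ∈ {1..7}` labels the density-matrix row, (λ, γ, T) are the Drude–Lorentz
bath parameters (reorganization energy, bath relaxation rate, temperature),
and the `f_k(t) = 1 / (1 + 15·e^−(t + c_k))`, `c_k = 5k − 1` (t in ps) are a
bank of 100 shifted logistic time encodings. Because every `f_k → 1` as
`t → ∞`, the all-ones vector is a legal input and the network predicts the
**asymptotic state directly** — any time, in any order, with no propagation.

The package contains everything needed to build such a surrogate from
scratch:

* `lindnet.exciton` — the seven-site exciton Hamiltonian (site energies
  12410…12630 cm⁻¹, couplings such as J₁₂ = −87.7 cm⁻¹) and the
  Drude–Lorentz spectral density J(ω) = 2λωγ/(ω² + γ²);
* `lindnet.lindblad` — the local-thermalising Lindblad master equation
  (LTLME): site projectors decomposed into exciton-basis frequency
  components, rates 2J(ω)[n(ω)+1] / 2J(ω)n(ω) with Bose–Einstein detailed
  balance, propagation by iterated one-step matrix exponential (an adaptive
  ODE route is kept as an independent cross-check), stationary states from
  the generator's null space;
* `lindnet.dataset` — parameter grids (11 λ × 12 γ × 15 T × 2 initial
  sites = 3960 trajectories), greedy farthest-point train/validation/test
  splits, the vanishing-gradient horizon rule (|dρ_nn/dt| < 10⁻¹⁰ fs⁻¹ for
  10 consecutive 5 fs steps), region-wise time sampling, featurization;
* `lindnet.surrogate` — the 2,379,663-parameter 1D-CNN
  (conv 90 → conv 70 → maxpool → 3×dense 512 → dense 13) implemented
  directly on numpy with explicit backprop and Adam — no deep-learning
  framework needed, seeded and deterministic;
* `lindnet.predictor` — Hermitian state reassembly from row predictions,
  channel-wise MAE/RMSE error reports, and parameter scans (e.g. ρ₃₃ at
  0.5 ps over a (λ, γ, T) box to find the fastest-transfer conditions).

## Worked example

```python
from lindnet import (BathParameters, build_fmo_hamiltonian, build_generator,
                     propagate, site_excitation, stationary_state)

gen = build_generator(build_fmo_hamiltonian(),
                      BathParameters(lam=310, gamma=30, temperature=25))
for site in (6, 1):
    traj = propagate(gen, site_excitation(site), t_max=500.0)  # fs
    print(site, round(traj.populations[-1][2], 4))
print(round(stationary_state(gen)[2, 2].real, 4))
```

prints

```
6 0.7614
1 0.6389
0.7782
```

i.e. under the fastest-transfer bath conditions (γ = 30 cm⁻¹,
λ = 310 cm⁻¹, T = 25 K) an excitation starting on site 6 delivers 76% of
its population to site 3 — the gateway to the reaction center — within half
a picosecond, while the more coherent site-1 pathway delivers 64%; at
infinite time site 3 holds 78%. The `examples/` directory walks every
capability the same way (Hamiltonian and bath, reference dynamics, dataset
construction, training, scanning and asymptotes); each script prints the
numbers it computes and a line on what they mean.

A thin CLI mirrors the pipeline for shell use:

```bash
lindnet generate  -c config.yaml -o traj.h5      # reference trajectories
lindnet featurize -c config.yaml -i traj.h5 -o train.h5
lindnet train     -c config.yaml --train-set train.h5 --val-set val.h5 -o model/
lindnet predict   -m model/ --lam 70 --gamma 175 --temperature 70 --site 1 -o pred.csv
lindnet scan      -m model/ -o scan.csv
lindnet reference --lam 310 --gamma 30 --temperature 25 --site 6 -o pops.csv
```

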