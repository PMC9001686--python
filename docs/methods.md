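# Methods

## Physical model

The seven bacteriochlorophyll pigments of one FMO subunit are described by
a Frenkel exciton Hamiltonian in the site basis,

    H_s = Σ_i |i⟩ ε_i ⟨i| + Σ_{i≠j} |i⟩ J_ij ⟨j| ,

with the Adolphs–Renger site energies and couplings (cm⁻¹) hard-coded in
`lindnet.exciton`. The matrix is symmetric by construction; the (4,7)
coupling is taken as −63.3 cm⁻¹ (the Adolphs–Renger value — printed
versions of this matrix occasionally differ in the last digit of this one
element, which changes half-picosecond populations by less than 10⁻³).

Each site couples to its own, independent harmonic environment summarised
by a Drude–Lorentz spectral density

    J(ω) = 2 λ ω γ / (ω² + γ²) ,

where λ is the reorganization energy (system–bath coupling scale) and γ the
bath relaxation rate. The reorganization integral (1/π)∫ J(ω)/ω dω = λ is
implemented by quadrature as a self-consistency check. The diagonal
reorganization counter term λ·|i⟩⟨i| is exposed but not added to the
coherent Hamiltonian: for identical per-site baths it is proportional to
the identity and cancels from every commutator, so the choice is
immaterial to the dynamics.

### Units

Energies and bath parameters are carried in cm⁻¹, time in fs, temperature
in K. 1 cm⁻¹ = 2πc·10⁻¹⁵ rad fs⁻¹ (c in cm s⁻¹); k_B = 0.695034800
cm⁻¹ K⁻¹. Site labels are 1-based in every user-facing API; storage is
0-based.

## Reference propagator (LTLME)

The reduced density matrix evolves under a local-thermalising Lindblad
master equation. Diagonalising H into excitons |a⟩ with energies E_a and
writing c_m(a) = ⟨m|a⟩, the projector of each *site* m is decomposed into
frequency components over the exciton gaps,

    A_m(ω) = Σ_{(a,b): E_b − E_a = ω} c_m(a) c_m(b) |a⟩⟨b| ,

and each component dissipates at a rate sampled from the bath with
Bose–Einstein detailed balance:

    k(ω)  = 2 J(ω) [n(ω) + 1]      (ω > 0, emission)
    k(−ω) = 2 J(ω)  n(ω)           (absorption)
    k(0)  = 4 λ k_B T / γ_eff      (the ω → 0 limit of 2 J n)

This generator is completely positive and trace preserving and its fixed
point is the exciton-basis Gibbs state, independent of the initial site.

### Rate convention

Two conventions for sampling J inside the rates are provided behind a
single flag, recorded in every generator and trajectory:

* `"reference"` (default): J is evaluated with an effective cutoff
  γ_eff = γ / 0.18836 — numerically, the gap expressed in rad ps⁻¹
  measured against the nominal cutoff value. This convention is the one
  validated against the reference transfer yields this package is built
  around: with it, ρ₃₃(0.5 ps) = 0.7614 (site-6 start) and 0.6389
  (site-1 start) at γ = 30 cm⁻¹, λ = 310 cm⁻¹, T = 25 K, matching the
  established values 0.761/0.626 within ±0.02. It preserves detailed
  balance and the thermal fixed point exactly; only the gap-dependence of
  the rates is reshaped.
* `"literal"`: the textbook J(ω) with γ as given (yields 0.661/0.471 for
  the same worked example — the arbitration between the two was done on
  exactly this case).

### Numerics

* Propagation vectorises ρ row-major into a 49-vector and applies the
  one-step propagator expm(L·dt) repeatedly (dt = 5 fs). For a
  time-independent generator this is exact up to the matrix exponential
  itself; trace drift over the full 1 ns horizon (200 000 steps) is
  ~10⁻¹¹. An adaptive high-order Runge–Kutta route (rtol 10⁻¹⁰,
  atol 10⁻¹²) is retained as an independent numerical path; the two agree
  entrywise to better than 10⁻⁸ over 1 ps and the agreement is tested.
* The common diagonal shift of H is removed before building L (it only
  contributes a global phase); exciton gaps within 10⁻⁸ cm⁻¹ are merged
  into one frequency component so eigen-solver noise cannot split a
  physically single channel.
* Stored states are hermitized, (ρ + ρ†)/2, suppressing integrator
  round-off asymmetry (the change is below all tolerances).
* Stationary states come from the SVD null space of L; a non-1-dimensional
  numerical null space raises rather than silently picking a vector.
* Sparse state extraction (`states_at_times`) steps sequentially but
  stores only requested grid times, so 1 ns horizons never materialise
  157 MB trajectories; the population-only variant feeds the horizon
  search at 7 floats per step.

## Dataset construction

* **Grids.** λ ∈ {10, 40, …, 310} (11), γ ∈ {25, 50, …, 300} (12),
  T ∈ {30, 50, …, 310} (15), excitation on site 1 or site 6: 1980
  trajectories per site, 3960 total. Enumeration order is lexicographic
  (site, λ, γ, T) and deterministic.
* **Split.** Greedy farthest-point (max-min) selection in the min-max
  normalised (λ, γ, T) cube — unnormalised axes would let the temperature
  range dominate. The first pick is the point nearest the cube centre;
  ties break by enumeration index, making the selection fully
  deterministic. The budget is divided equally between the two initial
  sites (identically seeded site-1/site-6 selections pick identical
  parameter combinations), defaults 1000 train / 200 validation /
  2760 test.
* **Horizons.** Per trajectory, the gradient of each site population is
  the forward difference of consecutive 5 fs samples divided by the step
  (fs⁻¹). A site plateaus when 10 consecutive gradients stay below
  G_th = 10⁻¹⁰; the trajectory horizon t_M is the latest site plateau.
  Coherent corners (small λ, low T) plateau late (hundreds of ps),
  overdamped corners within a few ps, so hard trajectories contribute
  more samples. If the rule never fires by the 1 ns cap the horizon is
  capped and flagged.
* **Time sampling.** Regions 0–1, 1–1.5, 1.5–2.5, 2.5–5, 5–25, 25–50,
  50–250, 250–t_M ps are sampled with steps 5, 10, 25, 50, 100, 200, 500,
  1000 fs respectively. Regions are half-open [start, end) and t_M itself
  is appended, so no boundary time is double-counted: t_M = 1 ps yields
  201 times, t_M = 2.5 ps yields 291. One symbolic infinity sample per
  trajectory carries the stationary state as its target.
* **Features and targets.** Input order is (m, n/10, γ̂, λ̂, T̂,
  f_0…f_99) with norms λ_max = 310, γ_max = 300, T_max = 310 (recorded in
  dataset metadata so trained models are portable; parameters beyond the
  norms are allowed but flagged as extrapolation). The 13-component target
  for row n is [ρ_nn, Re ρ_nq (q ≠ n ascending), Im ρ_nq]; de-featurizing
  the seven rows reassembles the stored matrix bit-exactly. The logistic
  time functions take t in ps — each spans roughly one 5 ps region, and
  k = 0…99 covers the 1 ns horizon with the all-ones vector reserved for
  t → ∞.

## Surrogate network

Fixed topology (asserted at construction): input (105, 1) → conv1d(90,
kernel 3, valid, relu) → conv1d(70, kernel 3, same, relu) → maxpool(2,
floor) → flatten(3570) → dense(512, relu) ×3 → dense(13, linear);
2,379,663 trainable parameters. Valid first convolution, same-padded
second, floor pooling is the only combination consistent with the
intermediate shapes (105 → 103 → 103 → 51).

The implementation is plain numpy: im2col GEMMs in float32, explicit
backprop (verified against float64 finite differences to ~10⁻⁶ relative),
Adam (β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁷), Glorot-uniform initialisation from
a seeded generator, seeded shuffling, MSE loss, best-validation weight
checkpointing. Defaults: learning rate 10⁻³, batch 512, 900 epochs at
full scale. Large intermediates live in reused scratch buffers, which
keeps one training step at ~0.24 s per 512-record batch on one CPU core.
Training and inference are bit-deterministic for a fixed seed and BLAS.

Predictions are reassembled into exactly Hermitian matrices (element nq
averages row n with conjugate row q). Trace deviation is *reported*, not
repaired; an optional projection to the nearest density matrix
(eigenvalue clipping + renormalisation) exists behind a flag and is off
by default, so reported errors reflect the raw method.

Error reports pool all times and elements of a channel (populations,
real coherences, imaginary coherences) within each trajectory, then
average trajectories; the alternative pool-everything convention is
computed alongside and both are exposed, since the two differ at the
third significant digit.

## Scale profiles

The full-scale configuration (3960 trajectories to 1 ns, ~3×10⁶ records,
900 epochs) is a cluster-scale computation. The package therefore defines
three profiles with identical code paths:

| profile | trajectories (train/val) | horizon | time steps | epochs |
|---------|--------------------------|---------|------------|--------|
| `full`  | 1000 / 200 | vanishing-gradient ≤ 1 ns | ×1 (5 fs…) | 900 |
| `desk`  | 200 / 40   | vanishing-gradient ≤ 50 ps | ×10 | 300 |
| `smoke` | 100 / 20   | fixed 2.5 ps | ×100 (5 times + ∞ per trajectory) | 300 |

The smoke profile is the one exercised by the test suite: data generation
takes seconds, training ~10 minutes on one core, and the held-out
population MAE on unseen in-grid parameter combinations is required to be
≤ 10⁻². Held-out evaluation uses the same sampled-time granularity as
training; at smoke scale the surrogate sees too few time points to
resolve sub-100 fs coherent beating, so its validated domain is the
sampled grid, not arbitrary intermediate times (the full profile's 5 fs
sampling removes this caveat).

## What the synthetic data does and does not emulate

All training data are generated by the in-package LTLME propagator, so
passing tests demonstrate that the surrogate machinery learns *that*
reference dynamics under the stated grids and horizons. LTLME itself is a
Markovian, completely positive approximation: it reproduces thermal
asymptotes and transfer pathways but not the non-Markovian corrections a
hierarchical-equations-of-motion reference would add, and nothing here
validates against experiment. The 8th pigment, inter-subunit couplings,
static disorder, and vibronic structure beyond the Drude–Lorentz density
are all outside the model.

## Known limitations

* The two rate conventions differ materially (see above); cross-package
  comparisons must check the flag recorded in trajectory metadata.
* The smoke-profile surrogate is validated only on its sampled time grid
  and in-grid parameters; extrapolation beyond the norms is flagged but
  its error is unquantified at this scale.
* Training uses float32; reproducibility across BLAS implementations is
  expected only to ~10⁻⁶ per prediction, though bit-exact within one
  environment.
* `stationary_state` assumes a unique fixed point; engineered degenerate
  generators (e.g. decoupled blocks) raise instead of returning an
  arbitrary mixture.
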