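# Methods

## Model

`spinpair` simulates the spin dynamics of a spin-correlated radical pair —
modelled on the FAD•– / TrpH•+ pair of avian cryptochrome — in a weak static
magnetic field, with explicitly time-dependent internal magnetic interactions.
The spin Hamiltonian contains the electron Zeeman interaction, the
electron–electron dipolar coupling **D**(t), and the electron–nuclear
hyperfine couplings **A**_i,m(t):

    H(t) = γe B·(S1 + S2) + S1·D(t)·S2 + Σm I1,m·A1,m(t)·S1 + Σm I2,m·A2,m(t)·S2

The exchange interaction is neglected (for this pair it is much smaller than
the dipolar coupling), as are nuclear Zeeman and quadrupolar terms, which are
negligible at geomagnetic field strengths (~50 μT).  Singlet and triplet
pairs recombine spin-selectively with equal rate constant k (default
10⁶ s⁻¹, i.e. a 1 μs lifetime — long enough for an Earth-strength field,
Larmor period ≈ 700 ns, to act).  The compass observable is the anisotropy
ΔΦ_S = max_θ Φ_S(θ) − min_θ Φ_S(θ) of the singlet yield

    Φ_S = k ∫₀ᵀ e^(−kt) P_S(t) dt × [1/(1 − e^(−kT)) if corrected]

computed by trapezoidal quadrature on the propagation grid.  The
finite-window correction is accurate for kT ≥ 5 (e^(−kT) = 0.67% of pairs
unreacted at kT = 5, 0.091% at kT = 7).  θ is the angle between **B** and
the flavin-plane normal (z), with **B** confined to the flavin xz-plane;
x is taken as the in-plane axis perpendicular to the long axis of the
isoalloxazine ring.

## Units

All couplings and fields are supplied in mT and converted to angular
frequency by γe = 0.176086 rad ns⁻¹ mT⁻¹ (equivalently γe/2π =
28.0249 MHz mT⁻¹).  Time-steps are in ns, integration windows in μs,
spectral quantities in MHz.

## Propagation

Two routes produce P_S(t) for singlet-born pairs:

* **direct trace** — every nuclear basis state |ψ⁽ʲ⁾⟩ is propagated as
  |S⟩⊗|ψ⁽ʲ⁾⟩ and P_S(t) = (1/Z) Σⱼ ⟨ψ|P̂_S|ψ⟩ with P̂_S = 1/4 − S1·S2.
  Exact; used for Z ≤ 1000.
* **SU(Z) trace sampling** (stochastic Schrödinger equation) — the trace is
  replaced by an average over M random nuclear vectors with independent
  standard complex Gaussian components, normalized (Haar-uniform on the unit
  sphere); this is the standard construction satisfying the self-averaging
  trace property.  Per-sample yields are retained so every scan can report
  the standard error of the mean.  Used for the 14-nucleus system
  (Z = 55,296, M = 96 by convention).

H(t) is held piecewise-constant over each step, evaluated at the step start
(this matches the per-step propagator e^(−iH(t)δt); a midpoint rule is
available via `PropagationConfig(midpoint=True)`).  Each step applies the
exact exponential: dense systems (4Z ≤ 4096) use per-step eigendecomposition
batched over blocks of 2048 steps; larger systems use sparse
Kronecker-product assembly and Krylov exponential action on the state block
without forming the propagator.  State norms are conserved to machine
precision, so 0 ≤ P_S(t) ≤ 1 holds throughout.

Step-start evaluation converges first order in δt (for the toy system under
200 MHz band-limited noise, halving δt = 1 ns moves Φ_S by ~7×10⁻⁴); the
midpoint rule is second order (< 10⁻⁴ per halving at the same sizes) and is
what the convergence test asserts.  The default δt = 500 ps for band-limited
trajectories keeps δt below half the period of the fastest modulation
(2.5 ns at 200 MHz) with margin; unfiltered synthetic noise is generated at
δt = 50 ps.

## Time-dependent interactions

Three sources of tensor time-dependence:

* **monochromatic** — C_ij(t) = ⟨C_ij⟩[1 + Δ sin(2πνt)], identical frequency,
  phase (0) and amplitude for every element of every tensor;
* **broadband noise** — each of the six independent tensor elements gets its
  own sum of N sinusoids with amplitudes Δn ~ N(0, σΔ), frequencies uniform
  on [ν₁, ν₂] and phases uniform on [0, 2π); symmetric partners are copied so
  frames are exactly symmetric.  The sum is scaled by √(2/N), which makes the
  stationary SD of the fractional modulation equal σΔ for any N — so
  σΔ = 0.1 means "elements fluctuate by 10%", directly comparable to the
  ~10% fluctuation of MD-derived tensors after low-pass filtering.  One
  master seed spawns per-tensor then per-element substreams in a documented
  order (nuclei in system order then dipolar; elements xx, xy, xz, yy, yz,
  zz), so results are reproducible regardless of evaluation order;
* **trajectory files** — plain-text tables (time column plus nine components
  per tensor block) emulating MD/DFT-derived series; the synthetic generator
  in `fixtures` produces such series with mean equal to the static tensor,
  fractional SD 10%, an additive noise floor of 0.0024 mT, and power uniform
  on 0–200 MHz (19,060 frames at 50 ps by default, i.e. a 953 ns record).

The dipolar tensor is modulated by the same mechanisms as the hyperfine
tensors.

### What the synthetic trajectories do and do not emulate

They reproduce the sampling (50 ps frames, ~1 μs records), the magnitude of
the fluctuations (SD ≈ 10% of the element magnitude plus a small floor) and
band-limited broadband spectra.  They do **not** reproduce the structure of
real protein motion: 1/f-like spectral weighting, slow conformational jumps,
correlations between tensor elements or between nuclei, or non-Gaussian
excursions.  Tests that pass on synthetic trajectories therefore validate
the machinery (filtering, propagation, yield statistics), not quantitative
predictions for cryptochrome; quantities that depend on the real MD noise
(e.g. the ~12× anisotropy enhancement seen with MD-derived modulation) are
out of reach by construction.

## Trajectory conditioning

Only modulation frequencies below ν_max — the span (λ_max − λ_min)/2π of the
static spin Hamiltonian — are resonant with spin transitions and able to
affect the yields.  High-frequency content is removed by a hard spectral
cutoff: real FFT, zeroing of all bins with frequency strictly above ν_cutoff
(the bin exactly at the cutoff survives; the DC bin is never touched, so
element means are preserved), inverse FFT; no apodization or zero-padding.
The filter is an orthogonal projection (idempotent, power-contracting).
After filtering, the grid may be decimated (keeping frames 0, f, 2f, …,
first frame retained); decimation is refused if the new Nyquist frequency
would fall below the stored cutoff.  Short records are extended to the
integration window by end-to-end concatenation followed by filtering, which
smooths the splice discontinuities; truncating the extended record to a
non-multiple of the original length introduces artificial spectral
components below the original fundamental (~1 MHz for a ~1 μs record) —
accepted as the cost of not running a 7 μs trajectory.

ν_max is computed by dense diagonalization up to dimension 4096 and by an
ARPACK Lanczos solver for the extreme eigenvalues above (relative tolerance
10⁻⁶; the 221,184-dimensional 14-nucleus Hamiltonian takes seconds).

## Point-dipole coupling

The dipolar tensor from radical centroids separated by **r** is
P·[δ_jk/r³ − 3 r_j r_k/r⁵] in field units, with the prefactor P expressed
through the conventional radical-pair dipolar constant D(r) = −2.78 mT nm³/r³
(axial parameter D = 3/4 of the tensor component along the inter-radical
axis: −0.824 mT at 1.5 nm, −0.347 mT at 2.0 nm).  Evaluating the prefactor
from CODATA constants instead gives −2.785 mT nm³/r³, a 0.2% difference that
is far below the accuracy of the point-dipole approximation itself; the
conventional constant is used because it is what the field's literature
(and the values above) are based on.

## Fixtures

The packaged `toy` (FN5 + WNE1, Z = 9) and `fourteen` (3 × ¹⁴N + 11 × ¹H,
Z = 55,296) systems are **synthetic reconstructions**: the canonical
literature DFT tensor is used for the flavin N5; the other tensors are
representative literature-range values.  Two quantities that the model
system is documented to possess were used to fix otherwise-unknown inputs:
the inter-radical axis was set to (1,1,1)/√3 (at 1.5 nm) and the WNE1 Azz
principal value to 0.8468 mT so that the toy static eigenvalue span is
81 MHz.  With that geometry the span drops by 4.9% when the dipolar
parameter is weakened to its 2.0 nm value and varies by 2.4% with field
orientation, consistent with the documented ~5% and ~3% without further
adjustment; the fourteen-nucleus set, left uncalibrated, has a span of
166.3 MHz at θ = 0 (within 2.3% of the documented 162.60 MHz).  Conclusions
that depend on the precise tensor values (absolute yields, exact spans)
inherit the uncertainty of this reconstruction.

## Ensembles and averaging order

For broadband noise, Φ_S(θ) is computed with the identical noise
realization at every θ (molecules in differently oriented receptor cells
are assumed, for a single scan, to share their motion), and ΔΦ_S is the
grid max − min without interpolation (default grid: 33 points on [0, π]).
Ensemble runs repeat the scan R times (default 16) with independent
realizations and report both averaging orders: ⟨Φ_S(θ)⟩_max − ⟨Φ_S(θ)⟩_min
(average first — the signal from a pool of receptors with independent
noise) and ⟨Φ_S(θ)_max − Φ_S(θ)_min⟩ (range first — relevant if all pairs
move coherently).  The range-first average is always ≥ the average-first
range.  For a static Hamiltonian Φ_S(θ) = Φ_S(θ + π) (field-inversion
symmetry, asserted to 10⁻⁶); a single time-dependent realization may break
this symmetry, and averaging over independent realizations restores it
within standard error — the test suite asserts symmetry only for static
Hamiltonians and restoration only in the ensemble mean.

## Numerical choices and problem sizes

* Hermiticity guards: tensors must be symmetric to 10⁻¹² mT (inputs) /
  10⁻⁹ (per-frame); Hamiltonians are validated against H† at 10⁻⁹ relative.
* Zeeman product basis ordered electron1 ⊗ electron2 ⊗ nuclei (system
  order), highest m first, for reproducible state indexing.
* Seeds: every stochastic object (noise model, SSE sampling, ensemble
  members) derives substreams from a recorded master seed via
  `numpy.random.SeedSequence.spawn`; outputs embed the seeds, parameters and
  fixture checksums needed to re-run bit-identically.
* The test suite scales the published protocols to fit a single-CPU run:
  orientation grids of 9–17 points instead of 33, dt = 1 ns instead of
  500 ps where the noise band (≤ 200 MHz) makes that adequate, and reduced
  SSE sample counts in statistical property tests.  The scaling choices are
  stated in each test.

## Known limitations

* The single-trajectory noise surrogates cannot reproduce MD-specific
  results; see above.
* No Redfield/Lindblad relaxation superoperators are provided — relaxation
  emerges only from the explicit time-dependence of H(t).
* The direct method stores one state per nuclear basis vector and is
  intentionally capped at Z = 1000.
* g-tensor anisotropy, exchange coupling, nuclear Zeeman and quadrupolar
  interactions are omitted (negligible for this system at 50 μT).
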