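# Methods

## Scope and model

`excitonbath` covers the downstream, analysis half of an excitation-energy-
transfer study of a pigment–protein complex such as the FMO
(Fenna–Matthews–Olson) trimer: given pigment geometries and site-energy
time series — however obtained — it builds the Frenkel exciton picture and
characterizes the protein/solvent bath. The upstream stages that would
normally produce those inputs (force-field preparation, MD sampling,
excited-state calculations of per-snapshot site energies) are out of scope
and are replaced by synthetic generators with the statistical structure the
analysis assumes.

### Frenkel exciton Hamiltonian

An aggregate of N pigments is described by the N×N symmetric matrix H with
site energies E_k (the Qy transition energy of pigment k in its protein
environment, cm⁻¹) on the diagonal and excitonic couplings V_km off the
diagonal. Eigenvectors of H are the delocalized exciton states; the squared
eigenvector component c²_{αk} is pigment k's contribution to level α. The
decomposition conserves the trace (Σ exciton energies = Σ site energies)
and each contribution row sums to 1 — both are asserted as invariants.
Energies are stored ascending; report tables list levels descending
(level 1 = highest), the convention used in the field's tables.

### Point-dipole couplings

Couplings are evaluated in the point-dipole approximation,

    V_km = f · 5.034 · μ_k μ_m · κ_km / R³_km  (cm⁻¹),

with κ = ê_k·ê_m − 3(ê_k·r̂)(ê_m·r̂), R the Mg–Mg distance in Å, dipole
strengths in Debye, and f a scalar protein screening factor. The prefactor
5.034 cm⁻¹·Å³/D² is the standard electrostatic conversion for these units.
Defaults f = 0.8 and μ_kμ_m = 37.5 D² are the values customary for BChl a.
The transition-dipole direction is taken as the unit vector from atom ND to
atom NB of the bacteriochlorin ring (PDB nomenclature). κ is even in r̂, so
the choice of distance-vector direction cannot leak into results; κ ∈
[−2, 2] always, which the property suite checks on 10⁵ random orientations
together with rotation invariance of whole coupling matrices.

### Embedded FMO reference matrix and the pigment-8 ambiguity

The package embeds a published eight-pigment monomer Hamiltonian (site
energies and MD-averaged couplings, cm⁻¹) plus the matching bath-fit table.
In the source layout the pigment-8 *site energy* is printed only in the 8′
row (the eighth pigment of the neighboring monomer), and two coupling rows
exist for pigment 8: its weak intra-monomer couplings and the 8′ row with a
sizable 32.4 cm⁻¹ coupling to pigment 1. Both variants are available
(`reference_hamiltonian(pigment8_couplings="inter"|"intra")`). Both
reproduce the published eight exciton energies within ±0.001 eV; only the
**inter** (8′-row) variant also reproduces all 64 published contributions
within ±0.05 (notably pigment 8's 0.80 at the 1.424 eV level, where the
intra variant gives 0.89, and the pigment-1/6 weights of the top two
levels). The inter variant is therefore the default, and the published
decomposition was evidently computed with the 8′ couplings.

### Absorption spectra

Exciton transition dipoles are μ_α = Σ_k c_{αk} μ_k; stick intensities
|μ_α|² are convolved with a unit-area Gaussian (default FWHM 80 cm⁻¹ — a
typical inhomogeneous width for BChl Qy bands; the spectrum shape is a
presentation choice, not a fitted quantity). Unitarity guarantees
Σ_α|μ_α|² = Σ_k|μ_k|², asserted to 1e-9, and the integral of the broadened
spectrum equals the stick sum on a sufficiently wide grid.

## Bath characterization

### Correlation function

Site-energy fluctuations ΔE(t) = E(t) − ⟨E⟩ define

    C(t_j) = (1/N_l) Σ_l (1/N) Σ_i ΔE_l(t_i+t_j) ΔE_l(t_i),

averaged over symmetry-equivalent monomers l. The biased estimator (divide
by the full length N, via `statsmodels.acovf(adjusted=False)`) is used:
standard for spectral estimation, it damps the large-lag noise and makes
C(0) the pooled biased variance. Default estimator window:
min(2000 fs, half the series span).

### Biexponential white-noise-residue (WNR) fit

C(t) is fitted by a·exp(−t/τ_slow) + b·exp(−t/τ_fast). Two modes:

* **Constrained (default).** τ_fast is pinned at the first bosonic
  Matsubara timescale ħ/(2π k_B T) — 4.05 fs at 300 K, depending only on
  temperature — and (a, τ_slow, b) are fitted by bounded least squares.
  This is the WNR prescription: the fast channel is a thermal, not a
  structural, timescale. It is also what makes the fit well-posed: when the
  underlying C(t) is close to a single exponential (as for an
  Ornstein–Uhlenbeck bath), a free 4-parameter biexponential is degenerate —
  the two slots split the one decay arbitrarily or one latches onto the
  noise floor — and recovered reorganization energies scatter wildly.
* **Unconstrained.** All four parameters free, multi-start initialization
  (deterministic starts from a log-linear tail fit; optional seeded random
  restarts). Appropriate when both timescales are genuinely resolvable;
  exact biexponential inputs are recovered to better than 1%.

Fit window: the lag grid is truncated adaptively at 10 integral correlation
times (τ_int = ∫C dt / C(0)); beyond that the estimator carries only
statistical noise, which a free slow component would otherwise absorb.
Weighting inside the window is uniform and lag 0 is included. A fast
timescale collapsing below the sampling step is reported at that bound with
a warning; non-convergence across all starts raises an error carrying the
best residual.

The reorganization energy uses the classical (high-temperature)
fluctuation–dissipation amplitude mapping λ = a_slow/(2 k_B T), which makes
the fitted Drude form exactly consistent with the direct transform for a
pure exponential. The imaginary (quantum) part of C(t) is not modeled: the
input is a classical trajectory.

### Spectral densities

Drude model: J(ω) = 2λγω/(ω² + γ²), with γ = 1/(2πcτ_slow); J(γ) = λ
identically. The frequency↔timescale convention γ(cm⁻¹) = 1/(2πcτ) is used
throughout (16.065 fs ↔ 330.4 cm⁻¹); with the convention lacking the 2π the
published aggregate cutoff could not be reproduced from the printed mean
timescale. The numerical route evaluates J(ω) = βω∫C(t)cos(ωt)dt by
trapezoidal quadrature (t converted to cm through ct). On synthetic OU data
the two routes agree within 10% at the peak for every tested seed, and in
median over ω ∈ [γ/2, 2γ]; pointwise agreement across that whole band is
noise-limited at single frequencies, so the consistency guard is stated at
the peak. A 150 fs (≈10τ) transform window is used there for the same
reason as the fit window.

### Aggregates and the transport parameter

Per-pigment parameters are averaged arithmetically; the aggregate cutoff
converts the *mean slow timescale* (γ̄ = 1/(2πc·mean τ_slow)), not the mean
rate — the embedded table reproduces the published aggregates (λ̄ = 102
cm⁻¹, γ̄ = 330 cm⁻¹, mean τ_fast = 4.20 fs) only under this reading.
`transport_parameter` evaluates a dimensionless combination of λ, γ, the
average excitonic gap g and k_BT signalling the optimal-transport regime.
The default, Λ = λγ/(g·k_BT), is a documented provisional stand-in — the
original definition is not transcribable from the available source text —
so Λ accepts a pluggable formula and its absolute value is not asserted
anywhere.

## Synthetic generators

* **OU site energies.** Stationary Gaussian process with exact
  discretization X_{n+1} = X_n e^{−Δt/τ} + σ√(1−e^{−2Δt/τ}) ξ_n, stationary
  variance σ² = 2λk_BT, initialized from the stationary distribution (no
  burn-in needed). Its exponential correlation is exactly the classical
  limit of a Drude bath, so generated data exercises the full
  autocorrelation→fit→spectral-density chain with known ground truth.
  Defaults emulate the production conditions of a site-energy study:
  20 ps at 0.5 fs (40 000 samples), three monomers, 300 K, λ = 100 cm⁻¹,
  τ = 15 fs, mean energy 11 450 cm⁻¹ (a typical BChl a Qy value).
  What it does **not** emulate: non-exponential/multi-timescale memory,
  vibronic peaks in J(ω), anharmonicity, cross-correlation between
  pigments, non-Gaussian tails. Passing recovery tests therefore validates
  the estimator chain, not the realism of any particular protein bath.
* **Ring geometries.** n pigments on a circle with tangential / parallel /
  seeded-random dipoles — analytic symmetry makes coupling matrices easy to
  check by brute force.
* **Jittered trajectories.** Base coordinates + iid isotropic Gaussian
  displacement per atom, optionally composed with a random rigid motion
  that superposition must remove. Mg–N-type distance distributions built
  this way are Gaussian with width σ√2 per pair, giving closed-form FWHM
  checks.

All generators consume a single integer seed (`numpy.random.default_rng`)
and are bit-reproducible for a fixed platform.

## Structural statistics

RMSD uses the closed-form optimal rigid superposition (Kabsch SVD with
proper-rotation correction via `scipy`'s `align_vectors`), selectable
label sets (`backbone`, `no-phytyl` presets for PDB naming), and a no-refit
mode for fixed-frame comparisons. Histogram widths come from an unweighted
least-squares Gaussian fit to bin counts (default bin 0.01 Å), reporting
FWHM = 2√(2 ln 2)·σ; if the fit fails the empirical half-maximum crossing
width is returned and flagged. Degenerate (spread-free) samples are
rejected rather than fitted.

## Numerical conventions and edge cases

* Internal energy unit cm⁻¹ (1 eV = 8065.544 cm⁻¹; k_B = 0.6950348
  cm⁻¹/K; c = 2.99792458×10⁻⁵ cm/fs); eV only at presentation.
* Hamiltonian CSVs are symmetrized by averaging on read; asymmetry above
  1e-3 cm⁻¹ is logged. Symmetry is enforced at 1e-6 cm⁻¹ on construction.
* Degenerate eigenvalues: contributions are reported per returned
  eigenvector with a logged warning; no subspace rotation is applied.
* Empty input files raise a distinct `EmptyInputError`; every writer
  produces files its paired reader accepts (round-trip tested).
* Site-energy tables require a uniform time grid (relative jitter < 1e-6).

## Problem sizes

The test suite and the acceptance script run entirely on embedded tables
and generated data: 8×8 diagonalizations, 40 000-sample OU series (10 seeds
for the recovery medians), 10⁵ random orientations for the κ bound, and
20 000-frame jitter ensembles for distribution statistics. These sizes give
Monte-Carlo errors comfortably inside the asserted tolerances.

## Known limitations

* The point-dipole approximation degrades below ~1.5 ring diameters
  (transition-charge schemes are out of scope by design).
* λ extraction assumes the classical high-temperature limit; at low
  temperature the fluctuation–dissipation mapping would need the quantum
  correction that is deliberately not modeled.
* The constrained fit pins τ_fast to the leading Matsubara timescale; a
  genuinely athermal fast structural mode would be misattributed.
* Exciton population dynamics (Redfield/HEOM), circular dichroism and
  trimer-scale (24×24) Hamiltonians are not implemented; the monomer 8×8
  reading reproduces the embedded decomposition's trace exactly, which is
  why it is the one shipped.
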