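# Methods

## Scope and model

`roafit` implements everything downstream of the two expensive external
engines in a simulation-aided Raman/ROA structure determination workflow:
MD (conformer sampling) and QM (per-snapshot vibrational frequencies and
Raman/ROA intensities) are consumed as data, never run. The package owns
spectral post-processing, similarity scoring, conformer-weight
decomposition with uncertainty, the NMR ³J population fit, and
torsion/puckering bookkeeping.

## Spectral processing

A snapshot enters as a stick spectrum: positive mode wavenumbers with a
Raman and a signed ROA intensity each. Processing applies, in order:

1. **Frequency scaling.** Harmonic frequencies carry a systematic error
   that differs below and above the fingerprint region. The scaling
   function is a logistic interpolation between two plateaus,
   φ(ν̃) = a + (b − a)/(1 + exp((ν̃ − d)/c)), with defaults
   a = 0.982 (high-frequency plateau), b = 1.00 (low-frequency plateau),
   transition width c = 15 cm⁻¹ and center d = 1210 cm⁻¹. The literature
   that popularized these four parameters does not fix the algebraic
   form in a universally quoted way, so the form is an explicit,
   documented choice here and is pluggable (`scale_frequencies(func=...)`)
   without touching callers. With the defaults, ν̃·φ(ν̃) is strictly
   increasing over the physical range, so mode ordering is preserved.
2. **Temperature factor.** The standard Stokes Raman Boltzmann occupation
   factor [1 − exp(−hcν̃/k_B T)]⁻¹ at T = 300 K, applied to both channels.
   It is > 1 for every finite wavenumber, approaches 1 at high
   wavenumber, and preserves the ROA sign. Whether the source protocol
   includes an additional ν̃-dependent prefactor is not documented;
   the plain occupation factor is the default and the function is
   overridable.
3. **Broadening.** Convolution with a *unit-area* Lorentzian of FWHM
   Γ = 7.5 cm⁻¹ (peak height 2/(πΓ)). Unit area — rather than unit peak —
   is chosen so that integrated broadened intensity equals summed stick
   intensity (conserved to < 1% when the grid margin exceeds ~50 Γ).
   Broadening is linear in the stick intensities.
4. **Ensemble averaging.** Pointwise arithmetic mean over snapshots of a
   conformer, on a shared grid.

The default grid is 200–1800 cm⁻¹ at 1 cm⁻¹ — the range where
carbohydrate Raman/ROA carries conformational information — and is fully
configurable (e.g. 75–3100 cm⁻¹).

The circular intensity difference CID = I_ROA/I_Raman is computed
pointwise; points with |I_Raman| below 10⁻⁶ of its maximum are masked
(NaN + mask flag) rather than divided, to avoid spurious infinities at
baseline.

## Overlap and decomposition

The similarity of two spectra over a window is the normalized inner
product S (trapezoidal quadrature). S is scale-invariant, symmetric and
bounded in [−1, 1]; a zero-norm spectrum on the window is rejected
explicitly.

Weights are constrained to the unit simplex (Aᵢ ≥ 0, Σ Aᵢ = 1). The
decomposition model itself does not force this, but S is
scale-invariant, so only the simplex direction is identifiable, and
populations are fractions by construction.

Because S depends on the conformer spectra only through inner products,
the fit precomputes per-channel Gram matrices (G_ij = ⟨Iᵢ, Iⱼ⟩,
mᵢ = ⟨Iᵢ, I_exp⟩, e = ⟨I_exp, I_exp⟩), reducing every cost evaluation to
O(K²). This makes the exhaustive simplex-grid scans below cheap even at
10⁵–10⁶ grid points.

**Optimizer.** F(A) = (1 − S_Raman)² + (1 − S_ROA)² is smooth on the
simplex but can be multimodal when conformer spectra are nearly
collinear. The minimizer is deterministic multi-start SLSQP: every
pure-conformer vertex, the uniform center, and seeded Dirichlet draws
(32 starts total). Including the vertices guarantees the returned F never
exceeds any pure-conformer cost. Among numerically co-optimal solutions
the maximal-entropy one is returned — reproducible and least committal.

**Intensity scale factors.** ρ_Raman and ρ_ROA (the ‖I_exp‖/‖I_sim(A)‖
norm ratios per channel) are reported for plotting parity; they play no
role in the fit because S is scale-invariant. For the same reason the
uncertainty scan needs no per-point renormalization.

**Uncertainty profile.** For each weight, the reported interval is the
min/max over all simplex points whose S_Raman + S_ROA exceeds a threshold
fraction (default 0.99) of the best-fit sum. For ≤ 5 conformers the scan
is an exhaustive simplex grid at step 0.01 (deterministic; yields the
nesting property across thresholds by construction). For more conformers
it switches to seeded Dirichlet sampling (10⁵ draws) plus SLSQP
extremization of each weight inside the acceptance region. Intervals
always contain the best-fit weights. Two identical conformer spectra
produce [0, 1] intervals — full non-identifiability — and the fit flags
numerically rank-deficient conformer bases via `identifiable_`.

## NMR population fit

G(A) = Σᵢ (³Jᵢ_sim(A) − ³Jᵢ_exp)² is convex; the same simplex-constrained
SLSQP multi-start applies. Karplus coefficients are required inputs:
published parameterizations differ by bond type, substituents and
parameterization study, so shipping a hidden default would silently
choose someone's chemistry.

The deviation budget for the uncertainty profile is 0.2 Hz, a typical
reported experimental error for ³J couplings. The published phrasing of
such budgets is ambiguous between per-coupling and aggregate deviation;
the default here accepts weight vectors whose RMS residual is within the
best-fit RMS + 0.2 Hz (consistent with the least-squares objective), and
`mode="per_coupling"` provides the strict per-coupling variant. Grid
enumeration alone underestimates intervals when the optimal set is a
measure-zero fiber (exactly fitted under-determined systems), so the
bounds are polished by constrained extremization of each weight; with
fewer couplings than free weights the fit reports the bounding box of the
optimal set and sets `unique_ = False`.

## Geometry

Torsions use the standard signed atan2 construction (IUPAC convention;
verified against MDAnalysis). Cremer–Pople puckering uses the canonical
mean plane (normal from the cross product of the two Fourier position
sums) and the m = 2 / m = 3 decomposition of the out-of-plane
displacements, mapped to (Q, θ, φ) with θ = atan2(q₂, q₃) ∈ [0, π].

Conventions: ring atoms are ordered with the ring oxygen first
(O5, C1…C5). The synthetic inverse construction (`gen_ring`) traverses
the hexagon clockwise seen from +z so the Cremer–Pople normal points
along +z; with these choices the ⁴C₁ chair sits at θ = 0 and ¹C₄ at
θ = π, matching the usual pyranose puckering-sphere convention, and
`cremer_pople(gen_ring(Q, θ, φ))` is an exact round trip (≤ 10⁻⁹).
Cyclic re-indexing by an even offset k preserves (Q, θ) and shifts φ by
4πk/6; odd offsets flip the pole (θ → π − θ), which is why the atom
ordering convention matters.

Region assignment is nearest-center under the periodic metric: wrapped
Euclidean distance on the torsion torus, great-circle distance on the
puckering sphere. A wildcard coordinate ("all", e.g. the azimuth of a
chair pole) is ignored in the distance; ties break to the first-listed
region. Populations are plain counted fractions.

Which four atoms define each glycosidic torsion varies by molecule and
is user-supplied configuration, not a package constant.

## Synthetic data

The generators emulate every input class: random stick spectra per
conformer (log-normal Raman, signed normal ROA at 10⁻³ relative
magnitude — the realistic CID scale), noisy weighted mixtures
(multiplicative Gaussian noise, since experimental Raman noise roughly
scales with signal), von Mises torsion ensembles (emulating harmonically
restrained biased-MD sampling), and inverse-Cremer–Pople ring geometries.
All are pure functions of their arguments including the seed.

What they deliberately do *not* emulate: physically correlated normal
modes, solvent bands, fluorescence baselines, instrument response, or
anharmonicity. Passing the recovery tests therefore demonstrates the
correctness and conditioning of the decomposition machinery — that
distinguishable conformer spectra at realistic noise levels yield
recoverable weights with honest intervals — not that any particular
force field or QM protocol reproduces a given sugar's spectra.

Default study conditions for the recovery harness: 4 conformers, 60 modes
each over 220–1780 cm⁻¹, 5% multiplicative noise, 100 seeds; the
four-component composition 0.48/0.31/0.07/0.12 (normalized onto the
simplex) is the canonical mixed-conformer scenario exercised throughout.

## Numerical choices and limitations

- Trapezoidal quadrature everywhere an integral appears; simulated and
  experimental spectra must share a grid, and experimental files are
  linearly interpolated onto it on read (the overlap integral needs a
  shared abscissa; instrument steps vary).
- Simplex grids enumerate integer compositions (exact, deterministic,
  lexicographic); chunked evaluation bounds memory.
- Degenerate inputs fail loudly: zero-norm spectra, empty ensembles,
  planar rings (Q = 0 → angles flagged undefined), collinear torsion
  atoms, off-simplex weights.
- The uncertainty intervals are bounding boxes of the acceptance set,
  not marginal confidence intervals; correlations between weights are
  not reported.
- Problem sizes in the test suite and acceptance script (grids of ~10³
  points, ≤ 6 conformers, 10²–10³ random draws, 100 noise seeds) were
  chosen as the smallest sizes at which every statistical check is
  comfortably stable.
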