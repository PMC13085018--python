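# Methods

This note records the physical model, the numerical choices behind it,
and what the synthetic conditions used in the tests do and do not show
about real measurements.

## Problem

Two identical fluorophores separated by a distance `d` well below the
diffraction limit cannot be resolved by eye, but `d` remains a
statistically estimable parameter. The package computes three kinds of
precision bound for this problem:

1. the classical Cramér-Rao bound (CRB) of five concrete detection
   schemes, from the Fisher information of Poisson-distributed camera
   pixels;
2. the quantum Cramér-Rao bound (QCRB), the measurement-independent
   limit obtained from the one-photon density operator of the collected
   field;
3. the interference visibility of the image-inversion interferometer
   stage, the single diagnostic that controls whether the classical
   bound diverges as `d → 0`.

A fluorophore is a dipole emitter, and in aqueous samples it typically
rotates much faster than its fluorescence lifetime, so each detected
photon is drawn from an isotropic mixture of the three orthogonal dipole
orientations. This breaks the scalar-field assumption of the
mode-sorting superresolution literature and is the entire reason the
vectorial machinery below exists.

## Vectorial pupil model

For a dipole along `j ∈ {x, y, z}` at the medium/coverslip interface,
the far field after the objective in the pupil's radial/azimuthal basis
is

    E_R(j) ∝ t_p (δ_jx cosθ_m cosφ + δ_jy cosθ_m sinφ − δ_jz sinθ_m) / √cosθ_imm
    E_A(j) ∝ t_s (−δ_jx sinφ + δ_jy cosφ) / √cosθ_imm

with `θ_m` the medium-side polar angle, `θ_imm` the immersion-side
angle, `1/√cosθ_imm` the sine-condition apodization, and `t_s`, `t_p`
Fresnel transmissions through the water/coverslip/oil stack evaluated
interface by interface (multiple reflections neglected). Beyond the
critical angle `cosθ_m` is taken on the `Im ≥ 0` branch, which produces
the supercritical-angle-fluorescence ring and, for an emitter at depth
`z₀ > 0`, the correct evanescent damping `exp(i k₀ n_m cosθ_m z₀)`.
Fixed-basis H/V components follow by the pointwise rotation
`E_H = E_R cosφ − E_A sinφ`, `E_V = E_R sinφ + E_A cosφ`.

Key symmetry facts, exact on the grid by construction:

* azimuthal scalar components are odd under `k → −k` for x/y dipoles and
  identically zero for a z dipole — hence the Polar-SLIVER null is exact
  at any NA and any index mismatch;
* H/V fields are even for x/y dipoles and odd for the z dipole — hence
  plain SLIVER's visibility deficit is exactly the collected z-dipole
  energy fraction, which grows with NA.

The six fields of one emitter are jointly normalized to unit collected
energy; the isotropic orientation average is absorbed into this
normalization.

### Sampling choices

* Pupil: a square grid with an odd number of samples per axis (default
  129) spanning the NA disc, so `k = 0` is a grid point and point
  inversion is an exact index reversal. `cosφ`/`sinφ` are computed as
  `kx/|k|`, `ky/|k|`, whose sign flips are exact in floating point; a
  0.1% interferometer-null error from interpolation would be
  indistinguishable from a real visibility loss, so no interpolation is
  permitted anywhere in the inversion path. The single singular sample
  at `k = 0` carries no energy (measure zero; real vortex plates have a
  central defect too).
* Image: pupil-to-image propagation is an explicit matrix-product DFT
  evaluated on the oversampled camera grid (default 150 pixels of
  λ/(8·NA) per channel, 2×2 subpixel integration per pixel, grid
  symmetric about the axis). This is numerically equivalent to a
  zero-padded FFT but samples exactly where the camera integrates.
* Channel sets are normalized so an on-axis emitter's probabilities sum
  to 1 over the computed field of view. The dipole PSF has Airy-like
  power-law tails that put O(1%) of the pupil energy outside any
  practical field of view, so normalizing to the pupil energy would make
  every channel set sum to ≈0.99 instead; the field-of-view convention
  keeps the Poisson model self-consistent. The constant is independent
  of the emitter position, so derivatives are unaffected.

## Detection methods

Five channel sets are modeled (labels as in the code):

| method       | channels                 | split                       |
|--------------|--------------------------|-----------------------------|
| DD           | one camera, I_H + I_V    | —                           |
| SLIVER       | sym, asym                | whole field interfered      |
| SLIVER+DD    | DD, sym, asym            | 1/2 DD, 1/2 to interferometer |
| DDA+DDR      | DD-R, DD-A               | VWP + PBS                   |
| PolarSLIVER  | DD-R, Sym-A, Asym-A      | VWP + PBS, A-port interfered |

The interferometer outputs of an input field `a(k)` are
`(a(k) ± a(−k))/2`, which conserves energy; a first-splitter intensity
ratio `r ≠ 1/2` and a residual arm phase Δφ generalize this while still
conserving energy for every setting. Image inversion acts on each
polarization component as a scalar, which is what a two-dove-prism
inverter implements.

The vortex wave plate is a half-wave retarder with fast axis at φ/2 —
the unique geometry mapping radial to horizontal polarization. The
chromatic model uses `δ(λ) = 2π·Δn(λ)·t/λ` with a two-term Cauchy
birefringence `Δn(λ) = a + b/λ²` (defaults a = 0.19, b = 7.0·10³ nm²,
a generic nematic liquid-crystal dispersion of the order of common
commercial mixtures) and thickness calibrated so `δ = π` exactly at the
design wavelength. Detuning leaves a residual that stays in the input
polarization and splits `cos²φ/sin²φ` at the polarizing beam splitter:
for pure radial input the φ-averaged wrong-port energy is
`cos²(δ/2)/2`. A finite detection bandwidth Δλ is modeled as a uniform
(flat-spectrum) average of monochromatic channel PSFs over 11 sampled
wavelengths; the flat weighting is a modeling choice — a real
fluorophore spectrum would weight the band edges differently.

## Classical bounds

The two-emitter expectation on channel `c`, pixel `q` is

    I_cq = s/2·PSF_cq(r₀+Δ/2) + s/2·PSF_cq(r₀−Δ/2) + f_c·b

with θ = (d, α, x₀, y₀, s, b), Δ = d(cosα, sinα). `b` is the background
in photons per camera pixel referenced to a single-camera measurement;
`f_c` is the fraction of background light the method's beam splitters
route to channel `c` (e.g. 1/2, 1/4, 1/4 for Polar-SLIVER). This
conserves the total background budget across methods — giving every
channel the full `b` would hand a three-camera method three times the
background of DD for the same sample. A helper converts the sweep unit
photons/σ_psf² to per-pixel values.

Fisher information assumes independent Poisson pixels. Derivatives of
the geometric parameters are central finite differences with steps
10⁻³·σ_psf (lengths) and 10⁻³ rad (angle) — verified to sit in the
quadratic regime by step-halving in the test suite — while s and b
enter affinely and are differentiated exactly. Empty pixels at `b = 0`
are regularized by adding 10⁻¹² to the expectation in the 1/I factor
only; the tests assert this moves no reported σ by more than 0.1%.

Full-parameter CRBs are obtained by inverting the FIM after
equilibrating it to correlation form (parameters live on nm, radian and
photon-count scales simultaneously; inverting the raw matrix is
numerically meaningless). Information-free directions report σ = ∞
rather than raising. With a truly zero background the `b` parameter is
excluded from full-parameter subsets: b = 0 is the boundary of the
parameter space and its floor-regularized row would be dominated by the
regularizer.

σ_psf is the geometric mean of the DD centroid CRBs of a single dipole
at s = 1, b = 0 and is the length unit of all reported results; the
circular symmetry of the DD dipole PSF (σ_x = σ_y, asserted to 0.5%)
makes it well defined. The signal-to-background ratio is
SBR = s/(A·b) with reference area A = 10σ_psf².

## Quantum bound

The one-photon density operator of the two-emitter mixture is

    ρ₁ = Σ_j p_j/2 (|ψ_1j⟩⟨ψ_1j| + |ψ_2j⟩⟨ψ_2j|),

where ψ_ej is the normalized two-component (R/A) pupil field of emitter
e with orientation j, and positions enter only through the tip-tilt
phase. By default the orientation probabilities are equal thirds (the
isotropic mixture read literally, under which the coincident-emitter
spectrum is exactly (1/3, 1/3, 1/3) and the large-separation bound sits
marginally above the d → 0 bound); weighting orientations by their
collected pupil energy is available as an option and changes K_d by
well under 1% at high NA.

Because `∂_d ψ_ej = ∓(i/2)(k·û)ψ_ej` is analytic, both ρ₁ and ∂_d ρ₁
live in the span of the 12 vectors {ψ_ej, ∂_d ψ_ej}. The computation
orthonormalizes that span with a rank-revealing eigendecomposition of
the Gram matrix (directions below 10⁻⁷ of the largest singular value are
dropped, which handles the exact degeneracy at d = 0), projects both
operators into it, and evaluates the symmetric-logarithmic-derivative
sum

    K_d = Σ_{λi+λj>0} 2|⟨e_i|∂_d ρ₁|e_j⟩|²/(λi+λj)

with the pair cutoff `λi+λj > 10⁻¹²·max λ`. The subspace result equals a
dense-grid eigendecomposition of the full operator to better than 10⁻⁶
relative (tested on a 33-point pupil). σ_QCRB(d) = 1/√(s·K_d); the
large-separation reference σ_∞,QCRB is evaluated at d = 16σ_psf and
accepted only if doubling d moves it by < 0.5%.

Substituting a scalar Gaussian pupil reproduces the closed form
σ²_QCRB = 4σ_psf² at one photon, independent of d, which anchors the
whole chain (state assembly, Gram orthonormalization, SLD sum, and the
classical σ_psf machinery) against a known result.

## Synthetic data

`sample_images` draws independent Poisson pixels from the two-emitter
expectation — exactly the noise model the Fisher matrix assumes. It
emulates shot-noise-limited sCMOS/EMCCD-free detection with a uniform
background; it does not emulate read noise, EMCCD excess noise, pixel
cross-talk, sample drift, fluorophore blinking/bleaching, or aberrated
optics. Tests passing on these images therefore validate the internal
consistency of the bounds (e.g. the Monte-Carlo score-covariance check
of the FIM on an 8×8 toy model), not the attainability of the bounds on
real hardware.

## Problem sizes

Headline numbers are computed at the production configuration
(129-point pupil, 150² pixels per channel, 2× oversampling). Property
and unit tests use reduced grids (21–41 pupil points, 8–40 pixels)
where the symmetries and scaling laws are identical; the dense-operator
QFI oracle uses a 33-point pupil so the full 2178-dimensional
eigenproblem stays cheap. The Monte-Carlo Fisher cross-check uses
2·10⁵ frames of an 8×8 toy camera.

## Known limitations

* Aberration-free optics; systematic and inter-arm aberrations are out
  of scope.
* Equal-brightness emitters only; `I₁ = I₂` is assumed throughout.
* The LC dispersion constants are generic, not a specific device
  datasheet; bandwidth results are qualitative in the constants but
  exact in the mechanism.
* Estimators (MLE etc.) are not implemented; all statements are bounds.
* The background-allocation convention (split by the optical train) is
  a modeling choice; a detector-local background (full b on every
  camera) would lower the multi-channel methods' advantage by roughly
  √2–2× at high background.
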