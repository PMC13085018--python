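# polarsliver

Precision bounds for estimating the separation of two freely rotating
dipole emitters (single fluorophores) with vectorial high-NA optics:
classical Cramér-Rao bounds for five detection schemes — including
**Polar-SLIVER**, a vortex-wave-plate-sorted image-inversion
interferometer — and the quantum Cramér-Rao bound from the one-photon
density operator.

## Why

Below the diffraction limit, direct imaging of two simultaneously
emitting fluorophores gives a separation Cramér-Rao bound

    σ_d² = [F⁻¹]_dd,   F_ij = Σ_q (1/I_q) ∂I_q/∂θ_i ∂I_q/∂θ_j

that diverges as d → 0. Mode-sorting measurements (SLIVER, SPADE) avoid
this divergence for *scalar* point sources, but a fluorophore is a
rotating **dipole**: its field is an incoherent mixture of six polarized
vectorial components, which mixes even and odd pupil fields and spoils
the interferometric null that mode sorting relies on. Sorting the
radiation into radial and azimuthal polarization with a vortex
half-wave plate restores an exactly odd field (the azimuthal component
of every dipole orientation), so an image-inversion interferometer on
the azimuthal arm recovers a perfect null — visibility 1 at any NA —
and a non-divergent σ_d at all separations, close to the quantum limit

    σ_d,QCRB = 1/√(s·K_d),   K_d = Σ_{λi+λj>0} 2|⟨e_i|∂_d ρ₁|e_j⟩|²/(λi+λj)

computed here numerically from the eigendecomposition of the one-photon
state ρ₁ of the two-dipole mixture. The package is for microscopists
and quantum-metrology researchers who want these bounds for concrete
optical configurations (wavelength, NA, index mismatch, pixelation,
detection bandwidth, background, misalignment, interferometer
imperfections).

## Worked example

σ_psf below is the single-dipole localization precision under direct
detection at one expected photon — the natural length unit. At the
production configuration (λ = 680 nm, NA 1.45, water/coverslip/oil =
1.33/1.516/1.516, 150² pixels of λ/(8·NA)):

```sh
$ polar-sliver visibility --method SLIVER --na 0.1
0.997203
$ polar-sliver visibility --method PolarSLIVER --na 1.45
1.000000
```

Plain SLIVER loses its null even at NA 0.1 (the collected z-dipole
light is odd in the H/V basis); Polar-SLIVER's null is exact. That
visibility difference is worth orders of magnitude at small separation:

```sh
$ polar-sliver crb --method DD --d 0.01          # d in units of σ_psf
{ "sigma_d_over_sigma_psf": 197.0, "sigma_psf_nm": 160.6, ... }
$ polar-sliver crb --method PolarSLIVER --d 0.01
{ "sigma_d_over_sigma_psf": 1.224, "sigma_psf_nm": 160.6, ... }
$ polar-sliver qcrb --d 0.01
{ "K_d_per_photon": 5.519e-05, "sigma_qcrb_nm": 134.6, ... }
```

At d = 0.01σ_psf direct detection is bounded at ≈197σ_psf per photon
while Polar-SLIVER achieves ≈1.22σ_psf — within a factor ~1.5 of the
quantum bound (134.6 nm), i.e. its Fisher information is ≈47% of the
quantum Fisher information; the missing half is carried by the
z-oriented dipole, whose radiation has no azimuthal component.

The same numbers are available from Python:

```python
from polarsliver import (OpticalConfig, ParameterVector, TwoEmitterModel,
                         get_engine, fisher_matrix, sigma_psf)

cfg = OpticalConfig()                      # 680 nm, NA 1.45, 150² px
sig = sigma_psf(cfg)                       # 160.6 nm
model = TwoEmitterModel(get_engine(cfg, "PolarSLIVER"))
res = fisher_matrix(model, ParameterVector(d=0.01 * sig, s=1.0), params=("d",))
print(res.crb["d"] / sig)                  # 1.224
```

`run_sweep` evaluates figure-style grids (method × d × NA × bandwidth ×
background × misalignment) into a tidy DataFrame, and `sample_images`
draws Poisson camera frames from any configuration for simulation
studies.

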