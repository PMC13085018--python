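"""Vortex wave plate, polarizing beam-splitter sort, and the visibility diagnostic.

A vortex wave plate (VWP) is a half-wave retarder whose fast axis rotates
with azimuth as q·φ (q = 1/2 here, the unique geometry that maps radial
polarization to horizontal).  With retardance δ the local Jones matrix in
the H/V basis is

    J(δ, ψ) = cos(δ/2)·I − i sin(δ/2)·[[cos 2ψ, sin 2ψ], [sin 2ψ, −cos 2ψ]],  ψ = qφ.

At δ = π this is an exact R→H, A→V converter (up to a global phase); at
δ ≠ π a fraction cos²(δ/2) of each input leaks into the wrong port of the
downstream polarizing beam splitter.

A liquid-crystal VWP is chromatic: δ(λ) = 2π·Δn(λ)·t/λ with the
birefringence Δn(λ) following a two-term Cauchy law Δn = a + b/λ².  The
plate satisfies the half-wave condition only at its design wavelength,
which is why a finite detection bandwidth degrades the Polar-SLIVER null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VWPModel",
    "InterferometerImperfections",
    "lc_retardance",
    "vwp_transform",
    "vwp_port_fields",
    "visibility",
]

# Generic nematic liquid crystal dispersion near the far-red: Δn ≈ 0.205
# at 680 nm with a normal-dispersion Cauchy B term.  Values are of the
# order of common commercial LC mixtures; they are configuration defaults
# and recorded here as the single source of truth.
CAUCHY_A_DEFAULT = 0.19
CAUCHY_B_DEFAULT = 7.0e3  # nm²


@dataclass(frozen=True)
class VWPModel:
    """Vortex half-wave retarder, ideal or chromatic.

    ``ideal`` short-circuits the retardance to π at every wavelength.
    Otherwise the thickness is calibrated so δ(design_wavelength) = π
    exactly, i.e. (ne−no)·t = design_wavelength/2 at the design point.
    """

    design_wavelength: float = 680.0
    cauchy_a: float = CAUCHY_A_DEFAULT
    cauchy_b: float = CAUCHY_B_DEFAULT  # nm²
    fast_axis_order: float = 0.5
    ideal: bool = True

    def birefringence(self, wavelength: float) -> float:
        return self.cauchy_a + self.cauchy_b / wavelength**2

    @property
    def thickness(self) -> float:
        """Plate thickness (nm) from the half-wave calibration point."""
        return self.design_wavelength / (2.0 * self.birefringence(self.design_wavelength))


def lc_retardance(vwp: VWPModel, wavelength: float) -> float:
    """Retardance δ(λ) = 2π·Δn(λ)·t/λ in radians (π at the design point)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if vwp.ideal:
        return np.pi
    return 2.0 * np.pi * vwp.birefringence(wavelength) * vwp.thickness / wavelength


def vwp_transform(e_r: np.ndarray, e_a: np.ndarray, cphi: np.ndarray,
                  sphi: np.ndarray, vwp: VWPModel,
                  wavelength: float) -> tuple[np.ndarray, np.ndarray]:
    """Propagate an (E_R, E_A) pupil field pair through the VWP.

    Returns the (E_H, E_V) output components.  ``cphi``/``sphi`` are the
    pupil azimuth cosines (kx/|k|, ky/|k|).  Energy is conserved
    pointwise (the Jones matrix is unitary).
    """
    delta = lc_retardance(vwp, wavelength)
    c, s = np.cos(delta / 2.0), np.sin(delta / 2.0)

    # input components in the fixed H/V basis
    in_h = e_r * cphi - e_a * sphi
    in_v = e_r * sphi + e_a * cphi

    # fast axis at ψ = φ/2 → 2ψ = φ, so cos2ψ = cphi, sin2ψ = sphi
    out_h = c * in_h - 1j * s * (cphi * in_h + sphi * in_v)
    out_v = c * in_v - 1j * s * (sphi * in_h - cphi * in_v)
    return out_h, out_v


def vwp_port_fields(e_r: np.ndarray, e_a: np.ndarray, cphi: np.ndarray,
                    sphi: np.ndarray, vwp: VWPModel,
                    wavelength: float) -> tuple[np.ndarray, np.ndarray]:
    """Scalar fields in the two PBS output arms after the VWP.

    The H port carries the (nominally radial) field sent to direct
    detection; the V port carries the (nominally azimuthal) field sent to
    the image-inversion interferometer.  With an ideal VWP these are
    exactly −i·E_R and i·E_A.
    """
    if vwp.ideal:
        # exact δ = π limit; the ±i global phases are kept for consistency
        return -1j * e_r, 1j * e_a
    out_h, out_v = vwp_transform(e_r, e_a, cphi, sphi, vwp, wavelength)
    return out_h, out_v


@dataclass(frozen=True)
class InterferometerImperfections:
    """Non-ideal image-inversion interferometer.

    ``split_ratio`` r is the intensity fraction sent into the inverting
    arm by the first beam splitter (ideal 1/2; the quoted 1:0.95 ratio is
    r = 1/1.95).  ``second_split_ratio`` plays the same role at the
    recombining splitter.  ``phase`` is the residual arm phase Δφ in
    radians at the nominally zero-delay operating point.
    """

    split_ratio: float = 0.5
    second_split_ratio: float = 0.5
    phase: float = 0.0

    @property
    def is_ideal(self) -> bool:
        return (
            self.split_ratio == 0.5
            and self.second_split_ratio == 0.5
            and self.phase == 0.0
        )


IDEAL_INTERFEROMETER = InterferometerImperfections()


def visibility(config, method: str, vwp: VWPModel | None = None,
               imperfections: InterferometerImperfections | None = None) -> float:
    """Interference visibility (Imax − Imin)/(Imax + Imin) of a SLIVER stage.

    Computed for a single freely rotating dipole exactly on the inversion
    axis; Imax/Imin are the total photons in the brighter/darker of the
    two interferometer output channels.  Raises for methods without an
    interferometer.
    """
    from .psf import method_psf, SLIVER_CHANNEL_LABELS

    psf = method_psf(config, method, emitter_offset=(0.0, 0.0), vwp=vwp,
                     imperfections=imperfections)
    totals = [
        ch.values.sum() for ch in psf.channels
        if ch.channel_label in SLIVER_CHANNEL_LABELS
    ]
    if len(totals) != 2:
        raise ValueError(f"method {method!r} has no interferometer stage")
    hi, lo = max(totals), min(totals)
    return float((hi - lo) / (hi + lo))
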