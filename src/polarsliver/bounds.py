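"""Two-emitter imaging model, Fisher information and Cramér-Rao bounds.

The expected pixel counts of two identical incoherent emitters are

    I(q) = s/2 · PSF_q(r₀ + Δ/2) + s/2 · PSF_q(r₀ − Δ/2) + f_c · b,

with Δ = d·(cos α, sin α), centroid r₀ = (x₀, y₀), total expected signal
photons s, and background b photons per camera pixel referenced to a
single-camera (direct-detection) measurement.  Background light passes
the same beam splitters as the signal, so channel c of a multi-channel
method receives the fraction f_c of the background (f summing to 1 over
a method's channels; e.g. Polar-SLIVER: 1/2 on the radial camera, 1/4 on
each interferometer output).
With independent Poisson pixels the Fisher information matrix is

    F_ij = Σ_q (1/I_q) (∂I_q/∂θ_i) (∂I_q/∂θ_j),   θ = (d, α, x₀, y₀, s, b),

additive over channels and pixels.  The CRB follows from the matrix
inverse (full-parameter estimation) or from 1/F_dd (separation-only
estimation, all other parameters known).

σ_psf — the geometric-mean centroid localization precision of a single
freely rotating dipole under direct detection at s = 1, b = 0 — is the
natural length unit of every result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .config import OpticalConfig
from .psf import PSFEngine, get_engine

__all__ = [
    "ParameterVector",
    "FisherResult",
    "TwoEmitterModel",
    "two_emitter_image",
    "fisher_matrix",
    "sigma_psf",
    "sigma_d",
    "sbr",
    "background_per_pixel",
]

ALL_PARAMS = ("d", "alpha", "x0", "y0", "s", "b")

# floor added to expected counts in the 1/I factor only: Eq-of-motion of
# the Poisson FI is singular on empty pixels when b = 0
_COUNT_FLOOR = 1e-12


@dataclass(frozen=True)
class ParameterVector:
    """θ = (d, α, x₀, y₀, s, b); lengths in nm, b in photons per pixel."""

    d: float = 0.0
    alpha: float = 0.0
    x0: float = 0.0
    y0: float = 0.0
    s: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("separation d must be nonnegative")
        if self.s <= 0:
            raise ValueError("total signal photons s must be positive")
        if self.b < 0:
            raise ValueError("background b must be nonnegative")

    def replace(self, **kw) -> "ParameterVector":
        return replace(self, **kw)


@dataclass(frozen=True)
class FisherResult:
    """Fisher matrix over a declared parameter subset and derived CRBs."""

    params: tuple[str, ...]
    fim: np.ndarray
    crb: dict[str, float]  # per-parameter standard deviations
    per_channel_fi: tuple[np.ndarray, ...]
    sigma_psf: float | None = None

    @property
    def sigma_d(self) -> float:
        return self.crb["d"]


class TwoEmitterModel:
    """Expected-count model of two identical emitters for one detection method."""

    def __init__(self, engine: PSFEngine):
        self.engine = engine

    @property
    def config(self) -> OpticalConfig:
        return self.engine.config

    @property
    def n_channels(self) -> int:
        return len(self.engine.channel_specs)

    def _positions(self, d: float, alpha: float, x0: float, y0: float):
        dx = 0.5 * d * math.cos(alpha)
        dy = 0.5 * d * math.sin(alpha)
        return (x0 + dx, y0 + dy), (x0 - dx, y0 - dy)

    def expected_images(self, theta: ParameterVector) -> list[np.ndarray]:
        """Per-channel expected pixel counts (Eq. above)."""
        return self._expected(theta.d, theta.alpha, theta.x0, theta.y0,
                              theta.s, theta.b)

    def _expected(self, d: float, alpha: float, x0: float, y0: float,
                  s: float, b: float) -> list[np.ndarray]:
        # d may go (infinitesimally) negative inside finite differences;
        # (−d, α) ≡ (d, α+π) with the emitters swapped, same image
        r1, r2 = self._positions(d, alpha, x0, y0)
        c1 = self.engine.channel_images(*r1)
        c2 = self.engine.channel_images(*r2)
        fracs = self.engine.background_fractions
        return [
            0.5 * s * (a + b_) + b * f
            for a, b_, f in zip(c1, c2, fracs)
        ]


def two_emitter_image(engine: PSFEngine, theta: ParameterVector) -> list[np.ndarray]:
    """Expected per-channel pixel counts for two identical emitters."""
    return TwoEmitterModel(engine).expected_images(theta)


def _finite_difference_steps(theta: ParameterVector, sigma: float) -> dict[str, float]:
    """Central-difference steps: 10⁻³·σ_psf for lengths, 10⁻³ rad for α."""
    return {
        "d": 1e-3 * sigma,
        "x0": 1e-3 * sigma,
        "y0": 1e-3 * sigma,
        "alpha": 1e-3,
    }


def _crb_from_fim(fim: np.ndarray, params: tuple[str, ...]) -> dict[str, float]:
    """Per-parameter standard deviations from the FIM inverse.

    Parameters live on wildly different scales (nm, radians, photon
    counts), so the matrix is equilibrated to correlation form
    C = D·F·D with D = diag(1/√F_ii) before inversion; then
    [F⁻¹]_ii = D_i²·[C⁻¹]_ii.  A singular FIM reports an infinite CRB
    along its null directions instead of failing: a parameter with no
    information, or an exactly degenerate direction, gets σ = ∞.
    """
    if len(params) == 1:
        f = float(fim[0, 0])
        return {params[0]: (1.0 / math.sqrt(f)) if f > 0 else math.inf}
    diag = np.diag(fim).copy()
    out: dict[str, float] = {}
    ok = diag > 0
    idx = np.flatnonzero(ok)
    for i, p in enumerate(params):
        if not ok[i]:
            out[p] = math.inf
    if idx.size == 0:
        return out
    sub = fim[np.ix_(idx, idx)]
    dscale = 1.0 / np.sqrt(diag[idx])
    corr = sub * np.outer(dscale, dscale)
    evals, evecs = np.linalg.eigh(corr)
    tol = evals.max() * 1e-10
    for pos, i in enumerate(idx):
        var = 0.0
        for k in range(len(evals)):
            w = evecs[pos, k] ** 2
            if evals[k] <= tol:
                if w > 1e-9:
                    var = math.inf
                    break
            else:
                var += w / evals[k]
        out[params[i]] = math.sqrt(var) * dscale[pos]
    return out


def fisher_matrix(model: TwoEmitterModel, theta: ParameterVector,
                  params: tuple[str, ...] = ("d",),
                  length_step_scale: float | None = None) -> FisherResult:
    """Poisson-pixel Fisher information over the requested parameter subset.

    Geometric parameters (d, α, x₀, y₀) are differentiated by central
    finite differences with steps of 10⁻³·σ_psf (lengths) and 10⁻³ rad
    (angle); s and b enter the model affinely, so their derivatives are
    exact.  ``length_step_scale`` overrides σ_psf for the step size (used
    to break the circularity when computing σ_psf itself).
    """
    unknown = set(params) - set(ALL_PARAMS)
    if unknown:
        raise ValueError(f"unknown parameters {sorted(unknown)}")
    sigma = length_step_scale
    if sigma is None and any(p in params for p in ("d", "x0", "y0")):
        sigma = sigma_psf(model.config)
    steps = _finite_difference_steps(theta, sigma or 1.0)

    images = model.expected_images(theta)
    derivs: dict[str, list[np.ndarray]] = {}
    fracs = model.engine.background_fractions
    for p in params:
        if p == "s":
            derivs[p] = [
                (img - theta.b * f) / theta.s
                for img, f in zip(images, fracs)
            ]
        elif p == "b":
            derivs[p] = [
                f * np.ones_like(img) for img, f in zip(images, fracs)
            ]
        else:
            h = steps[p]
            args = {"d": theta.d, "alpha": theta.alpha, "x0": theta.x0,
                    "y0": theta.y0, "s": theta.s, "b": theta.b}
            hi = dict(args)
            lo = dict(args)
            hi[p] += h
            lo[p] -= h
            plus = model._expected(**hi)
            minus = model._expected(**lo)
            derivs[p] = [(a - b_) / (2.0 * h) for a, b_ in zip(plus, minus)]

    n = len(params)
    per_channel = []
    for c in range(model.n_channels):
        inv_i = 1.0 / (images[c] + _COUNT_FLOOR)
        f = np.empty((n, n))
        for i, pi in enumerate(params):
            for j in range(i, n):
                pj = params[j]
                f[i, j] = f[j, i] = float(
                    np.sum(derivs[pi][c] * derivs[pj][c] * inv_i)
                )
        per_channel.append(f)
    fim = np.sum(per_channel, axis=0)
    crb = _crb_from_fim(fim, params)
    return FisherResult(params=tuple(params), fim=fim, crb=crb,
                        per_channel_fi=tuple(per_channel), sigma_psf=sigma)


@lru_cache(maxsize=32)
def sigma_psf(config: OpticalConfig) -> float:
    """Geometric-mean DD centroid precision of one dipole at s = 1, b = 0.

    σ_psf = √(σ_x0 σ_y0); the DD dipole PSF is circularly symmetric, so
    the two precisions agree (asserted to 0.5%).
    """
    engine = get_engine(config, "DD")
    model = TwoEmitterModel(engine)
    theta = ParameterVector(d=0.0, s=1.0, b=0.0)
    # provisional diffraction-scale step; σ_psf is not yet known here
    scale = config.wavelength / (4.0 * config.numerical_aperture)
    res = fisher_matrix(model, theta, params=("x0", "y0"),
                        length_step_scale=scale)
    sx, sy = res.crb["x0"], res.crb["y0"]
    if abs(sx / sy - 1.0) > 0.005:
        raise RuntimeError(
            f"DD centroid precision anisotropy {sx/sy:.4f}: PSF model is "
            "not circularly symmetric"
        )
    return math.sqrt(sx * sy)


def sigma_d(model: TwoEmitterModel, theta: ParameterVector,
            full_parameter: bool = False) -> float:
    """Separation CRB: 1/√F_dd (one-parameter) or √[F⁻¹]_dd (full).

    In full-parameter mode with a truly zero background the b parameter
    is dropped from the subset: b = 0 is the boundary of the parameter
    space and there is no background to estimate.
    """
    if full_parameter:
        params = ALL_PARAMS if theta.b > 0 else ("d", "alpha", "x0", "y0", "s")
    else:
        params = ("d",)
    return fisher_matrix(model, theta, params=params).crb["d"]


def background_per_pixel(b_sigma_units: float, sigma: float,
                         pixel_size: float) -> float:
    """Convert background from photons/σ_psf² to photons per camera pixel."""
    return b_sigma_units * (pixel_size / sigma) ** 2


def sbr(s: float, b: float, sigma: float, pixel_size: float | None = None,
        b_unit: str = "sigma_psf2", area_factor: float = 10.0) -> float:
    """Signal-to-background ratio s/(A·b) with reference area A = 10 σ_psf².

    ``b_unit`` selects the background convention: photons per σ_psf²
    (native unit of the sweeps) or photons per camera pixel (the model's
    internal unit; requires ``pixel_size``).  b = 0 means signal-only and
    reports infinity.
    """
    if b < 0:
        raise ValueError("background must be nonnegative")
    if b == 0:
        return math.inf
    if b_unit == "sigma_psf2":
        b_sigma = b
    elif b_unit == "pixel":
        if pixel_size is None:
            raise ValueError("pixel_size required for per-pixel background")
        b_sigma = b * (sigma / pixel_size) ** 2
    else:
        raise ValueError("b_unit must be 'sigma_psf2' or 'pixel'")
    return s / (area_factor * b_sigma)
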