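"""Optical configuration: the coordinate authority for all simulations.

Lengths are in nanometres throughout the package.  The default values
correspond to a typical oil-immersion superresolution setup: far-red
emission (680 nm), NA 1.45, aqueous sample behind a standard coverslip
(index stack 1.33 / 1.516 / 1.516).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

__all__ = ["OpticalConfig", "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class OpticalConfig:
    """Geometry and sampling of the imaging model.

    Parameters
    ----------
    wavelength:
        Central emission wavelength (nm).
    bandwidth:
        Detection bandwidth Δλ (nm) set by the emission filter. 0 means
        monochromatic; when positive, spectra are sampled uniformly over
        ``wavelength ± bandwidth/2`` at ``n_wavelengths`` points.
    numerical_aperture:
        NA of the objective; must not exceed ``n_immersion``.
    n_medium, n_coverslip, n_immersion:
        Refractive indices of sample medium, coverslip and immersion oil.
    pupil_grid_n:
        Samples per axis of the square pupil grid.  Kept odd so that the
        grid is symmetric about k = 0 and point inversion is an exact
        index reversal (no interpolation enters the interferometer model).
    image_size:
        Camera pixels per axis per channel.
    pixel_size:
        Camera pixel size (nm); defaults to λ/(8·NA), well below Nyquist.
    subpixel_oversampling:
        Sub-samples per pixel axis used for pixel integration.
    emitter_depth:
        Distance (nm) of the emitter from the medium/coverslip interface.
    n_wavelengths:
        Spectral samples used when ``bandwidth > 0``.
    """

    wavelength: float = 680.0
    bandwidth: float = 0.0
    numerical_aperture: float = 1.45
    n_medium: float = 1.33
    n_coverslip: float = 1.516
    n_immersion: float = 1.516
    pupil_grid_n: int = 129
    image_size: int = 150
    pixel_size: float | None = None
    subpixel_oversampling: int = 2
    emitter_depth: float = 0.0
    n_wavelengths: int = 11

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be nonnegative")
        if self.numerical_aperture <= 0:
            raise ValueError("numerical aperture must be positive")
        if self.numerical_aperture > self.n_immersion:
            raise ValueError(
                f"NA {self.numerical_aperture} exceeds immersion index "
                f"{self.n_immersion}: rays beyond the critical cone cannot "
                "propagate in the immersion medium"
            )
        if self.pupil_grid_n < 3:
            raise ValueError("pupil_grid_n must be >= 3")
        if self.pupil_grid_n % 2 == 0:
            raise ValueError("pupil_grid_n must be odd (symmetric k grid)")
        if self.image_size <= 0 or self.subpixel_oversampling <= 0:
            raise ValueError("image_size and subpixel_oversampling must be positive")
        if self.pixel_size is None:
            object.__setattr__(
                self,
                "pixel_size",
                self.wavelength / (8.0 * self.numerical_aperture),
            )
        elif self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_wavelengths < 2 and self.bandwidth > 0:
            raise ValueError("n_wavelengths must be >= 2 for a finite bandwidth")

    # -- derived sampling ------------------------------------------------

    @property
    def subpixel_n(self) -> int:
        """Samples per axis of the oversampled image grid."""
        return self.image_size * self.subpixel_oversampling

    @property
    def subpixel_size(self) -> float:
        return self.pixel_size / self.subpixel_oversampling

    @property
    def field_of_view(self) -> float:
        """Full image width (nm) of one channel."""
        return self.image_size * self.pixel_size

    def image_coords(self) -> np.ndarray:
        """Centres (nm) of the oversampled image grid, symmetric about 0."""
        n = self.subpixel_n
        return (np.arange(n) - (n - 1) / 2.0) * self.subpixel_size

    def pixel_coords(self) -> np.ndarray:
        """Centres (nm) of the camera pixels, symmetric about 0."""
        n = self.image_size
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_size

    def pupil_k(self, wavelength: float | None = None) -> np.ndarray:
        """1-D grid of transverse wavenumbers (rad/nm), symmetric about 0."""
        lam = self.wavelength if wavelength is None else wavelength
        kmax = 2.0 * np.pi * self.numerical_aperture / lam
        half = self.pupil_grid_n // 2
        return kmax * np.arange(-half, half + 1) / half

    def wavelengths(self) -> np.ndarray:
        """Sampled emission wavelengths (uniform over the detection band)."""
        if self.bandwidth == 0:
            return np.array([self.wavelength])
        return np.linspace(
            self.wavelength - self.bandwidth / 2.0,
            self.wavelength + self.bandwidth / 2.0,
            self.n_wavelengths,
        )

    def replace(self, **kwargs) -> "OpticalConfig":
        if "pixel_size" not in kwargs and (
            "wavelength" in kwargs or "numerical_aperture" in kwargs
        ):
            # recompute the λ/(8 NA) default unless explicitly pinned
            kwargs.setdefault("pixel_size", None)
        return replace(self, **kwargs)


def save_config(config: OpticalConfig, path) -> None:
    """Write the configuration as a flat YAML key-value file."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def load_config(path) -> OpticalConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return OpticalConfig(**data)


def config_hash(config: OpticalConfig) -> str:
    """Short stable hash identifying a configuration (for provenance columns)."""
    canon = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
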