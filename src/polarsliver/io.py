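"""Export helpers: multi-channel TIFF stacks, JSON sidecars, HDF5 pupils."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .config import OpticalConfig, config_hash
from .psf import DetectionPSF
from .pupil import dipole_field_set

__all__ = ["write_detection_psf", "write_pupil_fields", "write_image_stack"]


def write_detection_psf(psf: DetectionPSF, config: OpticalConfig, path) -> None:
    """Channel images as a 32-bit float TIFF stack plus a JSON sidecar."""
    path = Path(path)
    stack = np.stack([ch.values for ch in psf.channels]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "method": psf.method,
        "channels": [ch.channel_label for ch in psf.channels],
        "weights": [str(ch.weight) for ch in psf.channels],
        "config_hash": config_hash(config),
        "pixel_size_nm": config.pixel_size,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_pupil_fields(config: OpticalConfig, path,
                       wavelength: float | None = None) -> None:
    """All six polarized pupil fields as complex HDF5 datasets."""
    fields, grid = dipole_field_set(config, wavelength)
    with h5py.File(path, "w") as fh:
        fh.attrs["wavelength_nm"] = grid.wavelength
        fh.attrs["config_hash"] = config_hash(config)
        fh.create_dataset("kx", data=grid.kx)
        for j, comps in fields.items():
            for l, values in comps.items():
                fh.create_dataset(f"{j}/{l}", data=values)


def write_image_stack(stack: np.ndarray, path) -> None:
    """Poisson sample stacks as multi-channel TIFF (frames, channels, y, x)."""
    tifffile.imwrite(Path(path), stack.astype(np.float32), photometric="minisblack")
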