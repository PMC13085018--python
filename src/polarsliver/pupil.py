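"""Vectorial pupil-plane fields of a dipole emitter behind a high-NA objective.

A fluorophore is modelled as an electric dipole radiating in the sample
medium; the objective maps the collected cone onto a flat pupil.  For a
dipole along j ∈ {x, y, z} the far field after the objective, expressed in
the local radial (p) and azimuthal (s) polarization basis of the pupil, is

    E_R(j) ∝ t_p · (δ_jx cosθ_m cosφ + δ_jy cosθ_m sinφ − δ_jz sinθ_m) / √cosθ_imm
    E_A(j) ∝ t_s · (−δ_jx sinφ + δ_jy cosφ) / √cosθ_imm

where θ_m is the medium-side polar angle (complex beyond the critical
angle, which produces the supercritical-angle-fluorescence ring), θ_imm
the immersion-side angle, 1/√cosθ_imm the Abbe sine-condition apodization,
and t_p/t_s stratified-medium Fresnel transmission amplitudes through the
medium → coverslip → immersion-oil stack.  Fixed-basis horizontal/vertical
components follow by the pupil rotation

    E_H = E_R cosφ − E_A sinφ,   E_V = E_R sinφ + E_A cosφ.

Parity on the (kx, ky) grid, exact by construction: as scalar component
functions, the azimuthal components are odd under (kx, ky) → (−kx, −ky)
for x/y dipoles and identically zero for a z dipole, while the H/V fields
are even for x/y dipoles and odd for a z dipole.  These parities are the
entire mechanism behind the SLIVER null channels, so cosφ and sinφ are
computed as kx/|k| and ky/|k| (sign flips are exact in floating point),
the grid is sampled symmetrically about k = 0, and inversion is an exact
index flip.  The single sample at k = 0, where the polar basis is
singular, carries no energy in this model (a set of measure zero; real
vortex plates have a defect there as well).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import OpticalConfig

__all__ = [
    "PupilField",
    "PupilGrid",
    "dipole_pupil",
    "dipole_field_set",
    "apply_tip_tilt",
    "tip_tilt_phase",
    "invert",
    "fresnel_ts_tp",
    "collected_energy",
    "ORIENTATIONS",
    "POLARIZATIONS",
]

ORIENTATIONS = ("x", "y", "z")
POLARIZATIONS = ("H", "V", "R", "A")


@dataclass(frozen=True)
class PupilGrid:
    """Square symmetric sampling of the pupil disc for one wavelength."""

    kx: np.ndarray  # 1-D (n,), rad/nm
    ky: np.ndarray  # 1-D (n,), rad/nm
    wavelength: float

    @property
    def dk(self) -> float:
        return float(self.kx[1] - self.kx[0])

    @property
    def KX(self) -> np.ndarray:
        return self.kx[np.newaxis, :]

    @property
    def KY(self) -> np.ndarray:
        return self.ky[:, np.newaxis]


@dataclass(frozen=True)
class PupilField:
    """Complex amplitude of one dipole orientation / polarization pair.

    ``values`` is indexed ``[ky, kx]`` and is exactly zero outside the NA
    cutoff circle.
    """

    orientation: str
    polarization: str
    values: np.ndarray
    grid: PupilGrid

    @property
    def wavelength(self) -> float:
        return self.grid.wavelength


def fresnel_ts_tp(n1: float, n2: float, cos1: np.ndarray, cos2: np.ndarray):
    """Fresnel transmission amplitudes (s, p) from medium 1 into medium 2.

    The Im ≥ 0 branch of the cosine must be supplied on the evanescent
    side (beyond the critical angle the transmitted/incident wave is
    inhomogeneous and the coefficients become complex).
    """
    ts = 2.0 * n1 * cos1 / (n1 * cos1 + n2 * cos2)
    tp = 2.0 * n1 * cos1 / (n2 * cos1 + n1 * cos2)
    return ts, tp


def _angles_and_transmission(config: OpticalConfig, grid: PupilGrid):
    """Per-pupil-point angle cosines, stack transmission and apodization."""
    lam = grid.wavelength
    k0 = 2.0 * np.pi / lam
    kr = np.hypot(grid.KX * np.ones_like(grid.KY), grid.KY * np.ones_like(grid.KX))
    na_k = k0 * config.numerical_aperture
    mask = kr <= na_k * (1.0 + 1e-12)

    n_m, n_cs, n_imm = config.n_medium, config.n_coverslip, config.n_immersion
    # the transverse wavenumber is conserved through the index stack
    sin_imm = np.where(mask, kr / (k0 * n_imm), 0.0)
    sin_cs = np.where(mask, kr / (k0 * n_cs), 0.0)
    sin_m = np.where(mask, kr / (k0 * n_m), 0.0)
    cos_imm = np.sqrt(np.clip(1.0 - sin_imm**2, 0.0, None))
    cos_cs = np.sqrt((1.0 - sin_cs**2).astype(complex))
    # principal sqrt puts Im >= 0: the evanescent branch beyond the
    # medium-side critical angle (supercritical-angle fluorescence)
    cos_m = np.sqrt((1.0 - sin_m**2).astype(complex))

    ts1, tp1 = fresnel_ts_tp(n_m, n_cs, cos_m, cos_cs)
    ts2, tp2 = fresnel_ts_tp(n_cs, n_imm, cos_cs, cos_imm.astype(complex))
    ts = ts1 * ts2
    tp = tp1 * tp2

    apod = np.where(mask & (cos_imm > 0), 1.0 / np.sqrt(np.where(cos_imm > 0, cos_imm, 1.0)), 0.0)

    if config.emitter_depth != 0.0:
        # propagation from emitter depth to the interface; beyond the
        # critical angle Im(cos_m) >= 0 yields the evanescent decay
        phase = np.exp(1j * k0 * n_m * cos_m * config.emitter_depth)
        ts = ts * phase
        tp = tp * phase

    return mask, sin_m, cos_m, ts, tp, apod


def _azimuth(grid: PupilGrid):
    """cosφ, sinφ as kx/|k|, ky/|k|; zero at the singular centre sample."""
    KX = grid.KX * np.ones_like(grid.KY)
    KY = grid.KY * np.ones_like(grid.KX)
    kr = np.hypot(KX, KY)
    safe = np.where(kr > 0, kr, 1.0)
    cphi = np.where(kr > 0, KX / safe, 0.0)
    sphi = np.where(kr > 0, KY / safe, 0.0)
    return cphi, sphi


def _ra_fields(config: OpticalConfig, grid: PupilGrid) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Unnormalized (E_R, E_A) component pair for each dipole orientation."""
    mask, sin_m, cos_m, ts, tp, apod = _angles_and_transmission(config, grid)
    cphi, sphi = _azimuth(grid)
    # the centre sample carries no energy (polar basis singular at k=0)
    centre_ok = (cphi != 0.0) | (sphi != 0.0)

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    zero = np.zeros(mask.shape, dtype=complex)
    for j in ORIENTATIONS:
        if j == "x":
            er = tp * cos_m * cphi
            ea = ts * (-sphi)
        elif j == "y":
            er = tp * cos_m * sphi
            ea = ts * cphi
        else:  # z: purely radial (p) polarized, no azimuthal component
            er = np.where(centre_ok, tp * (-sin_m), 0.0)
            ea = zero
        er = np.where(mask, er * apod, 0.0).astype(complex)
        ea = np.where(mask, ea * apod, 0.0).astype(complex)
        out[j] = (er, ea)
    return out


def make_grid(config: OpticalConfig, wavelength: float | None = None) -> PupilGrid:
    lam = config.wavelength if wavelength is None else wavelength
    k = config.pupil_k(lam)
    return PupilGrid(kx=k, ky=k.copy(), wavelength=lam)


def dipole_field_set(config: OpticalConfig,
                     wavelength: float | None = None) -> tuple[dict, PupilGrid]:
    """All six polarized pupil fields of one freely rotating dipole.

    Returns ``(fields, grid)`` with ``fields[j][l]`` for j ∈ {x,y,z},
    l ∈ {R,A,H,V}, jointly normalized so that Σ_j Σ_{l∈{H,V}} Σ_k |field|²
    = 1 (one photon in the pupil; the isotropic orientation average is
    absorbed into this joint normalization).  The same total obtains in
    the R/A basis because the basis rotation preserves intensity
    pointwise.
    """
    grid = make_grid(config, wavelength)
    ra = _ra_fields(config, grid)
    cphi, sphi = _azimuth(grid)

    fields: dict[str, dict[str, np.ndarray]] = {}
    total = 0.0
    for j, (er, ea) in ra.items():
        eh = er * cphi - ea * sphi
        ev = er * sphi + ea * cphi
        fields[j] = {"R": er, "A": ea, "H": eh, "V": ev}
        total += float(np.sum(np.abs(eh) ** 2 + np.abs(ev) ** 2))
    norm = 1.0 / np.sqrt(total)
    for j in fields:
        for l in fields[j]:
            fields[j][l] = fields[j][l] * norm
    return fields, grid


def dipole_pupil(config: OpticalConfig, orientation: str, polarization: str,
                 wavelength: float | None = None) -> PupilField:
    """Single (orientation, polarization) pupil field as a ``PupilField``."""
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    if polarization not in POLARIZATIONS:
        raise ValueError(f"polarization must be one of {POLARIZATIONS}")
    fields, grid = dipole_field_set(config, wavelength)
    return PupilField(
        orientation=orientation,
        polarization=polarization,
        values=fields[orientation][polarization],
        grid=grid,
    )


def tip_tilt_phase(grid: PupilGrid, xe: float, ye: float) -> np.ndarray:
    """exp(−i kx xe − i ky ye): the pupil phase of an emitter at (xe, ye)."""
    return np.exp(-1j * (grid.KX * xe + grid.KY * ye))


def apply_tip_tilt(field: PupilField, xe: float, ye: float) -> PupilField:
    """Shift the emitter to (xe, ye) nm."""
    return PupilField(
        orientation=field.orientation,
        polarization=field.polarization,
        values=field.values * tip_tilt_phase(field.grid, xe, ye),
        grid=field.grid,
    )


def invert(values: np.ndarray) -> np.ndarray:
    """Point inversion (kx,ky) → (−kx,−ky): exact index flip on the grid."""
    return values[::-1, ::-1]


def collected_energy(config: OpticalConfig, wavelength: float | None = None) -> dict[str, float]:
    """Raw (pre-normalization) collected pupil energy per dipole orientation.

    The integrand depends only on the physical transverse wavenumber, so
    the integral over the NA disc is monotone nondecreasing in NA; used
    as the collection-efficiency weight of the one-photon density
    operator and for sanity checks.
    """
    grid = make_grid(config, wavelength)
    ra = _ra_fields(config, grid)
    dk2 = grid.dk ** 2
    return {
        j: float(np.sum(np.abs(er) ** 2 + np.abs(ea) ** 2) * dk2)
        for j, (er, ea) in ra.items()
    }
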