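"""Gaussian and Bessel beam parameters, profile fitting, and a wave-propagation oracle.

Closed-form relations for the two illumination modalities used in light-sheet
microscopy:

* Gaussian beams: hyperbolic width law ``w(z) = w0 * sqrt(1 + (z/zR)^2)``,
  with the confocal parameter ``b = 2 zR`` and a paraxial NA ``λ / (π w0)``.
* Bessel beams generated by an axicon of apex angle ``α`` and refractive
  index ``n``: cone angle ``Θ = (n − 1) α``, depth of focus ``δZ = d / Θ``
  for an input Gaussian of radius ``d``, and core radius
  ``r_c = 2.405 λ / (2π sinΘ)`` (first zero of J0).

Widths are stored internally as 1/e² *intensity* radii; FWHM values appear
only at I/O boundaries, converted with ``FWHM = w * sqrt(2 ln 2)``.

The module also provides a scalar angular-spectrum propagator used as a
numerical oracle for the geometric shadow models in :mod:`.synthetic`: it
reproduces Gaussian divergence, Bessel core formation behind an axicon
phase, and the self-healing of a Bessel beam behind an absorbing obstacle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "GaussianBeamSpec",
    "BesselBeamSpec",
    "BeamProfileSamples",
    "InvalidMediumError",
    "DegenerateBeamError",
    "SamplingError",
    "FWHM_FACTOR",
    "cone_angle",
    "depth_of_focus",
    "bessel_core_radius",
    "gaussian_width",
    "fit_beam_profile",
    "propagate_field",
    "shadow_reconstruction_distance",
    "gaussian_field",
    "axicon_phase",
    "apply_obstacle",
    "field_power",
]

#: FWHM of a Gaussian intensity profile divided by its 1/e^2 radius.
FWHM_FACTOR = float(np.sqrt(2.0 * np.log(2.0)))

#: First zero of the Bessel function J0.
J0_FIRST_ZERO = 2.404825557695773


class InvalidMediumError(ValueError):
    """Axicon refractive index must exceed that of the surrounding medium."""


class DegenerateBeamError(ValueError):
    """Beam geometry collapses (zero cone angle, zero waist, ...)."""


class SamplingError(ValueError):
    """Grid spacing too coarse for the angular content of the field."""


def cone_angle(alpha: float, n: float) -> float:
    """Cone half-angle Θ = (n − 1)·α of the light behind an axicon.

    Parameters
    ----------
    alpha : float
        Axicon apex angle in radians (small-angle regime).
    n : float
        Refractive index of the axicon glass; must exceed 1 (air).
    """
    if n <= 1.0:
        raise InvalidMediumError(f"axicon index n={n} must be > 1")
    if alpha < 0:
        raise ValueError(f"axicon angle must be >= 0, got {alpha}")
    return (n - 1.0) * alpha


def depth_of_focus(d: float, theta: float) -> float:
    """Propagation length δZ = d / Θ of the Bessel zone behind an axicon.

    ``d`` is the 1/e² radius of the incoming Gaussian beam (µm), ``theta``
    the cone angle in radians.  The returned length is in the units of ``d``.
    """
    if theta <= 0:
        raise DegenerateBeamError(f"cone angle must be > 0, got {theta}")
    if d < 0:
        raise ValueError(f"input beam radius must be >= 0, got {d}")
    return d / theta


def bessel_core_radius(wavelength: float, theta: float) -> float:
    """Radius of the central lobe, r_c = 2.405 λ / (2π sinΘ)."""
    if wavelength <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    if not 0 < theta < np.pi / 2:
        raise DegenerateBeamError(f"cone angle must be in (0, pi/2), got {theta}")
    return J0_FIRST_ZERO * wavelength / (2.0 * np.pi * np.sin(theta))


def shadow_reconstruction_distance(obstacle_radius: float, theta: float) -> float:
    """Axial distance r / tanΘ over which a Bessel core rebuilds behind a disk.

    Geometric estimate: the conical shadow of an obstacle of radius ``r``
    closes once the off-axis plane waves (travelling at Θ to the axis) have
    crossed the shadow cylinder.
    """
    if theta <= 0:
        raise DegenerateBeamError(f"cone angle must be > 0, got {theta}")
    if obstacle_radius < 0:
        raise ValueError("obstacle radius must be >= 0")
    return obstacle_radius / np.tan(theta)


@dataclass(frozen=True)
class GaussianBeamSpec:
    """Gaussian illumination beam. Lengths in µm, ``waist_w0`` a 1/e² intensity radius."""

    wavelength: float
    waist_w0: float
    rayleigh_zR: float

    def __post_init__(self) -> None:
        for name in ("wavelength", "waist_w0", "rayleigh_zR"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_waist(cls, wavelength: float, waist_w0: float) -> "GaussianBeamSpec":
        """Construct with the paraxial Rayleigh range zR = π w0² / λ."""
        return cls(wavelength, waist_w0, np.pi * waist_w0**2 / wavelength)

    @property
    def confocal_b(self) -> float:
        """Confocal parameter b = 2 zR (µm)."""
        return 2.0 * self.rayleigh_zR

    @property
    def numerical_aperture(self) -> float:
        """Paraxial divergence NA = λ / (π w0)."""
        return self.wavelength / (np.pi * self.waist_w0)

    @property
    def waist_fwhm(self) -> float:
        """FWHM of the intensity profile at the waist (µm)."""
        return self.waist_w0 * FWHM_FACTOR

    def to_dict(self) -> dict:
        return {
            "type": "gaussian",
            "wavelength_um": self.wavelength,
            "waist_w0_um": self.waist_w0,
            "rayleigh_zR_um": self.rayleigh_zR,
            "confocal_b_um": self.confocal_b,
            "numerical_aperture": self.numerical_aperture,
        }


@dataclass(frozen=True)
class BesselBeamSpec:
    """Bessel illumination beam generated by an axicon.

    Stored degrees of freedom are the physical inputs (λ, α, n, d); the cone
    angle Θ, depth of focus δZ and core radius r_c are derived properties, so
    the defining identities ``δZ·Θ = d`` and ``r_c·sinΘ = 2.405 λ / 2π`` hold
    by construction.
    """

    wavelength: float
    axicon_alpha: float
    refractive_index_n: float
    input_radius_d: float

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.input_radius_d <= 0:
            raise ValueError("input beam radius must be > 0")
        if self.refractive_index_n <= 1.0:
            raise InvalidMediumError(
                f"axicon index n={self.refractive_index_n} must be > 1"
            )
        if self.axicon_alpha <= 0:
            raise DegenerateBeamError("axicon angle must be > 0")

    @classmethod
    def from_cone_angle(
        cls, wavelength: float, theta: float, input_radius_d: float, n: float = 1.46
    ) -> "BesselBeamSpec":
        """Construct from a cone angle by back-solving the axicon angle α = Θ/(n−1)."""
        return cls(wavelength, theta / (n - 1.0), n, input_radius_d)

    @property
    def cone_angle_theta(self) -> float:
        return cone_angle(self.axicon_alpha, self.refractive_index_n)

    @property
    def depth_of_focus_dZ(self) -> float:
        return depth_of_focus(self.input_radius_d, self.cone_angle_theta)

    @property
    def core_radius_rc(self) -> float:
        return bessel_core_radius(self.wavelength, self.cone_angle_theta)

    def to_dict(self) -> dict:
        return {
            "type": "bessel",
            "wavelength_um": self.wavelength,
            "axicon_alpha_rad": self.axicon_alpha,
            "refractive_index_n": self.refractive_index_n,
            "input_radius_d_um": self.input_radius_d,
            "cone_angle_theta_rad": self.cone_angle_theta,
            "depth_of_focus_dZ_um": self.depth_of_focus_dZ,
            "core_radius_rc_um": self.core_radius_rc,
        }


def beam_spec_from_dict(d: dict):
    """Inverse of ``to_dict`` for either beam type (JSON/YAML round trip)."""
    kind = d.get("type")
    if kind == "gaussian":
        return GaussianBeamSpec(
            d["wavelength_um"], d["waist_w0_um"], d["rayleigh_zR_um"]
        )
    if kind == "bessel":
        return BesselBeamSpec(
            d["wavelength_um"],
            d["axicon_alpha_rad"],
            d["refractive_index_n"],
            d["input_radius_d_um"],
        )
    raise ValueError(f"unknown beam spec type {kind!r}")


def beam_spec_to_json(spec) -> str:
    return json.dumps(spec.to_dict(), indent=2, sort_keys=True)


@dataclass
class BeamProfileSamples:
    """Measured beam widths along the axis: FWHM (µm) vs axial position z (µm)."""

    axial_positions_z: np.ndarray
    widths_fwhm: np.ndarray

    def __post_init__(self) -> None:
        self.axial_positions_z = np.asarray(self.axial_positions_z, dtype=float)
        self.widths_fwhm = np.asarray(self.widths_fwhm, dtype=float)
        if self.axial_positions_z.shape != self.widths_fwhm.shape:
            raise ValueError("z and FWHM arrays must have equal length")
        if self.axial_positions_z.ndim != 1:
            raise ValueError("profile samples must be one-dimensional")

    @classmethod
    def from_csv(cls, path) -> "BeamProfileSamples":
        """Read a two-column CSV with header ``z_um,fwhm_um``."""
        arr = np.genfromtxt(path, delimiter=",", names=True)
        return cls(np.atleast_1d(arr["z_um"]), np.atleast_1d(arr["fwhm_um"]))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.axial_positions_z, self.widths_fwhm]),
            delimiter=",",
            header="z_um,fwhm_um",
            comments="",
        )


def gaussian_width(z, spec: GaussianBeamSpec, fwhm: bool = False):
    """Hyperbolic beam-width law w(z) = w0 √(1 + (z/zR)²).

    Returns the 1/e² intensity radius at axial offset ``z`` from the waist,
    or the FWHM if ``fwhm=True``.
    """
    z = np.asarray(z, dtype=float)
    w = spec.waist_w0 * np.sqrt(1.0 + (z / spec.rayleigh_zR) ** 2)
    return w * FWHM_FACTOR if fwhm else w


class BeamFitError(RuntimeError):
    """Beam profile fit could not be performed."""


def fit_beam_profile(
    samples: BeamProfileSamples, wavelength: float
) -> GaussianBeamSpec:
    """Fit the hyperbolic width law to measured FWHM-vs-z samples.

    Least-squares fit of ``w(z) = w0 √(1 + ((z − z0)/zR)²)`` (widths converted
    from FWHM to 1/e² radii first), with the focus position z0 a free nuisance
    parameter.  NA and the confocal parameter follow from the fitted w0, zR.
    """
    z = samples.axial_positions_z
    w = samples.widths_fwhm / FWHM_FACTOR
    if len(np.unique(z)) < 3:
        raise BeamFitError("need >= 3 distinct axial positions to fit w0, zR, z0")
    if not (np.all(np.isfinite(z)) and np.all(np.isfinite(w)) and np.all(w > 0)):
        raise BeamFitError("profile samples must be finite with positive widths")

    def model(z, w0, zR, z0):
        return w0 * np.sqrt(1.0 + ((z - z0) / zR) ** 2)

    i_min = int(np.argmin(w))
    p0 = [w[i_min], max(np.ptp(z) / 4.0, 1e-6), z[i_min]]
    try:
        popt, _ = curve_fit(model, z, w, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise BeamFitError(f"hyperbolic fit failed to converge: {exc}") from exc
    w0, zR = abs(popt[0]), abs(popt[1])
    return GaussianBeamSpec(wavelength, w0, zR)


# ---------------------------------------------------------------------------
# Angular-spectrum propagation oracle
# ---------------------------------------------------------------------------


def _freq_grid(n: int, spacing: float):
    f = np.fft.fftfreq(n, d=spacing)
    return np.meshgrid(f, f, indexing="ij")


def field_power(field: np.ndarray) -> float:
    """Total power (sum of |E|²) of a sampled complex field."""
    return float(np.sum(np.abs(field) ** 2))


def propagate_field(
    field: np.ndarray,
    distance: float,
    wavelength: float,
    grid_spacing: float,
    check_sampling: bool = True,
) -> np.ndarray:
    """Free-space scalar propagation of a sampled complex field.

    Angular-spectrum method: FFT, multiply by the exact transfer function
    ``exp(i 2π z sqrt(1/λ² − fx² − fy²))``, inverse FFT.  Evanescent
    components (fx² + fy² > 1/λ²) are discarded.  For a band-limited field
    the total power is conserved to floating-point precision.

    Raises
    ------
    SamplingError
        If a non-negligible fraction of the spectral power sits in the outer
        10% of the frequency plane (the field is not resolved by the grid) or
        in the evanescent region.
    """
    field = np.asarray(field, dtype=complex)
    if field.ndim != 2 or field.shape[0] != field.shape[1]:
        raise ValueError("field must be a square 2D array")
    n = field.shape[0]
    fx, fy = _freq_grid(n, grid_spacing)
    f2 = fx**2 + fy**2
    spec = np.fft.fft2(field)

    if check_sampling:
        p = np.abs(spec) ** 2
        total = p.sum()
        if total > 0:
            f_nyq = 0.5 / grid_spacing
            outer = p[f2 > (0.9 * f_nyq) ** 2].sum() / total
            evan = p[f2 > 1.0 / wavelength**2].sum() / total
            if outer > 1e-3 or evan > 1e-3:
                raise SamplingError(
                    "field spectrum reaches the grid band edge "
                    f"(outer fraction {outer:.2e}, evanescent {evan:.2e}); "
                    "reduce grid spacing"
                )

    kz_sq = np.maximum(1.0 / wavelength**2 - f2, 0.0)
    prop = np.where(f2 <= 1.0 / wavelength**2, 1.0, 0.0) * np.exp(
        2j * np.pi * distance * np.sqrt(kz_sq)
    )
    return np.fft.ifft2(spec * prop)


def radial_coords(n: int, spacing: float):
    """Centered transverse coordinate grids (x, y, r) for an n×n field, in µm."""
    c = (np.arange(n) - n // 2) * spacing
    x, y = np.meshgrid(c, c, indexing="ij")
    return x, y, np.hypot(x, y)


def gaussian_field(n: int, spacing: float, waist_w0: float) -> np.ndarray:
    """Gaussian amplitude at its waist: |E|² has 1/e² radius ``waist_w0``."""
    _, _, r = radial_coords(n, spacing)
    return np.exp(-(r**2) / waist_w0**2).astype(complex)


def axicon_phase(n: int, spacing: float, theta: float, wavelength: float) -> np.ndarray:
    """Thin-axicon transmission exp(−i 2π sinΘ r / λ) producing a cone of plane waves."""
    _, _, r = radial_coords(n, spacing)
    return np.exp(-2j * np.pi * np.sin(theta) * r / wavelength)


def apply_obstacle(
    field: np.ndarray,
    spacing: float,
    radius: float,
    transmittance: float = 0.0,
    edge_width: float | None = None,
) -> np.ndarray:
    """Multiply a field by a centered circular obstacle of given amplitude transmittance.

    The disk edge is smoothed with a raised-cosine ramp of width ``edge_width``
    (default 2 grid pixels) so the obstacle itself does not inject frequencies
    beyond the grid band limit.
    """
    n = field.shape[0]
    _, _, r = radial_coords(n, spacing)
    if edge_width is None:
        edge_width = 2.0 * spacing
    t = np.clip((r - radius) / max(edge_width, 1e-12), 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * t)  # 0 inside, 1 outside
    mask = transmittance + (1.0 - transmittance) * ramp
    return field * mask
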