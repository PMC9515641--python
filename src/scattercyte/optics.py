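"""Forward light-scattering model of a single cell as a coated sphere.

A suspended cell is idealized as two concentric spheres: the nucleus (core,
refractive index ``ri_nucleus``) inside the cytoplasm (shell,
``ri_cytoplasm``), immersed in buffer.  The exact electromagnetic solution
for this geometry is the Aden–Kerker extension of Mie theory; the observable
is the light-scattering profile (LSP) — scattered intensity versus polar
angle over the instrument's small-angle window (default 2–30 deg at 0.1 deg
steps, HeNe laser at 632.8 nm).

Intensities are relative (no radiometric calibration): downstream matching
is scale-invariant, so only the shape of the profile carries information.

The partial-wave series is truncated at the Wiscombe order
n_max = y + 4 y^(1/3) + 2 where y is the size parameter of the whole cell.
All refractive indices are real (non-absorbing cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._riccati import riccati_chi, riccati_derivative, riccati_psi

__all__ = [
    "OpticalConfig",
    "CoreShellCell",
    "MieCoefficients",
    "LSP",
    "DetectorConfig",
    "size_parameters",
    "coated_sphere_coefficients",
    "scattering_amplitudes",
    "lsp_intensity",
    "lsp_intensity_batch",
    "integrated_intensity",
    "detector_pattern",
    "radial_average",
]

Polarization = Literal["unpolarized", "perpendicular", "parallel"]


@dataclass(frozen=True)
class OpticalConfig:
    """Illumination and angular-readout geometry.

    wavelength_vacuum : nm, laser vacuum wavelength (HeNe default).
    medium_ri : refractive index of the suspension buffer (PBS with a dilute
        viscoelastic polymer; the polymer barely shifts the PBS index).
    angle_min/angle_max/angle_step : degrees; the angular grid is inclusive
        of angle_min with floor((angle_max-angle_min)/angle_step)+1 points.
    """

    wavelength_vacuum: float = 632.8
    medium_ri: float = 1.334
    angle_min: float = 2.0
    angle_max: float = 30.0
    angle_step: float = 0.1
    polarization: Polarization = "unpolarized"

    def __post_init__(self) -> None:
        if self.wavelength_vacuum <= 0:
            raise ValueError("wavelength_vacuum must be positive")
        if self.medium_ri < 1:
            raise ValueError("medium_ri must be >= 1")
        if not (0 < self.angle_min < self.angle_max <= 180):
            raise ValueError("need 0 < angle_min < angle_max <= 180")
        if self.angle_step <= 0:
            raise ValueError("angle_step must be positive")
        if self.polarization not in ("unpolarized", "perpendicular", "parallel"):
            raise ValueError(f"unknown polarization {self.polarization!r}")

    @property
    def angles(self) -> np.ndarray:
        """Angular grid in degrees (inclusive of angle_min)."""
        n = int(np.floor((self.angle_max - self.angle_min) / self.angle_step + 1e-9)) + 1
        return self.angle_min + self.angle_step * np.arange(n)

    def to_dict(self) -> dict:
        return {
            "wavelength_vacuum": self.wavelength_vacuum,
            "medium_ri": self.medium_ri,
            "angle_min": self.angle_min,
            "angle_max": self.angle_max,
            "angle_step": self.angle_step,
            "polarization": self.polarization,
        }


@dataclass(frozen=True)
class CoreShellCell:
    """Four-parameter biophysical cell model.

    diameter : total cell diameter D in micrometres.
    nc_ratio : nucleus-to-cell size ratio (core diameter / total diameter).
    ri_nucleus, ri_cytoplasm : real refractive indices of core and shell.
    """

    diameter: float
    nc_ratio: float
    ri_nucleus: float
    ri_cytoplasm: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not (0 < self.nc_ratio <= 1):
            raise ValueError("nc_ratio must lie in (0, 1]")
        for name in ("ri_nucleus", "ri_cytoplasm"):
            v = getattr(self, name)
            if not (1.0 < v < 2.0):
                raise ValueError(f"{name}={v} outside the physiological range (1, 2)")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.diameter, self.nc_ratio, self.ri_nucleus, self.ri_cytoplasm)


@dataclass(frozen=True)
class MieCoefficients:
    """Partial-wave coefficients a_n, b_n, n = 1..order_count."""

    order_count: int
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        if self.order_count < 1:
            raise ValueError("order_count must be >= 1")
        if len(self.a) != self.order_count or len(self.b) != self.order_count:
            raise ValueError("coefficient arrays must have length order_count")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise FloatingPointError("non-finite partial-wave coefficients")


@dataclass
class LSP:
    """Light-scattering profile of one cell: intensity versus polar angle."""

    angles: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.angles.shape != self.intensities.shape or self.angles.ndim != 1:
            raise ValueError("angles and intensities must be 1-D and equal length")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass(frozen=True)
class DetectorConfig:
    """Idealized camera geometry for rendering an LSP as a 2-D pattern."""

    pixel_count: int = 256
    pixel_pitch: float = 6.5          # micrometres
    propagation_distance: float = 1.0  # millimetres

    def __post_init__(self) -> None:
        if self.pixel_count <= 0 or self.pixel_pitch <= 0 or self.propagation_distance <= 0:
            raise ValueError("all detector parameters must be positive")


# ---------------------------------------------------------------------------
# Nondimensionalization


def size_parameters(cell: CoreShellCell, optics: OpticalConfig) -> tuple[float, float, float, float]:
    """Mie size parameters and relative indices of a cell.

    Returns (x_core, y_total, m_core, m_shell) with
    x = pi * d * n_medium / lambda_vacuum for core and total diameters and
    m = RI / n_medium for nucleus and cytoplasm.
    """
    lam_um = optics.wavelength_vacuum * 1e-3  # nm -> um
    y_total = np.pi * cell.diameter * optics.medium_ri / lam_um
    x_core = cell.nc_ratio * y_total
    m_core = cell.ri_nucleus / optics.medium_ri
    m_shell = cell.ri_cytoplasm / optics.medium_ri
    return x_core, y_total, m_core, m_shell


def wiscombe_order(y: float | np.ndarray) -> int:
    """Series truncation order n_max = ceil(y + 4 y^(1/3) + 2)."""
    y = np.max(np.asarray(y, dtype=np.float64))
    return int(np.ceil(y + 4.0 * y ** (1.0 / 3.0) + 2.0))


# ---------------------------------------------------------------------------
# Coated-sphere partial waves (Aden–Kerker / BHCOAT formulation)


def _coated_coefficients_batch(
    x: np.ndarray, y: np.ndarray, m1: np.ndarray, m2: np.ndarray, n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """a_n, b_n for a batch of coated spheres; arrays shape (n_max, batch).

    x, y: core and total size parameters; m1, m2: core and shell relative
    indices (real).  Orders where the auxiliary functions over/underflow are
    orders far beyond the physical cutoff; their coefficients are set to the
    correct limit 0.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    y = np.atleast_1d(np.asarray(y, dtype=np.float64))
    m1 = np.atleast_1d(np.asarray(m1, dtype=np.float64))
    m2 = np.atleast_1d(np.asarray(m2, dtype=np.float64))
    if np.any(x <= 0) or np.any(y <= 0) or np.any(x > y * (1 + 1e-12)):
        raise ValueError("require 0 < x_core <= y_total")
    if np.any(m1 <= 0) or np.any(m2 <= 0):
        raise ValueError("relative refractive indices must be positive")

    # Degenerate shell (core fills the cell): treat as homogeneous with the
    # core index, avoiding zero-thickness-shell recurrences.
    full_core = x >= y * (1 - 1e-12)
    m2 = np.where(full_core, m1, m2)

    psi_m1x = riccati_psi(n_max, m1 * x)
    psi_m2x = riccati_psi(n_max, m2 * x)
    chi_m2x = riccati_chi(n_max, m2 * x)
    psi_m2y = riccati_psi(n_max, m2 * y)
    chi_m2y = riccati_chi(n_max, m2 * y)
    psi_y = riccati_psi(n_max, y)
    chi_y = riccati_chi(n_max, y)

    dpsi_m1x = riccati_derivative(psi_m1x, m1 * x)
    dpsi_m2x = riccati_derivative(psi_m2x, m2 * x)
    dchi_m2x = riccati_derivative(chi_m2x, m2 * x)
    dpsi_m2y = riccati_derivative(psi_m2y, m2 * y)
    dchi_m2y = riccati_derivative(chi_m2y, m2 * y)
    dpsi_y = riccati_derivative(psi_y, y)
    dchi_y = riccati_derivative(chi_y, y)

    with np.errstate(all="ignore"):
        # Core-boundary auxiliaries; ->0 as the core vanishes or index-matches.
        A = (m2 * psi_m2x * dpsi_m1x - m1 * dpsi_m2x * psi_m1x) / (
            m2 * chi_m2x * dpsi_m1x - m1 * dchi_m2x * psi_m1x
        )
        B = (m2 * psi_m1x * dpsi_m2x - m1 * psi_m2x * dpsi_m1x) / (
            m2 * dchi_m2x * psi_m1x - m1 * dpsi_m1x * chi_m2x
        )
        A = np.where(np.isfinite(A), A, 0.0)
        B = np.where(np.isfinite(B), B, 0.0)

        xi_y = psi_y - 1j * chi_y
        dxi_y = dpsi_y - 1j * dchi_y

        Pa = dpsi_m2y - A * dchi_m2y
        Qa = psi_m2y - A * chi_m2y
        Pb = dpsi_m2y - B * dchi_m2y
        Qb = psi_m2y - B * chi_m2y

        a = (psi_y * Pa - m2 * dpsi_y * Qa) / (xi_y * Pa - m2 * dxi_y * Qa)
        b = (m2 * psi_y * Pb - dpsi_y * Qb) / (m2 * xi_y * Pb - dxi_y * Qb)
        a = np.where(np.isfinite(a), a, 0.0)
        b = np.where(np.isfinite(b), b, 0.0)

    return a[1:], b[1:]


def coated_sphere_coefficients(
    x_core: float, y_total: float, m_core: float, m_shell: float
) -> MieCoefficients:
    """Aden–Kerker partial-wave coefficients of one coated sphere.

    Truncated at the Wiscombe order for y_total.  Raises on nonphysical
    inputs or if the recurrences yield non-finite leading coefficients.
    """
    if not (0 < x_core <= y_total * (1 + 1e-12)):
        raise ValueError("require 0 < x_core <= y_total")
    if not (np.isfinite(m_core) and np.isfinite(m_shell) and m_core > 0 and m_shell > 0):
        raise ValueError("relative indices must be finite and positive")
    n_max = wiscombe_order(y_total)
    a, b = _coated_coefficients_batch(
        np.array([x_core]), np.array([y_total]), np.array([m_core]), np.array([m_shell]), n_max
    )
    return MieCoefficients(order_count=n_max, a=a[:, 0].copy(), b=b[:, 0].copy())


# ---------------------------------------------------------------------------
# Angular functions and amplitudes


def angular_functions(n_max: int, angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """pi_n and tau_n for n = 1..n_max at each angle; shape (n_max, n_angles)."""
    mu = np.cos(np.deg2rad(np.asarray(angles_deg, dtype=np.float64)))
    pi_n = np.zeros((n_max + 1, mu.size))
    tau_n = np.zeros_like(pi_n)
    pi_n[1] = 1.0
    tau_n[1] = mu
    for n in range(2, n_max + 1):
        pi_n[n] = (2 * n - 1) / (n - 1) * mu * pi_n[n - 1] - n / (n - 1) * pi_n[n - 2]
        tau_n[n] = n * mu * pi_n[n] - (n + 1) * pi_n[n - 1]
    return pi_n[1:], tau_n[1:]


def scattering_amplitudes(
    coeffs: MieCoefficients, angles_deg: Sequence[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Complex amplitudes S1 (perpendicular) and S2 (parallel) per angle.

    S1 = sum_n (2n+1)/(n(n+1)) (a_n pi_n + b_n tau_n), S2 with pi/tau swapped.
    """
    angles_deg = np.asarray(angles_deg, dtype=np.float64)
    if np.any(angles_deg <= 0) or np.any(angles_deg >= 180):
        raise ValueError("angles must lie strictly inside (0, 180) degrees")
    pi_n, tau_n = angular_functions(coeffs.order_count, angles_deg)
    n = np.arange(1, coeffs.order_count + 1)
    w = (2 * n + 1) / (n * (n + 1))
    s1 = (w * coeffs.a) @ pi_n + (w * coeffs.b) @ tau_n
    s2 = (w * coeffs.a) @ tau_n + (w * coeffs.b) @ pi_n
    return s1, s2


def _intensity_from_amplitudes(
    s1: np.ndarray, s2: np.ndarray, polarization: Polarization
) -> np.ndarray:
    if polarization == "perpendicular":
        return np.abs(s1) ** 2
    if polarization == "parallel":
        return np.abs(s2) ** 2
    return 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)


def lsp_intensity(cell: CoreShellCell, optics: OpticalConfig = OpticalConfig()) -> LSP:
    """Theoretical LSP of one cell on the optics angular grid."""
    x, y, m1, m2 = size_parameters(cell, optics)
    coeffs = coated_sphere_coefficients(x, y, m1, m2)
    s1, s2 = scattering_amplitudes(coeffs, optics.angles)
    inten = _intensity_from_amplitudes(s1, s2, optics.polarization)
    return LSP(
        angles=optics.angles,
        intensities=inten,
        meta={"cell": cell.as_tuple(), "optics": optics.to_dict()},
    )


def lsp_intensity_batch(
    params: np.ndarray, optics: OpticalConfig = OpticalConfig(), chunk: int = 8192
) -> np.ndarray:
    """Theoretical LSPs for many cells at once.

    params : array (n_cells, 4) of (diameter_um, nc_ratio, ri_nucleus,
        ri_cytoplasm) rows.  Returns intensities with shape
    (n_cells, n_angles).  This is the engine behind lookup-table builds and
    population simulation; identical numerics to :func:`lsp_intensity`.
    """
    params = np.asarray(params, dtype=np.float64)
    if params.ndim != 2 or params.shape[1] != 4:
        raise ValueError("params must have shape (n_cells, 4)")
    lam_um = optics.wavelength_vacuum * 1e-3
    y = np.pi * params[:, 0] * optics.medium_ri / lam_um
    x = params[:, 1] * y
    m1 = params[:, 2] / optics.medium_ri
    m2 = params[:, 3] / optics.medium_ri
    angles = optics.angles
    n_max = wiscombe_order(y)
    pi_n, tau_n = angular_functions(n_max, angles)
    n = np.arange(1, n_max + 1)[:, None]
    w = (2 * n + 1) / (n * (n + 1))
    out = np.empty((params.shape[0], angles.size))
    for lo in range(0, params.shape[0], chunk):
        hi = min(lo + chunk, params.shape[0])
        a, b = _coated_coefficients_batch(x[lo:hi], y[lo:hi], m1[lo:hi], m2[lo:hi], n_max)
        s1 = (w * a).T @ pi_n + (w * b).T @ tau_n
        s2 = (w * a).T @ tau_n + (w * b).T @ pi_n
        out[lo:hi] = _intensity_from_amplitudes(s1, s2, optics.polarization)
    return out


def integrated_intensity(lsp: LSP) -> float:
    """Power scattered into the angular window: trapezoidal integral of
    I(theta) sin(theta) dtheta.  The solid-angle weight makes this the
    physically meaningful window energy (and, unlike the plain angular sum,
    monotone in particle size for fixed indices)."""
    theta = np.deg2rad(lsp.angles)
    return float(np.trapezoid(lsp.intensities * np.sin(theta), theta))


# ---------------------------------------------------------------------------
# Idealized detector pair


def _angle_grid_of_detector(det: DetectorConfig) -> np.ndarray:
    """Polar scattering angle (deg) at each pixel of the detector plane."""
    half = det.pixel_count / 2 - 0.5
    coords = (np.arange(det.pixel_count) - half) * det.pixel_pitch  # um
    xx, yy = np.meshgrid(coords, coords)
    r = np.hypot(xx, yy)
    return np.rad2deg(np.arctan2(r, det.propagation_distance * 1e3))


def detector_pattern(lsp: LSP, det: DetectorConfig) -> np.ndarray:
    """Render an azimuthally symmetric LSP as an idealized camera image.

    Pixels outside the LSP angular range are zero; raises if the LSP range
    exceeds the detector's angular extent entirely.
    """
    theta = _angle_grid_of_detector(det)
    if lsp.angles[0] > theta.max():
        raise ValueError("LSP angular range exceeds detector extent")
    img = np.interp(theta, lsp.angles, lsp.intensities, left=0.0, right=0.0)
    return img


def radial_average(
    image: np.ndarray, det: DetectorConfig, optics: OpticalConfig, n_azimuth: int = 720
) -> LSP:
    """Recover an LSP from a detector image by azimuthal averaging.

    For each grid angle the image is sampled (bilinearly) along the circle
    of the corresponding detector radius and averaged over ``n_azimuth``
    azimuths.  Sampling thin circles rather than binning pixels into finite
    annuli avoids smearing the interference minima across angle bins, so
    the round trip with :func:`detector_pattern` agrees to well within the
    pixel-interpolation error away from the range edges.  Angles beyond the
    detector extent come back as zero.
    """
    from scipy import ndimage

    angles = optics.angles
    half = det.pixel_count / 2 - 0.5
    r_px = det.propagation_distance * 1e3 * np.tan(np.deg2rad(angles)) / det.pixel_pitch
    az = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    rows = half + r_px[:, None] * np.sin(az)[None, :]
    cols = half + r_px[:, None] * np.cos(az)[None, :]
    inside = (
        (rows.min(axis=1) >= 0)
        & (rows.max(axis=1) <= det.pixel_count - 1)
        & (cols.min(axis=1) >= 0)
        & (cols.max(axis=1) <= det.pixel_count - 1)
    )
    sampled = ndimage.map_coordinates(
        np.asarray(image, dtype=np.float64),
        np.stack([rows.ravel(), cols.ravel()]),
        order=1,
        mode="constant",
    ).reshape(rows.shape)
    inten = np.where(inside, sampled.mean(axis=1), 0.0)
    return LSP(angles=angles, intensities=np.clip(inten, 0.0, None), meta={"source": "radial_average"})
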