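"""Independent reference implementations used only as test oracles.

Deliberately written with different algorithms from the package:

* ``bhmie_coefficients`` — homogeneous-sphere Mie partial waves via the
  classical logarithmic-derivative downward recurrence (BHMIE style), scalar
  Python loops, no shared code with the package's coated-sphere path.
* ``rayleigh_homogeneous`` / ``rayleigh_coated`` — closed-form dipole limits,
  including the coated-sphere polarizability with core volume fraction f.
* ``brute_force_coated_lsp`` — scalar, per-order evaluation of the coated
  partial waves using scipy's spherical Bessel functions (the package uses
  hand-vectorized recurrences instead).
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from scipy import special


def bhmie_coefficients(x: float, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Homogeneous Mie a_n, b_n via logarithmic-derivative downward recurrence."""
    n_max = int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    n_start = n_max + 15
    # Log-derivative D_n(mx) downward
    d = [0.0] * (n_start + 1)
    mx = m * x
    for n in range(n_start, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    # Riccati-Bessel psi, chi upward at x
    psi_m1, psi_0 = math.cos(x), math.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi_0 = -math.sin(x), math.cos(x)
    a = np.zeros(n_max, dtype=complex)
    b = np.zeros(n_max, dtype=complex)
    psi_nm1, psi_n = psi_m1, psi_0
    chi_nm1, chi_n = chi_m1, chi_0
    for n in range(1, n_max + 1):
        psi = (2 * n - 1) / x * psi_n - psi_nm1
        chi = (2 * n - 1) / x * chi_n - chi_nm1
        xi = complex(psi, -chi)
        xi_prev = complex(psi_n, -chi_n)
        ta = d[n] / m + n / x
        tb = d[n] * m + n / x
        a[n - 1] = (ta * psi - psi_n) / (ta * xi - xi_prev)
        b[n - 1] = (tb * psi - psi_n) / (tb * xi - xi_prev)
        psi_nm1, psi_n = psi_n, psi
        chi_nm1, chi_n = chi_n, chi
    return a, b


def bhmie_lsp(
    diameter_um: float,
    ri: float,
    angles_deg: np.ndarray,
    wavelength_nm: float = 632.8,
    medium_ri: float = 1.334,
    polarization: str = "unpolarized",
) -> np.ndarray:
    """Unpolarized LSP of a homogeneous sphere, scalar summation throughout."""
    x = math.pi * diameter_um * medium_ri / (wavelength_nm * 1e-3)
    m = ri / medium_ri
    a, b = bhmie_coefficients(x, m)
    return _scalar_intensity(a, b, angles_deg, polarization)


def _scalar_intensity(a, b, angles_deg, polarization="unpolarized"):
    n_max = len(a)
    out = np.zeros(len(angles_deg))
    for k, th in enumerate(np.asarray(angles_deg, dtype=float)):
        mu = math.cos(math.radians(th))
        s1 = 0j
        s2 = 0j
        pi_prev, pi_cur = 0.0, 1.0
        for n in range(1, n_max + 1):
            tau = n * mu * pi_cur - (n + 1) * pi_prev
            w = (2 * n + 1) / (n * (n + 1))
            s1 += w * (a[n - 1] * pi_cur + b[n - 1] * tau)
            s2 += w * (a[n - 1] * tau + b[n - 1] * pi_cur)
            pi_next = (2 * n + 1) / n * mu * pi_cur - (n + 1) / n * pi_prev
            pi_prev, pi_cur = pi_cur, pi_next
        if polarization == "perpendicular":
            out[k] = abs(s1) ** 2
        elif polarization == "parallel":
            out[k] = abs(s2) ** 2
        else:
            out[k] = 0.5 * (abs(s1) ** 2 + abs(s2) ** 2)
    return out


def rayleigh_homogeneous(x: float, m: float, angles_deg: np.ndarray) -> np.ndarray:
    """Dipole-limit unpolarized intensity for a small homogeneous sphere."""
    alpha = (m**2 - 1) / (m**2 + 2)
    mu = np.cos(np.deg2rad(angles_deg))
    pref = x**6 * alpha**2
    return 0.5 * pref * (1 + mu**2)


def rayleigh_coated(x: float, y: float, m1: float, m2: float, angles_deg: np.ndarray) -> np.ndarray:
    """Dipole-limit unpolarized intensity for a small coated sphere.

    Classical coated-sphere polarizability with core volume fraction
    f = (x/y)^3 and permittivities eps = m^2 (medium = 1 in relative units).
    """
    e1, e2 = m1**2, m2**2
    f = (x / y) ** 3
    num = (e2 - 1) * (e1 + 2 * e2) + f * (e1 - e2) * (1 + 2 * e2)
    den = (e2 + 2) * (e1 + 2 * e2) + f * (2 * e2 - 2) * (e1 - e2)
    alpha = num / den
    mu = np.cos(np.deg2rad(angles_deg))
    return 0.5 * y**6 * alpha**2 * (1 + mu**2)


def brute_force_coated_lsp(
    diameter_um: float,
    nc_ratio: float,
    ri_nucleus: float,
    ri_cytoplasm: float,
    angles_deg: np.ndarray,
    wavelength_nm: float = 632.8,
    medium_ri: float = 1.334,
) -> np.ndarray:
    """Coated-sphere LSP by direct per-order evaluation with scipy Bessels."""
    lam_um = wavelength_nm * 1e-3
    y = math.pi * diameter_um * medium_ri / lam_um
    x = nc_ratio * y
    m1 = ri_nucleus / medium_ri
    m2 = ri_cytoplasm / medium_ri
    n_max = int(math.ceil(y + 4.0 * y ** (1.0 / 3.0) + 2.0))

    def psi(n, z):
        return z * special.spherical_jn(n, z)

    def dpsi(n, z):
        return special.spherical_jn(n, z) + z * special.spherical_jn(n, z, derivative=True)

    def chi(n, z):
        return -z * special.spherical_yn(n, z)

    def dchi(n, z):
        return -(special.spherical_yn(n, z) + z * special.spherical_yn(n, z, derivative=True))

    a = np.zeros(n_max, dtype=complex)
    b = np.zeros(n_max, dtype=complex)
    for n in range(1, n_max + 1):
        with np.errstate(all="ignore"):
            An_num = m2 * psi(n, m2 * x) * dpsi(n, m1 * x) - m1 * dpsi(n, m2 * x) * psi(n, m1 * x)
            An_den = m2 * chi(n, m2 * x) * dpsi(n, m1 * x) - m1 * dchi(n, m2 * x) * psi(n, m1 * x)
            Bn_num = m2 * psi(n, m1 * x) * dpsi(n, m2 * x) - m1 * psi(n, m2 * x) * dpsi(n, m1 * x)
            Bn_den = m2 * dchi(n, m2 * x) * psi(n, m1 * x) - m1 * dpsi(n, m1 * x) * chi(n, m2 * x)
            An = An_num / An_den if An_den != 0 else 0.0
            Bn = Bn_num / Bn_den if Bn_den != 0 else 0.0
            if not np.isfinite(An):
                An = 0.0
            if not np.isfinite(Bn):
                Bn = 0.0
            xi_y = complex(psi(n, y), -chi(n, y))
            dxi_y = complex(dpsi(n, y), -dchi(n, y))
            Pa = dpsi(n, m2 * y) - An * dchi(n, m2 * y)
            Qa = psi(n, m2 * y) - An * chi(n, m2 * y)
            Pb = dpsi(n, m2 * y) - Bn * dchi(n, m2 * y)
            Qb = psi(n, m2 * y) - Bn * chi(n, m2 * y)
            a[n - 1] = (psi(n, y) * Pa - m2 * dpsi(n, y) * Qa) / (xi_y * Pa - m2 * dxi_y * Qa)
            b[n - 1] = (m2 * psi(n, y) * Pb - dpsi(n, y) * Qb) / (m2 * xi_y * Pb - dxi_y * Qb)
            if not np.isfinite(a[n - 1]):
                a[n - 1] = 0.0
            if not np.isfinite(b[n - 1]):
                b[n - 1] = 0.0
    return _scalar_intensity(a, b, angles_deg)
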