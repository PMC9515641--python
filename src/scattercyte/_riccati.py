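"""Vectorized Riccati–Bessel functions for real arguments.

The coated-sphere partial-wave solution needs psi_n(z) = z j_n(z) and
chi_n(z) = -z y_n(z) (plus derivatives) for every order 0..n_max at every
grid argument.  Building a lookup table evaluates these at ~10^6 (order,
argument) pairs, so the functions are computed by the classical three-term
recurrences, vectorized over the argument axis: upward for chi (which grows
with order and is therefore stable upward) and Miller's downward recurrence
for psi (stable downward), normalized against psi_0(z) = sin z.

All arguments here are real and strictly positive: the cell model uses
non-absorbing refractive indices.
"""

from __future__ import annotations

import numpy as np

__all__ = ["riccati_psi", "riccati_chi", "riccati_derivative"]

# Extra orders above n_max for Miller's downward start; 16 is ample for
# float64 once n_start exceeds the Bessel turning point.
_MILLER_PAD = 16

# Rescale threshold keeping unnormalized downward iterates inside float64.
_RESCALE_AT = 1e250
_RESCALE_BY = 1e-250


def riccati_psi(n_max: int, z: np.ndarray) -> np.ndarray:
    """psi_n(z) = z j_n(z) for n = 0..n_max, shape (n_max+1, len(z)).

    Downward (Miller) recurrence with periodic rescaling, so arguments much
    smaller than n_max (where j_n underflows) yield 0 rather than overflow.
    """
    z = np.asarray(z, dtype=np.float64)
    if np.any(z <= 0):
        raise ValueError("riccati_psi requires strictly positive arguments")
    n_start = n_max + _MILLER_PAD
    j_above = np.zeros_like(z)
    j_cur = np.full_like(z, 1e-30)
    out = np.empty((n_max + 1, z.size))
    for n in range(n_start, 0, -1):
        j_below = (2 * n + 1) / z * j_cur - j_above
        j_above, j_cur = j_cur, j_below
        if n - 1 <= n_max:
            out[n - 1] = j_cur
        big = np.abs(j_cur) > _RESCALE_AT
        if big.any():
            j_cur = np.where(big, j_cur * _RESCALE_BY, j_cur)
            j_above = np.where(big, j_above * _RESCALE_BY, j_above)
            out[:, big] *= _RESCALE_BY  # rows not yet written hold garbage; harmless
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        scale = (np.sin(z) / z) / out[0]
        psi = out * scale * z
    return psi


def riccati_chi(n_max: int, z: np.ndarray) -> np.ndarray:
    """chi_n(z) = -z y_n(z) for n = 0..n_max, shape (n_max+1, len(z)).

    Upward recurrence; chi grows with order, so this is stable.  Values may
    overflow to inf for orders far above z — callers treat the associated
    partial waves as negligible (see ``coated_sphere_coefficients``).
    """
    z = np.asarray(z, dtype=np.float64)
    chi = np.empty((n_max + 1, z.size))
    chi[0] = np.cos(z)
    if n_max >= 1:
        chi[1] = np.cos(z) / z + np.sin(z)
    with np.errstate(over="ignore", invalid="ignore"):
        for n in range(1, n_max):
            chi[n + 1] = (2 * n + 1) / z * chi[n] - chi[n - 1]
    return chi


def riccati_derivative(f: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Derivative of a Riccati–Bessel family from the recurrence
    f'_n = f_{n-1} - n f_n / z (valid for psi, chi and xi alike).

    Row 0 is left as NaN: order 0 never enters the partial-wave sums.
    """
    n = np.arange(f.shape[0])[:, None]
    out = np.empty_like(f)
    out[0] = np.nan
    with np.errstate(invalid="ignore", over="ignore"):
        out[1:] = f[:-1] - n[1:] * f[1:] / z
    return out
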