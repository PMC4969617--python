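"""Lorenz-Mie partial-wave coefficients for solid and coated spheres.

The implementation follows the numerically stable route used by the
classic BHMIE/BHCOAT programs: the logarithmic derivative
``D_n(z) = psi_n'(z)/psi_n(z)`` is generated by *downward* recurrence
(upward recurrence is unstable for absorbing media), and all interior
Riccati-Bessel functions of complex argument enter only through bounded
ratios (``chi_{n-1}/chi_n``, ``chi_n/psi_n``), so strongly absorbing
metallic shells do not overflow. Riccati-Bessel functions of the real
outer size parameter are generated by upward recurrence.

Conventions: time dependence ``exp(-i w t)``, absorbing refractive
indices have *positive* imaginary part (``m = n + ik``, ``k >= 0``).

Size parameters are ``x = 2 pi n_medium r / lambda`` and relative
indices ``m = m_material / n_medium``.
"""
from __future__ import annotations

import math

import numpy as np

from .exceptions import ConvergenceError, GeometryError, ValidationError

__all__ = ["wiscombe_n_max", "mie_solid", "mie_coated", "cross_sections"]

#: Relative tolerance below which a slightly negative C_abs is clamped to 0.
ABS_CLAMP_RTOL = 1e-6


def wiscombe_n_max(x: float) -> int:
    """Wiscombe series-truncation criterion ``ceil(x + 4 x^(1/3) + 2)``."""
    return int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def _check_finite(**kw) -> None:
    for name, v in kw.items():
        if not np.all(np.isfinite([np.real(v), np.imag(v)])):
            raise ValidationError(f"{name} must be finite, got {v!r}")


def _log_deriv_psi(z: complex, n_max: int) -> np.ndarray:
    """``D_n(z) = psi_n'(z)/psi_n(z)`` for n = 1..n_max, downward recurrence."""
    n_start = max(n_max, int(abs(z))) + 16
    d = 0.0 + 0.0j
    out = np.empty(n_start + 1, dtype=complex)
    out[n_start] = d
    for n in range(n_start, 0, -1):
        out[n - 1] = n / z - 1.0 / (out[n] + n / z)
    return out[1 : n_max + 1]


def _tan(z: complex) -> complex:
    # tan via exp(2iz); bounded for Im(z) >= 0 (absorbing media).
    t = np.exp(2j * z)
    return -1j * (t - 1.0) / (t + 1.0)


def _chi_ratios(z: complex, n_max: int) -> np.ndarray:
    """``s_n = chi_n(z)/chi_{n-1}(z)`` for n = 1..n_max (upward, stable)."""
    s = np.empty(n_max + 1, dtype=complex)
    s[1] = 1.0 / z + _tan(z)
    for n in range(2, n_max + 1):
        s[n] = (2 * n - 1) / z - 1.0 / s[n - 1]
    return s[1:]


def _chi_over_psi(z: complex, n_max: int, d1: np.ndarray, s: np.ndarray) -> np.ndarray:
    """``Q_n = chi_n(z)/psi_n(z)`` for n = 1..n_max via ratio recurrence."""
    q = np.empty(n_max, dtype=complex)
    q_prev = 1.0 / _tan(z)  # cot z = chi_0/psi_0
    for i, n in enumerate(range(1, n_max + 1)):
        p = 1.0 / (d1[i] + n / z)  # psi_n/psi_{n-1}
        q_prev = q_prev * s[i] / p
        q[i] = q_prev
    return q


def _riccati_real(x: float, n_max: int):
    """psi_n, chi_n for n = -1..n_max at real x (upward recurrence)."""
    psi = np.empty(n_max + 2)
    chi = np.empty(n_max + 2)
    psi[0], psi[1] = math.cos(x), math.sin(x)  # n = -1, 0
    chi[0], chi[1] = -math.sin(x), math.cos(x)
    for n in range(1, n_max + 1):
        f = (2 * n - 1) / x
        psi[n + 1] = f * psi[n] - psi[n - 1]
        chi[n + 1] = f * chi[n] - chi[n - 1]
    return psi, chi


def _coefficients_from_deriv(x: float, m: complex, dt_a: np.ndarray,
                             dt_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assemble a_n, b_n from effective interior logarithmic derivatives."""
    n_max = len(dt_a)
    psi, chi = _riccati_real(x, n_max)
    n = np.arange(1, n_max + 1)
    psi_n, psi_nm1 = psi[n + 1], psi[n]
    xi_n = psi[n + 1] - 1j * chi[n + 1]
    xi_nm1 = psi[n] - 1j * chi[n]
    fa = dt_a / m + n / x
    fb = dt_b * m + n / x
    a = (fa * psi_n - psi_nm1) / (fa * xi_n - xi_nm1)
    b = (fb * psi_n - psi_nm1) / (fb * xi_n - xi_nm1)
    return a, b


def mie_solid(x: float, m: complex, n_max: int | None = None):
    """Partial-wave coefficients (a_n, b_n) of a homogeneous sphere.

    Parameters
    ----------
    x : float
        Size parameter (> 0).
    m : complex
        Refractive index relative to the medium, Im(m) >= 0.
    n_max : int, optional
        Series truncation; defaults to the Wiscombe criterion.
    """
    _check_finite(x=x, m=m)
    if x <= 0:
        raise ValidationError(f"size parameter must be > 0, got {x}")
    if n_max is None:
        n_max = wiscombe_n_max(x)
    if n_max < 1:
        raise ValidationError(f"n_max must be >= 1, got {n_max}")
    d1 = _log_deriv_psi(m * x, n_max)
    return _coefficients_from_deriv(x, m, d1, d1)


def mie_coated(x_core: float, x_outer: float, m_core: complex,
               m_shell: complex, n_max: int | None = None):
    """Partial-wave coefficients of a concentric core-shell sphere.

    Uses the Bohren & Huffman coated-sphere solution rewritten entirely
    in terms of logarithmic derivatives and bounded Bessel-function
    ratios, which remains stable for metallic (strongly absorbing)
    shells where naive evaluation of ``psi_n``/``chi_n`` at complex
    argument overflows.
    """
    _check_finite(x_core=x_core, x_outer=x_outer, m_core=m_core, m_shell=m_shell)
    if not 0 < x_core < x_outer:
        raise GeometryError(
            f"need 0 < x_core < x_outer, got x_core={x_core}, x_outer={x_outer}"
        )
    if n_max is None:
        n_max = wiscombe_n_max(x_outer)
    if n_max < 1:
        raise ValidationError(f"n_max must be >= 1, got {n_max}")

    z1 = m_core * x_core   # core index at inner boundary
    z2 = m_shell * x_core  # shell index at inner boundary
    z3 = m_shell * x_outer  # shell index at outer boundary
    n = np.arange(1, n_max + 1)

    d1_z1 = _log_deriv_psi(z1, n_max)
    d1_z2 = _log_deriv_psi(z2, n_max)
    d1_z3 = _log_deriv_psi(z3, n_max)
    s_z2 = _chi_ratios(z2, n_max)
    s_z3 = _chi_ratios(z3, n_max)
    g_z2 = 1.0 / s_z2 - n / z2  # chi_n'/chi_n at z2
    g_z3 = 1.0 / s_z3 - n / z3
    w_z2 = 1.0 / _chi_over_psi(z2, n_max, d1_z2, s_z2)  # psi_n/chi_n at z2
    q_z3 = _chi_over_psi(z3, n_max, d1_z3, s_z3)        # chi_n/psi_n at z3

    # Interior-boundary mixing coefficients (B&H A_n, B_n) in ratio form.
    a_mix = w_z2 * (m_shell * d1_z1 - m_core * d1_z2) / (
        m_shell * d1_z1 - m_core * g_z2)
    b_mix = w_z2 * (m_shell * d1_z2 - m_core * d1_z1) / (
        m_shell * g_z2 - m_core * d1_z1)

    # Effective logarithmic derivatives at the outer boundary.
    dt_a = (d1_z3 - a_mix * q_z3 * g_z3) / (1.0 - a_mix * q_z3)
    dt_b = (d1_z3 - b_mix * q_z3 * g_z3) / (1.0 - b_mix * q_z3)
    return _coefficients_from_deriv(x_outer, m_shell, dt_a, dt_b)


def cross_sections(coefficients, wavelength_nm: float, medium_index: float):
    """Absorption, scattering and extinction cross-sections in nm².

    Parameters
    ----------
    coefficients : (a_n, b_n)
        Partial-wave coefficients from :func:`mie_solid` / :func:`mie_coated`.
    wavelength_nm : float
        Vacuum wavelength.
    medium_index : float
        Real refractive index of the host medium.

    Returns
    -------
    (C_abs, C_sca, C_ext) : tuple of float
        ``C_abs = C_ext - C_sca``; a negative difference within
        ``ABS_CLAMP_RTOL`` (relative to C_ext) is clamped to zero, a
        larger one raises :class:`ConvergenceError`.
    """
    a, b = coefficients
    a = np.asarray(a, dtype=complex)
    b = np.asarray(b, dtype=complex)
    k = 2.0 * np.pi * medium_index / wavelength_nm  # nm^-1
    n = np.arange(1, len(a) + 1)
    w = 2 * n + 1
    c_sca = 2.0 * np.pi / k**2 * float(np.sum(w * (np.abs(a) ** 2 + np.abs(b) ** 2)))
    c_ext = 2.0 * np.pi / k**2 * float(np.sum(w * np.real(a + b)))
    c_abs = c_ext - c_sca
    if c_abs < 0:
        scale = max(abs(c_ext), abs(c_sca))
        if scale > 0 and -c_abs > ABS_CLAMP_RTOL * scale:
            raise ConvergenceError(
                f"C_abs = {c_abs:.3e} nm² is negative beyond tolerance; "
                "increase n_max"
            )
        c_abs = 0.0
    return c_abs, c_sca, c_ext
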