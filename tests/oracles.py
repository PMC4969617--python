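"""Independent oracles for the test suite.

These deliberately avoid the package's recurrence-based code paths:
Mie coefficients are evaluated directly from scipy's spherical Bessel
functions (which accept complex arguments), and small-particle limits
come from the quasi-static closed forms.
"""
import numpy as np
from scipy.special import spherical_jn, spherical_yn


def _psi(n, z):
    return z * spherical_jn(n, z)


def _psi_d(n, z):
    return spherical_jn(n, z) + z * spherical_jn(n, z, derivative=True)


def _chi(n, z):
    return -z * spherical_yn(n, z)


def _chi_d(n, z):
    return -(spherical_yn(n, z) + z * spherical_yn(n, z, derivative=True))


def _xi(n, z):
    return _psi(n, z) - 1j * _chi(n, z)


def _xi_d(n, z):
    return _psi_d(n, z) - 1j * _chi_d(n, z)


def mie_solid_direct(x, m, n_max):
    """a_n, b_n from the textbook formulas, direct Bessel evaluation."""
    a = np.zeros(n_max, complex)
    b = np.zeros(n_max, complex)
    mx = m * x
    for i, n in enumerate(range(1, n_max + 1)):
        a[i] = (m * _psi(n, mx) * _psi_d(n, x) - _psi(n, x) * _psi_d(n, mx)) / (
            m * _psi(n, mx) * _xi_d(n, x) - _xi(n, x) * _psi_d(n, mx))
        b[i] = (_psi(n, mx) * _psi_d(n, x) - m * _psi(n, x) * _psi_d(n, mx)) / (
            _psi(n, mx) * _xi_d(n, x) - m * _xi(n, x) * _psi_d(n, mx))
    return a, b


def mie_coated_direct(x1, x2, m1, m2, n_max):
    """Coated-sphere a_n, b_n, direct Bessel evaluation (no recurrences)."""
    a = np.zeros(n_max, complex)
    b = np.zeros(n_max, complex)
    for i, n in enumerate(range(1, n_max + 1)):
        A = (m2 * _psi(n, m2 * x1) * _psi_d(n, m1 * x1)
             - m1 * _psi_d(n, m2 * x1) * _psi(n, m1 * x1)) / (
            m2 * _chi(n, m2 * x1) * _psi_d(n, m1 * x1)
            - m1 * _chi_d(n, m2 * x1) * _psi(n, m1 * x1))
        B = (m2 * _psi(n, m1 * x1) * _psi_d(n, m2 * x1)
             - m1 * _psi(n, m2 * x1) * _psi_d(n, m1 * x1)) / (
            m2 * _chi_d(n, m2 * x1) * _psi(n, m1 * x1)
            - m1 * _psi_d(n, m1 * x1) * _chi(n, m2 * x1))
        f = _psi(n, m2 * x2) - A * _chi(n, m2 * x2)
        fd = _psi_d(n, m2 * x2) - A * _chi_d(n, m2 * x2)
        g = _psi(n, m2 * x2) - B * _chi(n, m2 * x2)
        gd = _psi_d(n, m2 * x2) - B * _chi_d(n, m2 * x2)
        a[i] = (_psi(n, x2) * fd - m2 * _psi_d(n, x2) * f) / (
            _xi(n, x2) * fd - m2 * _xi_d(n, x2) * f)
        b[i] = (m2 * _psi(n, x2) * gd - _psi_d(n, x2) * g) / (
            m2 * _xi(n, x2) * gd - _xi_d(n, x2) * g)
    return a, b


def rayleigh_solid_cross_sections(x, m, wavelength_nm, medium_index):
    """Dipole (Rayleigh) limit: C_abs = k Im(alpha), C_sca = k^4 |alpha|^2/(6 pi).

    alpha is the Clausius-Mossotti polarizability of a sphere of radius
    r = x / k relative to the medium.
    """
    k = 2.0 * np.pi * medium_index / wavelength_nm  # nm^-1
    r = x / k
    alpha = 4.0 * np.pi * r**3 * (m**2 - 1.0) / (m**2 + 2.0)
    c_abs = k * np.imag(alpha)
    c_sca = k**4 * np.abs(alpha) ** 2 / (6.0 * np.pi)
    return c_abs, c_sca, c_abs + c_sca


def quasistatic_coated_a1(x1, x2, m1, m2):
    """Electric-dipole coefficient of a small coated sphere (closed form)."""
    e1, e2 = m1**2, m2**2
    f = (x1 / x2) ** 3
    alpha = ((e2 - 1.0) * (e1 + 2.0 * e2) + f * (e1 - e2) * (1.0 + 2.0 * e2)) / (
        (e2 + 2.0) * (e1 + 2.0 * e2) + f * (2.0 * e2 - 2.0) * (e1 - e2))
    return -2j / 3.0 * x2**3 * alpha


def rotate_about(image, center_xy, angle_deg, order=1):
    """Rotate an image about an arbitrary point (bilinear), same shape."""
    from scipy import ndimage

    h, w = image.shape
    cx, cy = center_xy
    th = np.deg2rad(angle_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    # inverse map: output pixel -> source coordinates
    xs = np.cos(th) * (xx - cx) + np.sin(th) * (yy - cy) + cx
    ys = -np.sin(th) * (xx - cx) + np.cos(th) * (yy - cy) + cy
    return ndimage.map_coordinates(image, [ys, xs], order=order, mode="nearest")
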