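"""Independent brute-force oracle for 3D Zernike moments.

Evaluates the basis per voxel from first principles: spherical harmonics
come from scipy.special and the radial polynomials are orthonormalized
symbolically (exact rational Gram-Schmidt over the monomials r^(l+2k) with
the unit-ball radial measure), entirely independent of the geometric-moment
path used by the implementation.
"""

from fractions import Fraction
from math import pi, sqrt

import numpy as np
from scipy.special import sph_harm_y


def radial_polynomials(order):
    """Exact Gram-Schmidt radial polynomials R_nl.

    Returns {(n, l): {k: coeff of r^(l+2k)}} normalized so that
    3 * integral_0^1 R_nl^2 r^2 dr = 1, leading coefficient positive.
    """
    out = {}
    for l in range(order + 1):
        kmax = (order - l) // 2

        def ip(u, v):
            return sum(
                cu * cv * Fraction(1, (l + 2 * a) + (l + 2 * b) + 3)
                for a, cu in u.items()
                for b, cv in v.items()
            )

        basis = []
        for k in range(kmax + 1):
            vec = {k: Fraction(1)}
            for prev in basis:
                proj = 3 * ip(vec, prev)  # prev has 3*<prev,prev> = 1
                for b, cb in prev.items():
                    vec[b] = vec.get(b, Fraction(0)) - proj * cb
            nrm = sqrt(3 * float(ip(vec, vec)))
            sign = 1.0 if vec[k] > 0 else -1.0
            poly = {b: sign * float(cb) / nrm for b, cb in vec.items()}
            # re-rationalize so later projections stay exact
            basis.append(
                {b: Fraction(c).limit_denominator(10**14) for b, c in poly.items()}
            )
            out[(2 * k + l, l)] = poly
    return out


def brute_force_moments(values, order):
    """Per-voxel numerical integration of f * conj(Z_nlm) over the unit ball.

    Returns {(n, l, m): complex} for all m in [-l, l].
    """
    values = np.asarray(values, dtype=float)
    dim = values.shape[0]
    ax = (np.arange(dim) + 0.5 - dim / 2) * (2.0 / dim)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    nz = values != 0
    xv, yv, zv, fv = x[nz], y[nz], z[nz], values[nz]
    r = np.sqrt(xv**2 + yv**2 + zv**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zv / np.where(r > 0, r, 1), 0), -1, 1))
    phi = np.arctan2(yv, xv)
    dvol = (2.0 / dim) ** 3

    radials = radial_polynomials(order)
    result = {}
    for (n, l), poly in sorted(radials.items()):
        rad = sum(c * r ** (l + 2 * k) for k, c in poly.items())
        for m in range(-l, l + 1):
            ylm = sph_harm_y(l, m, theta, phi) * sqrt(4 * pi)
            result[(n, l, m)] = (
                (3.0 / (4.0 * pi)) * np.sum(fv * rad * np.conj(ylm)) * dvol
            )
    return result
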