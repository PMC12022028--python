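"""Circular (directional) helpers shared across modules.

Angles are degrees at every public boundary of the package; these helpers
work in degrees unless the name says otherwise.  0 deg is horizontal
rightward motion, counter-clockwise positive.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, i1e

TWO_PI = 2.0 * np.pi

#: Concentrations above this are clipped; beyond it a von Mises is
#: numerically indistinguishable from a wrapped normal with sd < 0.6 deg.
KAPPA_CAP = 1.0e4


def wrap_deg(theta):
    """Wrap angles into [0, 360)."""
    return np.mod(theta, 360.0)


def wrap_signed_deg(theta):
    """Wrap angles into [-180, 180)."""
    return np.mod(np.asarray(theta) + 180.0, 360.0) - 180.0


def vm_logpdf_deg(theta_deg, mu_deg, kappa):
    """Log density (per degree) of a von Mises distribution.

    kappa = 0 gives the uniform density 1/360.  Uses exponentially scaled
    Bessel functions so large concentrations stay finite.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    mu = np.deg2rad(np.asarray(mu_deg, dtype=float))
    kappa = np.asarray(kappa, dtype=float)
    # density per radian, then change of variables to per degree
    logp = kappa * (np.cos(theta - mu) - 1.0) - np.log(TWO_PI * i0e(kappa))
    return logp + np.log(np.pi / 180.0)


def vm_resultant(kappa):
    """Mean resultant length A(kappa) = I1(kappa)/I0(kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    with np.errstate(invalid="ignore"):
        out = i1e(kappa) / i0e(kappa)
    return np.where(kappa <= 0.0, 0.0, out)


def vm_kappa_from_resultant(rbar):
    """Invert A(kappa) = rbar (Best & Fisher seed + Newton refinement)."""
    r = np.clip(np.asarray(rbar, dtype=float), 0.0, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(
            r < 0.53,
            2.0 * r + r**3 + 5.0 * r**5 / 6.0,
            np.where(
                r < 0.85,
                -0.4 + 1.39 * r + 0.43 / (1.0 - r),
                1.0 / np.maximum(r**3 - 4.0 * r**2 + 3.0 * r, 1e-300),
            ),
        )
    k = np.clip(k, 1e-8, KAPPA_CAP)
    for _ in range(4):
        a = vm_resultant(k)
        # dA/dkappa = 1 - A/kappa - A^2
        da = 1.0 - a / k - a * a
        step = np.where(da > 0, (a - r) / np.maximum(da, 1e-12), 0.0)
        k = np.clip(k - step, 1e-10, KAPPA_CAP)
    return np.where(r <= 0.0, 0.0, k)


def vm_convolve_kappa(kappa1, kappa2):
    """Concentration of the von Mises approximation to a convolution.

    The sum of two independent von Mises variables is approximated by a von
    Mises whose mean resultant length is the product of the two resultants.
    """
    return vm_kappa_from_resultant(vm_resultant(kappa1) * vm_resultant(kappa2))


def circ_mean_deg(theta_deg, weights=None):
    """Weighted circular mean, in [0, 360)."""
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    if weights is None:
        weights = np.ones_like(t)
    c = np.sum(weights * np.cos(t))
    s = np.sum(weights * np.sin(t))
    return wrap_deg(np.rad2deg(np.arctan2(s, c)))


def circ_sd_deg(theta_deg):
    """Circular standard deviation sqrt(-2 ln Rbar), reported in degrees."""
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    rbar = np.hypot(np.mean(np.cos(t)), np.mean(np.sin(t)))
    rbar = min(rbar, 1.0)
    if rbar <= 0.0:
        return np.inf
    return np.rad2deg(np.sqrt(-2.0 * np.log(rbar)))


def logsumexp(a, axis=None):
    from scipy.special import logsumexp as _lse

    return _lse(a, axis=axis)
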