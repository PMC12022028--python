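"""Map velocity-space percept mixtures to circular direction mixtures.

Each isotropic Gaussian component N(mu, sigma^2 I) over 2-D velocity
induces a distribution over direction that is well approximated by a von
Mises with mean atan2(mu_y, mu_x) and a concentration that depends only on
the ratio r = sigma^2 / ||mu||^2.  The mapping r -> kappa has no closed
form; it is calibrated once by Monte Carlo (T2 table) and interpolated.
A lapse component is prepended with weight lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from ._circ import (
    KAPPA_CAP,
    logsumexp,
    vm_kappa_from_resultant,
    vm_logpdf_deg,
    wrap_deg,
)
from .inference import PerceptMixture
from .model import ModelParams

#: variance-to-squared-speed ratios below this are clipped (numerical floor)
RATIO_FLOOR = 1.0e-8

_DEFAULT_GRID = np.logspace(-4.0, 4.0, 65)


@dataclass
class T2Table:
    """Monte-Carlo calibration of concentration vs variance ratio.

    ``kappas`` is strictly decreasing in ``ratios``; evaluation clips the
    ratio to [RATIO_FLOOR, inf), continues with the exact small-ratio
    asymptote kappa ~ 1/r below the grid, with a 1/sqrt(r) tail above it,
    and caps kappa at KAPPA_CAP.
    """

    ratios: np.ndarray
    kappas: np.ndarray
    n_mc: int
    seed: int
    _interp: PchipInterpolator = field(init=False, repr=False)

    def __post_init__(self):
        if np.any(np.diff(self.ratios) <= 0):
            raise ValueError("ratio grid must be strictly increasing")
        if np.any(np.diff(self.kappas) >= 0):
            raise ValueError("kappa must be strictly decreasing in the ratio")
        self._interp = PchipInterpolator(
            np.log(self.ratios), np.log(self.kappas), extrapolate=False
        )

    def __call__(self, ratio) -> np.ndarray:
        r = np.clip(np.asarray(ratio, dtype=float), RATIO_FLOOR, None)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.empty_like(r)
        lo, hi = self.ratios[0], self.ratios[-1]
        below, above = r < lo, r > hi
        mid = ~(below | above)
        out[mid] = np.exp(self._interp(np.log(r[mid])))
        # small-ratio asymptote: angular variance = r, kappa = 1/r
        out[below] = self.kappas[0] * (lo / r[below])
        # large-ratio tail: Rbar ~ sqrt(pi/(4r)) so kappa ~ 1/sqrt(r)
        out[above] = self.kappas[-1] * np.sqrt(hi / r[above])
        out = np.clip(out, 0.0, KAPPA_CAP)
        return float(out[0]) if scalar else out


def calibrate_t2(
    ratio_grid: np.ndarray | None = None,
    n_mc: int = 200_000,
    seed: int = 0,
) -> T2Table:
    """Calibrate the direction-concentration table by simulation.

    For each ratio r, draws 2-D Gaussian samples with mean (1, 0) and
    isotropic variance r, computes their angles, and fits a von Mises by
    matching the mean resultant length.  Common random numbers across the
    grid make the calibrated curve smooth and monotone.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be at least 10^4 for a stable calibration")
    grid = _DEFAULT_GRID if ratio_grid is None else np.asarray(ratio_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("ratios must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, 2))
    kappas = np.empty_like(grid)
    for i, r in enumerate(grid):
        pts = z * np.sqrt(r)
        pts[:, 0] += 1.0
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        rbar = np.hypot(np.mean(np.cos(ang)), np.mean(np.sin(ang)))
        kappas[i] = vm_kappa_from_resultant(rbar)
    # enforce strict monotonicity against residual MC noise
    kappas = np.minimum.accumulate(kappas)
    eps = np.cumsum(np.full_like(kappas, 1e-12))
    kappas = np.clip(kappas - eps, 1e-10, KAPPA_CAP)
    return T2Table(ratios=grid, kappas=kappas, n_mc=n_mc, seed=seed)


_default_table: T2Table | None = None


def default_t2() -> T2Table:
    """The package-wide calibration table (lazy, deterministic seed 0)."""
    global _default_table
    if _default_table is None:
        _default_table = calibrate_t2()
    return _default_table


@dataclass
class DirectionMixture:
    """Von Mises mixture over perceived direction; lapse at index 0."""

    weights: np.ndarray
    thetas_deg: np.ndarray
    kappas: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.thetas_deg = wrap_deg(np.asarray(self.thetas_deg, dtype=float))
        self.kappas = np.asarray(self.kappas, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-10):
            raise ValueError("mixture weights must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.weights)


def direction_mixture(
    pm: PerceptMixture,
    t2: T2Table | None = None,
    params: ModelParams | None = None,
) -> DirectionMixture:
    """Project a percept mixture onto the circle (with the lapse component).

    Components with zero mean speed (STATIONARY percepts) have no defined
    direction and are assigned kappa = 0 (uniform), which preserves their
    posterior mass; see the package methods note.
    """
    t2 = default_t2() if t2 is None else t2
    params = ModelParams() if params is None else params
    speed2 = np.sum(pm.means**2, axis=1)
    thetas = np.rad2deg(np.arctan2(pm.means[:, 1], pm.means[:, 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(speed2 > 0, pm.variances / np.maximum(speed2, 1e-300), np.inf)
    kappas = np.where(np.isinf(ratio), 0.0, t2(np.clip(ratio, RATIO_FLOOR, 1e30)))
    # exact-zero posterior variance with nonzero mean: direction is certain
    kappas = np.where((pm.variances == 0.0) & (speed2 > 0), KAPPA_CAP, kappas)
    lam = params.lambda_lapse
    weights = np.concatenate(([lam], (1.0 - lam) * pm.weights))
    thetas = np.concatenate(([params.theta_lapse_deg], thetas))
    kappas = np.concatenate(([params.kappa_lapse], kappas))
    return DirectionMixture(weights=weights, thetas_deg=thetas, kappas=kappas)


def mixture_log_density(dm: DirectionMixture, theta_deg) -> np.ndarray:
    """Log density (per degree) of the von Mises mixture at given angles."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    with np.errstate(divide="ignore"):
        logw = np.log(dm.weights)
    comp = vm_logpdf_deg(theta[:, None], dm.thetas_deg[None, :], dm.kappas[None, :])
    out = logsumexp(logw[None, :] + comp, axis=1)
    return out if np.ndim(theta_deg) else float(out[0])


def sample_directions(
    dm: DirectionMixture, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Draw directions (deg) from the mixture."""
    rng = np.random.default_rng(rng)
    idx = rng.choice(dm.n_components, size=n, p=dm.weights / dm.weights.sum())
    mu = np.deg2rad(dm.thetas_deg[idx])
    kappa = dm.kappas[idx]
    draws = np.where(
        kappa > 0, rng.vonmises(mu, np.maximum(kappa, 1e-12)), rng.uniform(-np.pi, np.pi, size=n)
    )
    return wrap_deg(np.rad2deg(draws))
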