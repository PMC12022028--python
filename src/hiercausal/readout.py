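"""From direction mixtures to single-trial estimates and response
distributions.

Four readout strategies map the posterior to a perceptual estimate:
*model averaging* (circular mean of the mixture), *model selection* (mean
direction of the max-weight component), *structure sampling* (mean
direction of a component drawn by weight), and *posterior sampling* (a
draw from the full mixture).  Response distributions marginalize
observation noise with Gauss-Hermite quadrature; at each quadrature node
the estimate distribution is convolved analytically with motor noise, so
the predicted density is deterministic for every strategy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._circ import (
    logsumexp,
    vm_convolve_kappa,
    vm_logpdf_deg,
    vm_resultant,
    wrap_deg,
)
from .direction import DirectionMixture, T2Table, default_t2, RATIO_FLOOR
from ._circ import KAPPA_CAP
from .inference import InferenceEngine
from .experiments import StimulusCondition
from .model import ModelParams

AVERAGING = "averaging"
SELECTION = "selection"
STRUCTURE_SAMPLING = "structure_sampling"
POSTERIOR_SAMPLING = "posterior_sampling"
STRATEGIES = (AVERAGING, SELECTION, STRUCTURE_SAMPLING, POSTERIOR_SAMPLING)

MAX_QUAD_DIMS = 6


def _check_strategy(strategy: str):
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


# ---------------------------------------------------------------------------
# single-mixture point estimates


def point_estimate(
    dm: DirectionMixture,
    strategy: str,
    rng: np.random.Generator | int | None = None,
) -> float:
    """One perceptual estimate (deg) from a direction mixture."""
    _check_strategy(strategy)
    if strategy == AVERAGING:
        t = np.deg2rad(dm.thetas_deg)
        a = dm.weights * vm_resultant(dm.kappas)
        return float(wrap_deg(np.rad2deg(np.arctan2(a @ np.sin(t), a @ np.cos(t)))))
    if strategy == SELECTION:
        return float(dm.thetas_deg[int(np.argmax(dm.weights))])
    rng = np.random.default_rng(rng)
    idx = int(rng.choice(dm.n_components, p=dm.weights / dm.weights.sum()))
    if strategy == STRUCTURE_SAMPLING:
        return float(dm.thetas_deg[idx])
    kappa = dm.kappas[idx]
    if kappa <= 0:
        return float(rng.uniform(0.0, 360.0))
    return float(
        wrap_deg(np.rad2deg(rng.vonmises(np.deg2rad(dm.thetas_deg[idx]), kappa)))
    )


# ---------------------------------------------------------------------------
# batched direction mixtures for a stimulus condition


@dataclass
class _BatchMixtures:
    """Direction-mixture components for a batch of observation sets.

    weights (B, C), thetas (B, C), kappas (B, C); component 0 is the lapse.
    """

    weights: np.ndarray
    thetas_deg: np.ndarray
    kappas: np.ndarray


def _batch_direction_mixtures(
    engine: InferenceEngine,
    obs: np.ndarray,
    params: ModelParams,
    t2: T2Table,
) -> _BatchMixtures:
    logw, means, variances = engine.batch_mixture(obs)
    w = np.exp(logw)
    speed2 = np.sum(means**2, axis=2)
    thetas = np.rad2deg(np.arctan2(means[:, :, 1], means[:, :, 0]))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            speed2 > 0, variances[None, :] / np.maximum(speed2, 1e-300), np.inf
        )
    kappas = np.where(
        np.isinf(ratio), 0.0, t2(np.clip(ratio, RATIO_FLOOR, 1e30).ravel()).reshape(ratio.shape)
    )
    kappas = np.where((variances[None, :] == 0.0) & (speed2 > 0), KAPPA_CAP, kappas)
    B = obs.shape[0] if obs.ndim == 3 else 1
    lam = params.lambda_lapse
    weights = np.concatenate([np.full((B, 1), lam), (1.0 - lam) * w], axis=1)
    thetas = np.concatenate(
        [np.full((B, 1), params.theta_lapse_deg), thetas], axis=1
    )
    kappas = np.concatenate([np.full((B, 1), params.kappa_lapse), kappas], axis=1)
    return _BatchMixtures(weights=weights, thetas_deg=wrap_deg(thetas), kappas=kappas)


def _batch_point_estimates(
    bm: _BatchMixtures, strategy: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    if strategy == AVERAGING:
        t = np.deg2rad(bm.thetas_deg)
        a = bm.weights * vm_resultant(bm.kappas)
        return wrap_deg(
            np.rad2deg(
                np.arctan2(np.sum(a * np.sin(t), axis=1), np.sum(a * np.cos(t), axis=1))
            )
        )
    if strategy == SELECTION:
        idx = np.argmax(bm.weights, axis=1)
        return bm.thetas_deg[np.arange(len(idx)), idx]
    assert rng is not None, "sampling strategies need an rng"
    B, C = bm.weights.shape
    cdf = np.cumsum(bm.weights, axis=1)
    cdf /= cdf[:, -1][:, None]
    u = rng.random((B, 1))
    idx = np.sum(u > cdf, axis=1)
    rows = np.arange(B)
    theta = bm.thetas_deg[rows, idx]
    if strategy == STRUCTURE_SAMPLING:
        return theta
    kappa = bm.kappas[rows, idx]
    draws = np.where(
        kappa > 0,
        np.rad2deg(rng.vonmises(np.deg2rad(theta), np.maximum(kappa, 1e-12))),
        rng.uniform(0.0, 360.0, size=B),
    )
    return wrap_deg(draws)


# ---------------------------------------------------------------------------
# response distribution via quadrature


def gauss_hermite_nodes(
    nu: np.ndarray, sigma: np.ndarray, order: int
) -> tuple[np.ndarray, np.ndarray]:
    """Product Gauss-Hermite nodes for isotropic Gaussian observation noise.

    Returns (obs (B, n, 2), weights (B,)) with B = order^(2n).
    """
    if order < 3:
        raise ValueError("quadrature order must be at least 3 per dimension")
    n = nu.shape[0]
    dims = 2 * n
    if dims > MAX_QUAD_DIMS:
        raise ValueError(
            f"quadrature over {dims} dimensions unsupported (max {MAX_QUAD_DIMS}); "
            "use Monte Carlo via simulate_responses instead"
        )
    x, w = np.polynomial.hermite.hermgauss(order)
    grids = np.meshgrid(*([x] * dims), indexing="ij")
    weights = np.ones_like(grids[0])
    for g in np.meshgrid(*([w] * dims), indexing="ij"):
        weights = weights * g
    weights = (weights / np.pi ** (dims / 2.0)).ravel()
    obs = np.empty((weights.size, n, 2))
    for e in range(n):
        for ax in (0, 1):
            obs[:, e, ax] = nu[e, ax] + np.sqrt(2.0) * sigma[e] * grids[2 * e + ax].ravel()
    return obs, weights


@dataclass
class ResponseDistribution:
    """Predicted distribution over reported directions for one condition.

    A finite von Mises mixture: observation noise enters through the
    quadrature weights, motor bias shifts every component, and motor noise
    is folded into the component concentrations.
    """

    weights: np.ndarray
    thetas_deg: np.ndarray
    kappas: np.ndarray
    condition: StimulusCondition | None = None
    strategy: str = ""
    quad_order: int = 0
    _cdf_grid: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        keep = self.weights > 0.0
        self.weights = np.asarray(self.weights, dtype=float)[keep]
        self.thetas_deg = wrap_deg(np.asarray(self.thetas_deg, dtype=float)[keep])
        self.kappas = np.asarray(self.kappas, dtype=float)[keep]
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise ValueError(f"response weights must sum to 1, got {total}")
        self.weights = self.weights / total

    def logpdf(self, theta_deg) -> np.ndarray:
        theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        out = np.empty_like(theta)
        logw = np.log(self.weights)
        # chunk over evaluation points to bound the (points x components) buffer
        step = max(1, int(4e6 / max(len(self.weights), 1)))
        for i in range(0, len(theta), step):
            block = theta[i : i + step, None]
            comp = vm_logpdf_deg(block, self.thetas_deg[None, :], self.kappas[None, :])
            out[i : i + step] = logsumexp(logw[None, :] + comp, axis=1)
        return out if np.ndim(theta_deg) else float(out[0])

    def pdf(self, theta_deg) -> np.ndarray:
        return np.exp(self.logpdf(theta_deg))

    def cdf(self, theta_deg) -> np.ndarray:
        """CDF on [0, 360) measured from 0 deg (grid-integrated, cached)."""
        if self._cdf_grid is None:
            grid = np.arange(0.0, 360.0 + 0.1, 0.1)
            pdf = self.pdf(grid)
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))]
            )
            cum /= cum[-1]
            self._cdf_grid = (grid, cum)
        grid, cum = self._cdf_grid
        return np.interp(wrap_deg(np.asarray(theta_deg, dtype=float)), grid, cum)

    def circular_mean(self) -> float:
        t = np.deg2rad(self.thetas_deg)
        a = self.weights * vm_resultant(self.kappas)
        return float(wrap_deg(np.rad2deg(np.arctan2(a @ np.sin(t), a @ np.cos(t)))))


def _prune(weights, thetas, kappas, tol=1e-12):
    order = np.argsort(weights)[::-1]
    w = weights[order]
    cum = np.cumsum(w)
    keep_n = int(np.searchsorted(cum, 1.0 - tol) + 1)
    keep = order[:keep_n]
    return weights[keep] / weights[keep].sum(), thetas[keep], kappas[keep]


def response_distribution(
    nu: StimulusCondition,
    params: ModelParams,
    strategy: str,
    quad_order: int = 7,
    t2: T2Table | None = None,
) -> ResponseDistribution:
    """Predicted report distribution for a stimulus condition.

    For averaging and selection the estimate at each quadrature node is a
    point, contributing one motor-noise von Mises.  For the sampling
    strategies the estimate at a node is itself a distribution over
    components; each component is convolved with the motor von Mises
    analytically (resultant-length multiplication), keeping the density
    deterministic and hence usable inside likelihood optimization.
    """
    _check_strategy(strategy)
    t2 = default_t2() if t2 is None else t2
    v = nu.velocity_array()
    sigma = np.array(
        [params.sigma_for(r) * s for r, s in zip(nu.roles, nu.obs_scale)]
    )
    obs, wq = gauss_hermite_nodes(v, sigma, quad_order)
    engine = InferenceEngine(
        params, n_elements=nu.n_elements, roles=nu.roles, obs_scale=nu.obs_scale
    )
    bm = _batch_direction_mixtures(engine, obs, params, t2)
    b = params.motor_bias_deg
    if strategy in (AVERAGING, SELECTION):
        est = _batch_point_estimates(bm, strategy)
        weights, thetas = wq, est + b
        kappas = np.full_like(weights, params.kappa_motor)
    else:
        weights = (wq[:, None] * bm.weights).ravel()
        thetas = (bm.thetas_deg + b).ravel()
        if strategy == STRUCTURE_SAMPLING:
            kappas = np.full_like(weights, params.kappa_motor)
        else:
            kappas = vm_convolve_kappa(bm.kappas, params.kappa_motor).ravel()
    weights, thetas, kappas = _prune(weights, thetas, kappas)
    return ResponseDistribution(
        weights=weights,
        thetas_deg=thetas,
        kappas=kappas,
        condition=nu,
        strategy=strategy,
        quad_order=quad_order,
    )


def simulate_responses(
    nu: StimulusCondition,
    params: ModelParams,
    strategy: str,
    n_trials: int,
    rng: np.random.Generator | int | None = None,
    t2: T2Table | None = None,
) -> np.ndarray:
    """Simulate reported directions with the full forward pass.

    Per trial: sample noisy observations around the condition velocities,
    run exact structure inference, apply the readout strategy, then add
    motor bias and von Mises motor noise.  Seeded and reproducible.
    """
    _check_strategy(strategy)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(rng)
    t2 = default_t2() if t2 is None else t2
    v = nu.velocity_array()
    sigma = np.array(
        [params.sigma_for(r) * s for r, s in zip(nu.roles, nu.obs_scale)]
    )
    obs = v[None, :, :] + rng.normal(size=(n_trials, v.shape[0], 2)) * sigma[None, :, None]
    engine = InferenceEngine(
        params, n_elements=nu.n_elements, roles=nu.roles, obs_scale=nu.obs_scale
    )
    bm = _batch_direction_mixtures(engine, obs, params, t2)
    est = _batch_point_estimates(bm, strategy, rng=rng)
    motor = np.rad2deg(rng.vonmises(0.0, max(params.kappa_motor, 1e-12), size=n_trials))
    return wrap_deg(est + params.motor_bias_deg + motor)
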