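"""Exact posterior over causal structures and perceived velocities.

For a fixed causal structure all conditionals are linear-Gaussian, so the
stacked observations are jointly Gaussian per axis with

    Sigma[e, f] = sum over nodes k shared by the paths of elements e and f
                  of (flag_k * sigma_prior^2 + sigma_delta^2)
                  + delta_ef * sigma_obs_e^2

and zero mean (flagged-zero relative velocities are marginalized to a hard
zero).  The posterior over the relative velocity at an element's percept
node is scalar-Gaussian per axis by conjugate conditioning, and the
posterior over structures is a softmax of (structure prior + marginal
likelihood).  x and y are independent chains sharing weights (all
covariances are isotropic), so each structure contributes one isotropic
Gaussian component to the percept mixture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from ._circ import logsumexp
from .model import ModelParams, ObservationSet, node_role, tree_log_prior
from .structures import (
    STATIONARY,
    CausalStructure,
    enumerate_causal_structures,
    percept_node,
)

LOG_2PI = np.log(2.0 * np.pi)


class DegenerateModelError(ValueError):
    """Raised when every causal structure has zero posterior mass."""


@dataclass
class PerceptMixture:
    """Mixture-of-Gaussians posterior over an element's perceived velocity.

    One isotropic component per causal structure: ``weights`` sum to 1,
    ``means`` has shape (S, 2) and ``variances`` (S,).  Components whose
    percept is STATIONARY carry mean (0, 0) and variance 0.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    structure_ids: np.ndarray
    element: int

    def __post_init__(self):
        total = float(np.sum(self.weights))
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"mixture weights must sum to 1, got {total}")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def mean(self) -> np.ndarray:
        return self.weights @ self.means


def _structure_flag_log_prior(structure: CausalStructure, params: ModelParams, roles) -> float:
    lp = 0.0
    with np.errstate(divide="ignore"):
        for node, flag in enumerate(structure.moving_flags):
            alpha = params.alpha_for(node_role(structure, node, roles))
            lp += np.log(alpha) if flag == 0 else np.log1p(-alpha)
    return float(lp)


def _structure_gaussian(structure, params, sigma_obs, element):
    """Per-axis observation covariance and percept-conditional gain.

    Returns (Sigma (n,n), c (n,), prior_var) where the percept posterior per
    axis is N(c' Sigma^-1 o, prior_var - c' Sigma^-1 c); c is None for
    STATIONARY percepts.
    """
    tree = structure.tree
    n = tree.n_elements
    paths = [set(tree.path_to_world(e)) for e in range(n)]
    sp2 = params.sigma_prior**2
    sd2 = params.sigma_delta**2
    sigma = np.zeros((n, n))
    for e in range(n):
        for f in range(e, n):
            shared = paths[e] & paths[f]
            v = sum(structure.moving_flags[k] * sp2 + sd2 for k in shared)
            sigma[e, f] = sigma[f, e] = v
        sigma[e, e] += sigma_obs[e] ** 2
    k_star = percept_node(structure, element)
    if k_star == STATIONARY:
        return sigma, None, 0.0
    c = np.array([sp2 if k_star in paths[e] else 0.0 for e in range(n)])
    return sigma, c, sp2


class InferenceEngine:
    """Precomputed per-structure quantities for one parameter set.

    Reusable across observation batches with the same element roles and
    observation-noise scales (i.e. one stimulus condition).
    """

    def __init__(
        self,
        params: ModelParams,
        n_elements: int | None = None,
        structures: Sequence[CausalStructure] | None = None,
        roles: Sequence[str] | None = None,
        obs_scale: Sequence[float] | None = None,
        element: int = 0,
    ):
        if structures is None:
            if n_elements is None:
                raise ValueError("need n_elements or an explicit structure set")
            structures = enumerate_causal_structures(n_elements)
        if len(structures) == 0:
            raise ValueError("structure set must be nonempty")
        n = structures[0].n_elements
        if any(s.n_elements != n for s in structures):
            raise ValueError("structures must share an element count")
        if roles is None:
            roles = ("center",) + ("surround",) * (n - 1)
        if obs_scale is None:
            obs_scale = (1.0,) * n
        sigma_obs = np.array(
            [params.sigma_for(r) * s for r, s in zip(roles, obs_scale)]
        )
        self.params = params
        self.structures = tuple(structures)
        self.roles = tuple(roles)
        self.element = element
        self.n_elements = n

        S = len(structures)
        self.log_prior = np.empty(S)
        self.percept_nodes = np.empty(S, dtype=int)
        self.variances = np.zeros(S)
        self._chol = []
        self._logdet = np.empty(S)
        self._gain = np.zeros((S, n))
        for i, s in enumerate(structures):
            self.log_prior[i] = tree_log_prior(
                s.tree, params.beta, normalized=True
            ) + _structure_flag_log_prior(s, params, roles)
            sigma, c, prior_var = _structure_gaussian(s, params, sigma_obs, element)
            cf = cho_factor(sigma, lower=True)
            self._chol.append(cf)
            self._logdet[i] = 2.0 * np.sum(np.log(np.diag(cf[0])))
            self.percept_nodes[i] = percept_node(s, element)
            if c is not None:
                g = cho_solve(cf, c)
                self._gain[i] = g
                self.variances[i] = max(prior_var - float(c @ g), 0.0)

    # -- batched core ------------------------------------------------------

    def log_joint(self, obs: np.ndarray) -> np.ndarray:
        """Unnormalized log posterior of each structure, batched.

        ``obs`` has shape (B, n, 2); returns (B, S).
        """
        obs = np.asarray(obs, dtype=float)
        if obs.ndim == 2:
            obs = obs[None]
        B = obs.shape[0]
        S = len(self.structures)
        out = np.full((B, S), -np.inf)
        n = self.n_elements
        for i in range(S):
            if not np.isfinite(self.log_prior[i]):
                continue
            quad = 0.0
            for ax in (0, 1):
                o = obs[:, :, ax]
                z = cho_solve(self._chol[i], o.T)
                quad = quad + np.sum(o.T * z, axis=0)
            out[:, i] = (
                self.log_prior[i]
                - 0.5 * quad
                - self._logdet[i]
                - n * LOG_2PI
            )
        return out

    def batch_mixture(self, obs: np.ndarray):
        """Normalized log weights and component means for a batch.

        Returns ``(logw (B, S), means (B, S, 2), variances (S,))``.
        """
        obs = np.asarray(obs, dtype=float)
        if obs.ndim == 2:
            obs = obs[None]
        lj = self.log_joint(obs)
        norm = logsumexp(lj, axis=1)
        if not np.all(np.isfinite(norm)):
            raise DegenerateModelError(
                "all causal structures have zero posterior mass"
            )
        logw = lj - norm[:, None]
        means = np.einsum("bna,sn->bsa", obs, self._gain)
        return logw, means, self.variances


# ---------------------------------------------------------------------------
# operation-level wrappers


def _as_obs(obs) -> ObservationSet:
    if isinstance(obs, ObservationSet):
        return obs
    return ObservationSet(velocities=np.asarray(obs, dtype=float))


def structure_log_weight(
    structure: CausalStructure, obs, params: ModelParams
) -> float:
    """Unnormalized log posterior of one causal structure given observations:
    log tree prior + log flag prior + log Gaussian marginal likelihood."""
    o = _as_obs(obs)
    if structure.n_elements != o.n_elements:
        raise ValueError("structure and observations disagree on element count")
    eng = InferenceEngine(
        params, structures=(structure,), roles=o.roles, obs_scale=o.obs_scale
    )
    return float(eng.log_joint(o.velocities[None])[0, 0])


def percept_conditional(
    structure: CausalStructure, obs, params: ModelParams, element: int = 0
) -> tuple[np.ndarray, float]:
    """Gaussian posterior (mean, isotropic variance) over the relative
    velocity at the element's percept node; ((0,0), 0) when STATIONARY."""
    o = _as_obs(obs)
    if structure.n_elements != o.n_elements:
        raise ValueError("structure and observations disagree on element count")
    eng = InferenceEngine(
        params,
        structures=(structure,),
        roles=o.roles,
        obs_scale=o.obs_scale,
        element=element,
    )
    mean = o.velocities.T @ eng._gain[0]
    return mean, float(eng.variances[0])


def percept_mixture(
    obs,
    params: ModelParams,
    element: int = 0,
    structures: Sequence[CausalStructure] | None = None,
) -> PerceptMixture:
    """The full mixture-of-Gaussians posterior over an element's percept."""
    o = _as_obs(obs)
    eng = InferenceEngine(
        params,
        n_elements=o.n_elements,
        structures=structures,
        roles=o.roles,
        obs_scale=o.obs_scale,
        element=element,
    )
    logw, means, variances = eng.batch_mixture(o.velocities[None])
    w = np.exp(logw[0])
    w = w / w.sum()
    return PerceptMixture(
        weights=w,
        means=means[0],
        variances=variances.copy(),
        structure_ids=np.arange(len(eng.structures)),
        element=element,
    )
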