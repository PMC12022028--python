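"""Generative model: parameters, the delta+Gaussian velocity prior, and
forward simulation of latent velocities and noisy observations.

Velocities are 2-D retinal vectors in deg/s (x rightward, y upward).  Each
node of a causal structure carries a *relative* velocity drawn from the
spike-and-slab prior ``alpha * delta(0) + (1 - alpha) * N(0, sigma_prior^2 I)``;
absolute velocities compose down the tree with isotropic Gaussian
composition noise ``sigma_delta``, starting from the stationary WORLD frame
(v_world = 0).  Element observations add per-element isotropic observation
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .structures import (
    ELEMENT,
    WORLD,
    CausalStructure,
    enumerate_grouping_trees,
)

ROLE_CENTER = "center"
ROLE_GROUP = "group"


@dataclass
class ModelParams:
    """All generative and readout parameters.

    Prior-mass parameters ``alpha_*`` give the probability that a relative
    velocity is exactly zero; ``alpha_group`` defaults to ``alpha_surround``
    (group nodes share the surround's stationarity expectation).  All sigmas
    are in deg/s, angles in degrees, concentrations unitless.
    """

    alpha_center: float = 0.9
    alpha_surround: float = 0.9
    alpha_group: float | None = None
    sigma_prior: float = 1.0
    sigma_delta: float = 0.1
    sigma_center: float = 0.2
    sigma_surround: float = 0.2
    beta: float = 0.5
    lambda_lapse: float = 0.02
    theta_lapse_deg: float = 0.0
    kappa_lapse: float = 0.0
    motor_bias_deg: float = 0.0
    kappa_motor: float = 50.0

    def __post_init__(self):
        for name in ("alpha_center", "alpha_surround", "beta", "lambda_lapse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.alpha_group is not None and not 0.0 <= self.alpha_group <= 1.0:
            raise ValueError("alpha_group must be in [0, 1]")
        for name in ("sigma_prior", "sigma_delta", "sigma_center", "sigma_surround"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be > 0")
        for name in ("kappa_lapse", "kappa_motor"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")

    def alpha_for(self, role: str) -> float:
        if role == ROLE_CENTER:
            return self.alpha_center
        if role == ROLE_GROUP:
            return self.alpha_surround if self.alpha_group is None else self.alpha_group
        return self.alpha_surround

    def sigma_for(self, role: str) -> float:
        return self.sigma_center if role == ROLE_CENTER else self.sigma_surround

    def with_updates(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class ObservationSet:
    """One noisy retinal velocity per element, with element roles."""

    velocities: np.ndarray  # (n, 2) deg/s
    roles: tuple[str, ...] = ()
    #: multiplicative scale on each element's observation noise sd
    #: (e.g. 1/sqrt(k) for a surround made of k patches)
    obs_scale: tuple[float, ...] | None = None

    def __post_init__(self):
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.velocities.ndim != 2 or self.velocities.shape[1] != 2:
            raise ValueError("velocities must have shape (n, 2)")
        n = self.velocities.shape[0]
        if not self.roles:
            self.roles = (ROLE_CENTER,) + ("surround",) * (n - 1)
        if len(self.roles) != n:
            raise ValueError("one role per element required")
        if self.obs_scale is None:
            self.obs_scale = (1.0,) * n
        if len(self.obs_scale) != n:
            raise ValueError("one obs_scale per element required")

    @property
    def n_elements(self) -> int:
        return self.velocities.shape[0]

    def sigma_obs(self, params: ModelParams) -> np.ndarray:
        return np.array(
            [params.sigma_for(r) * s for r, s in zip(self.roles, self.obs_scale)]
        )


def node_role(structure: CausalStructure, node: int, roles: Sequence[str]) -> str:
    """Role of a node: its element role for leaves, 'group' otherwise."""
    if structure.tree.kinds[node] == ELEMENT:
        return roles[node]
    return ROLE_GROUP


def relative_velocity_log_prior(
    v: Sequence[float], alpha: float, sigma_prior: float
) -> tuple[float, bool]:
    """Log prior of a relative velocity under the delta+Gaussian mixture.

    Returns ``(log_value, is_atom)``.  The atom applies only when the
    velocity is *exactly* zero (the delta component has mass, not density);
    the caller must keep the two cases separate.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if sigma_prior <= 0.0:
        raise ValueError("sigma_prior must be > 0")
    v = np.asarray(v, dtype=float)
    if v.shape != (2,) or not np.all(np.isfinite(v)):
        raise ValueError("v must be a finite 2-vector")
    if v[0] == 0.0 and v[1] == 0.0:
        with np.errstate(divide="ignore"):
            return float(np.log(alpha)), True
    log_gauss = -np.sum(v**2) / (2.0 * sigma_prior**2) - np.log(
        2.0 * np.pi * sigma_prior**2
    )
    with np.errstate(divide="ignore"):
        return float(np.log1p(-alpha) + log_gauss), False


def tree_log_prior(tree, beta: float, normalized: bool = True, n_elements: int | None = None) -> float:
    """Log prior over grouping trees induced by the sharing probability beta.

    Convention: weight proportional to beta^(#groups) * (1-beta)^(#roots - 1),
    i.e. every group node is a merge event favoured by beta and every extra
    independent root is a split favoured by 1-beta.  For two elements this
    reduces exactly to P(shared group) = beta.
    """
    def _raw(t):
        g = len(t.group_nodes())
        r = t.n_roots() - 1
        with np.errstate(divide="ignore"):
            lp = 0.0
            if g:
                lp += g * np.log(beta)
            if r:
                lp += r * np.log1p(-beta)
            return lp

    lp = _raw(tree)
    if not normalized:
        return float(lp)
    n = tree.n_elements if n_elements is None else n_elements
    raws = np.array([_raw(t) for t in enumerate_grouping_trees(n)])
    from ._circ import logsumexp

    return float(lp - logsumexp(raws))


def sample_structure_and_latents(
    params: ModelParams,
    n_elements: int,
    rng: np.random.Generator | int | None = None,
    roles: Sequence[str] | None = None,
):
    """Draw a causal structure and all node velocities from the prior.

    Returns ``(structure, v_relative, v_absolute)`` where the velocity
    arrays have shape (n_nodes, 2).  Structures are drawn using the tree
    prior (beta) and per-node stationarity flags (alpha by role); relative
    velocities are exactly zero where the flag is 0; absolute velocities
    compose parent -> child with N(0, sigma_delta^2 I) composition noise and
    v_world = 0.
    """
    rng = np.random.default_rng(rng)
    if roles is None:
        roles = (ROLE_CENTER,) + ("surround",) * (n_elements - 1)
    trees = enumerate_grouping_trees(n_elements)
    logw = np.array([tree_log_prior(t, params.beta, normalized=True) for t in trees])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    tree = trees[rng.choice(len(trees), p=w)]
    flags = []
    for node in range(tree.n_nodes):
        role = roles[node] if tree.kinds[node] == ELEMENT else ROLE_GROUP
        alpha = params.alpha_for(role)
        flags.append(0 if rng.random() < alpha else 1)
    structure = CausalStructure(tree=tree, moving_flags=tuple(flags))

    n_nodes = tree.n_nodes
    v_rel = np.zeros((n_nodes, 2))
    for node in range(n_nodes):
        if flags[node] == 1:
            v_rel[node] = rng.normal(0.0, params.sigma_prior, size=2)
    v_abs = np.zeros((n_nodes, 2))
    # compose top-down: parents before children
    order = sorted(range(n_nodes), key=lambda i: len(_ancestors(tree, i)))
    for node in order:
        parent = tree.parents[node]
        base = np.zeros(2) if parent == WORLD else v_abs[parent]
        v_abs[node] = base + v_rel[node] + rng.normal(0.0, params.sigma_delta, size=2)
    return structure, v_rel, v_abs


def _ancestors(tree, node):
    out = []
    p = tree.parents[node]
    while p != WORLD:
        out.append(p)
        p = tree.parents[p]
    return out


def sample_observations(
    v_abs_elements: np.ndarray,
    sigma_obs: Sequence[float],
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Corrupt element velocities with independent isotropic Gaussian noise."""
    rng = np.random.default_rng(rng)
    v = np.atleast_2d(np.asarray(v_abs_elements, dtype=float))
    sigma = np.asarray(sigma_obs, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma_obs must be >= 0")
    return v + rng.normal(size=v.shape) * sigma[:, None]
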