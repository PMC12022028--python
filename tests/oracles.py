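"""Independent oracles for the exact inference machinery.

The importance-sampling oracle simulates the generative model literally:
for each causal structure it draws relative velocities from the
spike-and-slab prior, composes absolute velocities with explicit
composition noise, and weights particles by the Gaussian observation
likelihood.  It shares no code with the analytic per-structure Gaussian
algebra it is used to check.
"""

from __future__ import annotations

import numpy as np

from hiercausal.model import ModelParams, node_role
from hiercausal.structures import (
    STATIONARY,
    CausalStructure,
    WORLD,
    percept_node,
)


def is_structure_estimates(
    structure: CausalStructure,
    obs: np.ndarray,
    params: ModelParams,
    roles,
    sigma_obs: np.ndarray,
    element: int,
    n_particles: int,
    rng: np.random.Generator,
):
    """Monte-Carlo marginal likelihood and percept posterior for one structure.

    Returns dict with mlik, mlik_se, mean (2,), mean_se (2,), var.
    """
    tree = structure.tree
    nn = tree.n_nodes
    n = tree.n_elements
    flags = np.array(structure.moving_flags)

    v_rel = np.zeros((n_particles, nn, 2))
    moving = np.where(flags == 1)[0]
    if moving.size:
        v_rel[:, moving, :] = rng.normal(
            0.0, params.sigma_prior, size=(n_particles, moving.size, 2)
        )
    eps = rng.normal(0.0, params.sigma_delta, size=(n_particles, nn, 2))
    v_abs = np.zeros((n_particles, nn, 2))
    order = sorted(range(nn), key=lambda i: len(tree.path_to_world(i)) if i < n else 0)
    # compose parents before children: sort by depth from WORLD
    depth = {}
    for node in range(nn):
        d, p = 0, tree.parents[node]
        while p != WORLD:
            d, p = d + 1, tree.parents[p]
        depth[node] = d
    for node in sorted(range(nn), key=depth.get):
        parent = tree.parents[node]
        base = 0.0 if parent == WORLD else v_abs[:, parent, :]
        v_abs[:, node, :] = base + v_rel[:, node, :] + eps[:, node, :]

    # log observation likelihood per particle
    loglik = np.zeros(n_particles)
    for e in range(n):
        d2 = np.sum((obs[e][None, :] - v_abs[:, e, :]) ** 2, axis=1)
        loglik += -d2 / (2.0 * sigma_obs[e] ** 2) - np.log(
            2.0 * np.pi * sigma_obs[e] ** 2
        )
    w = np.exp(loglik - loglik.max())
    scale = np.exp(loglik.max())
    mlik = float(np.mean(w)) * scale
    mlik_se = float(np.std(w) / np.sqrt(n_particles)) * scale

    k_star = percept_node(structure, element)
    if k_star == STATIONARY:
        return dict(
            mlik=mlik, mlik_se=mlik_se, mean=np.zeros(2), mean_se=np.zeros(2)
        )
    x = v_rel[:, k_star, :]
    wbar = np.mean(w)
    mean = (w @ x) / (w.sum())
    # ratio-estimator standard error (delta method)
    se = np.std(w[:, None] * (x - mean[None, :]), axis=0) / (
        np.sqrt(n_particles) * wbar
    )
    return dict(mlik=mlik, mlik_se=mlik_se, mean=mean, mean_se=se)


def structure_flag_tree_log_prior(structure, params, roles):
    """Prior over a structure, re-derived independently of the engine."""
    from hiercausal.model import tree_log_prior

    lp = tree_log_prior(structure.tree, params.beta, normalized=True)
    with np.errstate(divide="ignore"):
        for node, flag in enumerate(structure.moving_flags):
            a = params.alpha_for(node_role(structure, node, roles))
            lp += np.log(a) if flag == 0 else np.log1p(-a)
    return lp
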