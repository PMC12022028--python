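"""Likelihood, MLE/MAP optimization, MCMC posteriors, AIC, VE, bootstrap.

The per-trial likelihood is the deterministic response density of
:func:`hiercausal.readout.response_distribution` (sampling strategies use
the analytic motor-noise convolution), so optimization is well posed.
Optimization runs in an unconstrained space: log for scale and
concentration parameters, logit for probabilities, untransformed circular
means.  Default weakly informative priors: Beta(1,1) for probabilities,
half-normal(5 deg/s) for sigmas, log-normal for concentrations, uniform
for angles; all overridable.

For prior-mass parameters (alphas, beta, lapse) under the sampling
strategies, per-structure marginal likelihoods and von Mises response
kernels do not change with the parameter, so :class:`WeightLikelihood`
precomputes them once and re-evaluates the dataset likelihood in
milliseconds — this is what makes desk-scale MCMC recovery runs practical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import halfnorm, lognorm

from ._circ import logsumexp, vm_convolve_kappa, vm_logpdf_deg
from .direction import T2Table, default_t2, RATIO_FLOOR
from ._circ import KAPPA_CAP
from .inference import InferenceEngine
from .io import TrialTable
from .model import ModelParams
from .readout import (
    POSTERIOR_SAMPLING,
    STRUCTURE_SAMPLING,
    _batch_direction_mixtures,
    _check_strategy,
    gauss_hermite_nodes,
    response_distribution,
)

#: "alpha" is a role-tied pseudo-parameter: one delta mass shared by
#: center, surround and group nodes
PROB_PARAMS = (
    "alpha",
    "alpha_center",
    "alpha_surround",
    "alpha_group",
    "beta",
    "lambda_lapse",
)
SCALE_PARAMS = ("sigma_prior", "sigma_delta", "sigma_center", "sigma_surround")
CONC_PARAMS = ("kappa_lapse", "kappa_motor")
ANGLE_PARAMS = ("theta_lapse_deg", "motor_bias_deg")
#: parameters that only reweight mixture components (fast-path eligible)
WEIGHT_PARAMS = frozenset(PROB_PARAMS)


class LikelihoodError(RuntimeError):
    """Raised when a trial has non-finite likelihood (names the trial)."""


# ---------------------------------------------------------------------------
# parameter transforms and priors


def _get_param(params: ModelParams, name: str) -> float:
    if name == "alpha":
        return float(params.alpha_center)
    v = getattr(params, name)
    if name == "alpha_group" and v is None:
        v = params.alpha_surround
    return float(v)


def _expand_updates(name: str, value: float) -> dict:
    if name == "alpha":
        return {"alpha_center": value, "alpha_surround": value, "alpha_group": None}
    return {name: value}


def _to_unconstrained(name: str, value: float) -> float:
    if name in PROB_PARAMS:
        return float(logit(np.clip(value, 1e-9, 1.0 - 1e-9)))
    if name in SCALE_PARAMS or name in CONC_PARAMS:
        return float(np.log(max(value, 1e-12)))
    return float(value)


def _from_unconstrained(name: str, z: float) -> float:
    if name in PROB_PARAMS:
        return float(expit(z))
    if name in SCALE_PARAMS or name in CONC_PARAMS:
        return float(np.exp(np.clip(z, -30.0, 30.0)))
    return float(z)


def _default_log_prior(name: str, value: float) -> float:
    if name in PROB_PARAMS:
        return 0.0  # Beta(1, 1)
    if name in SCALE_PARAMS:
        return float(halfnorm.logpdf(value, scale=5.0))
    if name in CONC_PARAMS:
        return float(lognorm.logpdf(value, s=2.0, scale=20.0))
    return -np.log(360.0)  # uniform circular


def _log_jacobian(name: str, z: float) -> float:
    """log |d value / d z| for the change of variables into z-space."""
    if name in PROB_PARAMS:
        p = expit(z)
        return float(np.log(max(p * (1.0 - p), 1e-300)))
    if name in SCALE_PARAMS or name in CONC_PARAMS:
        return float(np.clip(z, -30.0, 30.0))
    return 0.0


def pack(params: ModelParams, free: Sequence[str]) -> np.ndarray:
    return np.array([_to_unconstrained(n, _get_param(params, n)) for n in free])


def unpack(z: np.ndarray, base: ModelParams, free: Sequence[str]) -> ModelParams:
    updates: dict = {}
    for n, zi in zip(free, z):
        updates.update(_expand_updates(n, _from_unconstrained(n, zi)))
    return replace(base, **updates)


# ---------------------------------------------------------------------------
# dataset likelihood


def dataset_log_likelihood(
    params: ModelParams,
    trials: TrialTable,
    strategy: str,
    quad_order: int = 7,
    t2: T2Table | None = None,
) -> float:
    """Sum of log response densities over all trials (per-condition cache)."""
    _check_strategy(strategy)
    t2 = default_t2() if t2 is None else t2
    total = 0.0
    for label, sub in trials.df.groupby("condition", sort=True):
        cond = trials.condition_of(str(label))
        rd = response_distribution(cond, params, strategy, quad_order, t2=t2)
        lp = rd.logpdf(sub["report_deg"].to_numpy())
        if not np.all(np.isfinite(lp)):
            bad = sub.index[~np.isfinite(np.atleast_1d(lp))].tolist()
            raise LikelihoodError(
                f"non-finite likelihood for trials {bad} in condition {label!r}"
            )
        total += float(np.sum(lp))
    return total


class WeightLikelihood:
    """Cached dataset likelihood over prior-mass parameters.

    Valid for the sampling strategies and free parameters among the
    probabilities (alphas, beta, lambda): component directions,
    concentrations and per-structure marginal likelihoods are precomputed
    once; each evaluation only recomputes structure weights.
    """

    def __init__(
        self,
        trials: TrialTable,
        base_params: ModelParams,
        strategy: str = POSTERIOR_SAMPLING,
        quad_order: int = 5,
        t2: T2Table | None = None,
    ):
        if strategy not in (POSTERIOR_SAMPLING, STRUCTURE_SAMPLING):
            raise ValueError(
                "WeightLikelihood supports the sampling strategies only"
            )
        t2 = default_t2() if t2 is None else t2
        self.strategy = strategy
        self.base_params = base_params
        self._conds = []
        from .model import node_role
        from .structures import GROUP as _G

        for label, sub in trials.df.groupby("condition", sort=True):
            cond = trials.condition_of(str(label))
            reports = sub["report_deg"].to_numpy()
            v = cond.velocity_array()
            sigma = np.array(
                [
                    base_params.sigma_for(r) * s
                    for r, s in zip(cond.roles, cond.obs_scale)
                ]
            )
            obs, wq = gauss_hermite_nodes(v, sigma, quad_order)
            engine = InferenceEngine(
                base_params,
                n_elements=cond.n_elements,
                roles=cond.roles,
                obs_scale=cond.obs_scale,
            )
            # likelihood-only part (structure priors removed)
            loglik = engine.log_joint(obs) - engine.log_prior[None, :]
            bm = _batch_direction_mixtures(engine, obs, base_params, t2)
            if strategy == POSTERIOR_SAMPLING:
                kap = vm_convolve_kappa(bm.kappas, base_params.kappa_motor)
            else:
                kap = np.full_like(bm.kappas, base_params.kappa_motor)
            # lapse component keeps its own concentration (motor-convolved)
            kap[:, 0] = vm_convolve_kappa(
                base_params.kappa_lapse, base_params.kappa_motor
            )
            theta = bm.thetas_deg + base_params.motor_bias_deg
            # kernel[(j, c), t]: component density at each report, flattened
            # so each evaluation is a single BLAS matvec
            kernel = (
                np.exp(
                    vm_logpdf_deg(
                        reports[None, None, :], theta[:, :, None], kap[:, :, None]
                    )
                )
                .astype(np.float32)
                .reshape(-1, len(reports))
            )
            # per-structure flag counts by role, and tree merge/root counts
            structures = engine.structures
            roles = engine.roles
            role_names = ("center", "surround", "group")
            n0 = np.zeros((len(structures), 3))
            n1 = np.zeros((len(structures), 3))
            g_cnt = np.zeros(len(structures))
            r_cnt = np.zeros(len(structures))
            for i, s in enumerate(structures):
                g_cnt[i] = len(s.tree.group_nodes())
                r_cnt[i] = s.tree.n_roots() - 1
                for node, flag in enumerate(s.moving_flags):
                    role = node_role(s, node, roles)
                    k = role_names.index(role if role in role_names else "surround")
                    (n1 if flag else n0)[i, k] += 1
            self._conds.append(
                dict(
                    label=str(label),
                    wq=wq,
                    loglik=loglik,
                    kernel=kernel,
                    n0=n0,
                    n1=n1,
                    g=g_cnt,
                    r=r_cnt,
                    n_trials=len(reports),
                )
            )

    def __call__(self, params: ModelParams) -> float:
        a = np.array(
            [
                params.alpha_center,
                params.alpha_surround,
                _get_param(params, "alpha_group"),
            ]
        )
        lam = params.lambda_lapse
        total = 0.0
        with np.errstate(divide="ignore"):
            la0 = np.log(a)
            la1 = np.log1p(-a)
            lb = np.log(params.beta)
            lb1 = np.log1p(-params.beta)
        def _nmul(n, l):  # n * l with the 0 * (-inf) = 0 convention
            return np.where(n == 0, 0.0, n * l)

        for c in self._conds:
            lp = (
                _nmul(c["n0"], la0[None, :]).sum(axis=1)
                + _nmul(c["n1"], la1[None, :]).sum(axis=1)
                + _nmul(c["g"], lb)
                + _nmul(c["r"], lb1)
            )
            lw = c["loglik"] + lp[None, :]
            norm = logsumexp(lw, axis=1)
            w = np.exp(lw - norm[:, None])
            wfull = np.concatenate(
                [np.full((w.shape[0], 1), lam), (1.0 - lam) * w], axis=1
            )
            wvec = (c["wq"][:, None] * wfull).ravel().astype(np.float32)
            dens = wvec @ c["kernel"]
            if np.any(dens <= 0) or not np.all(np.isfinite(dens)):
                return -np.inf
            total += float(np.sum(np.log(dens)))
        return total


def make_loglik(
    trials: TrialTable,
    strategy: str,
    base_params: ModelParams,
    free: Sequence[str],
    quad_order: int = 5,
    t2: T2Table | None = None,
) -> Callable[[np.ndarray], float]:
    """Dataset log-likelihood as a function of the transformed free vector.

    Automatically uses the cached fast path when every free parameter is a
    prior-mass parameter and the strategy is a sampling strategy.
    """
    fast = set(free) <= WEIGHT_PARAMS and strategy in (
        POSTERIOR_SAMPLING,
        STRUCTURE_SAMPLING,
    )
    if fast:
        cached = WeightLikelihood(trials, base_params, strategy, quad_order, t2)

        def fn(z: np.ndarray) -> float:
            return cached(unpack(np.atleast_1d(z), base_params, free))

        return fn

    def fn(z: np.ndarray) -> float:
        params = unpack(np.atleast_1d(z), base_params, free)
        try:
            return dataset_log_likelihood(params, trials, strategy, quad_order, t2)
        except (ValueError, LikelihoodError):
            return -np.inf

    return fn


# ---------------------------------------------------------------------------
# results


@dataclass
class FitResult:
    """Point estimates (and optionally posterior samples) for one model."""

    params: ModelParams
    free: tuple[str, ...]
    strategy: str
    log_likelihood: float
    aic: float
    n_params: int
    converged: bool
    data_hash: str
    message: str = ""
    samples: dict | None = None  # name -> (chain, draw) in natural space
    rhat: dict | None = None
    ess: dict | None = None
    label: str = ""

    def credible_interval(self, name: str, level: float = 0.95):
        if self.samples is None or name not in self.samples:
            raise ValueError(f"no posterior samples for {name!r}")
        flat = np.asarray(self.samples[name]).ravel()
        lo = (1.0 - level) / 2.0
        return tuple(np.quantile(flat, [lo, 1.0 - lo]))


def fit_mle(
    trials: TrialTable,
    strategy: str,
    free: Sequence[str] = ("alpha_center", "alpha_surround"),
    init: ModelParams | None = None,
    quad_order: int = 5,
    n_starts: int = 1,
    seed: int = 0,
    t2: T2Table | None = None,
    label: str = "",
) -> FitResult:
    """Maximum-likelihood fit via quasi-Newton (BFGS) on the transformed
    space, with optional jittered multi-start.  Non-convergence is flagged
    on the result rather than raised."""
    from scipy.optimize import minimize

    if len(trials) == 0:
        raise ValueError("trial table is empty")
    base = ModelParams() if init is None else init
    free = tuple(free)
    loglik = make_loglik(trials, strategy, base, free, quad_order, t2)
    rng = np.random.default_rng(seed)
    z0 = pack(base, free)
    best = None
    converged = False
    # gradient tolerance scales with the dataset log-likelihood magnitude:
    # cached kernels are single precision, so machine-tight gradients are
    # unattainable and would spuriously flag non-convergence
    gtol = max(1e-5, 0.02 * np.sqrt(len(trials)))
    for start in range(max(1, n_starts)):
        z_init = z0 if start == 0 else z0 + rng.normal(0.0, 0.5, size=z0.shape)
        if len(free) == 0:
            best = (loglik(z0), z0, True)
            converged = True
            break
        # finite-difference step large enough to beat the single-precision
        # kernel noise floor (~1e-7 relative) in cached likelihoods
        res = minimize(
            lambda z: -loglik(z),
            z_init,
            method="BFGS",
            options={"gtol": gtol, "eps": 1e-3},
        )
        ok = bool(res.success) or float(np.linalg.norm(res.jac)) < 10.0 * gtol
        cand = (-res.fun, res.x, ok)
        if best is None or cand[0] > best[0]:
            best = cand
        converged = converged or cand[2]
    ll, z, _ = best
    params = unpack(z, base, free)
    k = len(free)
    return FitResult(
        params=params,
        free=free,
        strategy=strategy,
        log_likelihood=float(ll),
        aic=float(2 * k - 2 * ll),
        n_params=k,
        converged=converged,
        data_hash=trials.data_hash(),
        message="" if converged else "optimizer did not report convergence",
        label=label or f"{strategy}:{'+'.join(free) or 'fixed'}",
    )


def sample_posterior(
    trials: TrialTable,
    strategy: str,
    free: Sequence[str] = ("alpha_center",),
    init: ModelParams | None = None,
    n_chains: int = 4,
    n_samples: int = 5000,
    burn_in: int | None = None,
    thin: int = 10,
    seed: int = 0,
    quad_order: int = 5,
    t2: T2Table | None = None,
    priors: dict | None = None,
    label: str = "",
) -> FitResult:
    """MCMC posterior over the free parameters (affine-invariant ensemble).

    ``n_chains`` is the number of walkers (raised to the sampler minimum if
    needed) and ``n_samples`` the steps per walker; burn-in defaults to 20%
    and every ``thin``-th draw is kept.  R-hat and effective sample size
    are computed per parameter; R-hat > 1.1 sets a warning message, not a
    failure.
    """
    import emcee

    base = ModelParams() if init is None else init
    free = tuple(free)
    if not free:
        raise ValueError("sample_posterior needs at least one free parameter")
    loglik = make_loglik(trials, strategy, base, free, quad_order, t2)
    prior_fns = priors or {}

    def log_prob(z):
        lp = 0.0
        for n, zi in zip(free, z):
            v = _from_unconstrained(n, zi)
            fn = prior_fns.get(n)
            lp += (fn(v) if fn is not None else _default_log_prior(n, v))
            lp += _log_jacobian(n, zi)
        if not np.isfinite(lp):
            return -np.inf
        ll = loglik(z) if len(trials) else 0.0
        return lp + ll

    ndim = len(free)
    nwalkers = max(n_chains, 2 * ndim + 2)
    if nwalkers % 2:
        nwalkers += 1
    rng = np.random.default_rng(seed)
    z0 = pack(base, free)
    p0 = z0[None, :] + 0.3 * rng.normal(size=(nwalkers, ndim))
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_prob)
    sampler.random_state = np.random.RandomState(seed).get_state()
    sampler.run_mcmc(p0, n_samples, progress=False)
    burn = int(0.2 * n_samples) if burn_in is None else int(burn_in)
    chain = sampler.get_chain(discard=burn, thin=max(1, thin))  # (draw, walker, dim)
    samples = {}
    rhat: dict = {}
    ess: dict = {}
    import arviz as az

    for j, name in enumerate(free):
        nat = np.vectorize(lambda z: _from_unconstrained(name, z))(chain[:, :, j])
        arr = nat.T  # (chain, draw)
        samples[name] = arr
        rhat[name] = float(np.asarray(az.rhat(arr)))
        ess[name] = float(np.asarray(az.ess(arr)))
    point: dict = {}
    for n in free:
        point.update(_expand_updates(n, float(np.median(np.asarray(samples[n])))))
    params = replace(base, **point)
    ll = loglik(pack(params, free))
    max_rhat = max(rhat.values())
    msg = "" if max_rhat <= 1.1 else f"R-hat {max_rhat:.3f} exceeds 1.1"
    k = len(free)
    return FitResult(
        params=params,
        free=free,
        strategy=strategy,
        log_likelihood=float(ll),
        aic=float(2 * k - 2 * ll),
        n_params=k,
        converged=max_rhat <= 1.1,
        data_hash=trials.data_hash(),
        message=msg,
        samples=samples,
        rhat=rhat,
        ess=ess,
        label=label or f"{strategy}:mcmc",
    )


def aic_compare(fits: Sequence[FitResult]):
    """Delta-AIC table relative to the best model, sorted ascending.

    All fits must be on the same dataset (verified via the data hash).
    """
    import pandas as pd

    if not fits:
        raise ValueError("need at least one fit")
    hashes = {f.data_hash for f in fits}
    if len(hashes) > 1:
        raise ValueError("fits were computed on different datasets")
    rows = sorted(fits, key=lambda f: f.aic)
    best = rows[0].aic
    return pd.DataFrame(
        {
            "model": [f.label for f in rows],
            "strategy": [f.strategy for f in rows],
            "n_params": [f.n_params for f in rows],
            "log_likelihood": [f.log_likelihood for f in rows],
            "aic": [f.aic for f in rows],
            "delta_aic": [f.aic - best for f in rows],
        }
    )


def variance_explained(
    fit: FitResult | ModelParams,
    trials: TrialTable,
    strategy: str | None = None,
    quad_order: int = 5,
    t2: T2Table | None = None,
) -> float:
    """Goodness of fit: model vs empirical response CDFs, as a percentage.

    Per condition with at least two trials, the model CDF (measured from 0
    deg) is evaluated at the sorted reports and compared with the empirical
    CDF levels (i - 1/2)/n; VE = 100 * (1 - SS_res / SS_tot) pooled over
    conditions.
    """
    if isinstance(fit, FitResult):
        params, strategy = fit.params, fit.strategy
    else:
        params = fit
        if strategy is None:
            raise ValueError("strategy required when passing bare params")
    t2 = default_t2() if t2 is None else t2
    resid = []
    levels_all = []
    for label, sub in trials.df.groupby("condition", sort=True):
        reports = np.sort(sub["report_deg"].to_numpy())
        if len(reports) < 2:
            continue
        cond = trials.condition_of(str(label))
        rd = response_distribution(cond, params, strategy, quad_order, t2=t2)
        model_cdf = rd.cdf(reports)
        levels = (np.arange(1, len(reports) + 1) - 0.5) / len(reports)
        resid.append(model_cdf - levels)
        levels_all.append(levels)
    if not resid:
        raise ValueError("need at least one condition with >= 2 trials")
    resid = np.concatenate(resid)
    levels_all = np.concatenate(levels_all)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((levels_all - levels_all.mean()) ** 2))
    return 100.0 * (1.0 - ss_res / ss_tot)


def bootstrap_pvalue(samples, boundary: float, side: str = "greater") -> float:
    """Conservative bootstrap p-value (t+1)/(N+2).

    ``t`` counts bootstrap samples beyond the boundary on the stated side;
    the +1/+2 correction is the MAP estimate under a uniform prior,
    accounting for the finite number of resamples.
    """
    s = np.asarray(samples, dtype=float)
    if s.size < 1:
        raise ValueError("need at least one bootstrap sample")
    if side == "greater":
        t = int(np.sum(s > boundary))
    elif side == "less":
        t = int(np.sum(s < boundary))
    else:
        raise ValueError("side must be 'greater' or 'less'")
    return (t + 1) / (s.size + 2)
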