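# hiercausal

Hierarchical Bayesian causal inference for visual motion perception.

Motion is only defined relative to a reference frame, and the frame the
brain uses appears to be inferred from the scene itself: dots that move
together become an object, an object becomes the frame for a differently
moving part, and the percept of each element is its motion in the lowest
frame in which it actually moves.  `hiercausal` implements this idea as a
complete, fittable observer model for psychophysicists and computational
neuroscientists: it enumerates candidate grouping structures, computes the
exact posterior over structures and perceived velocities, maps that
posterior to circular report distributions, simulates synthetic observers,
and fits the model to trial data.

## The model in brief

A scene of n elements is explained by a *causal structure*: a grouping
tree (elements → groups → supergroups → stationary world) with a binary
flag C per node saying whether its relative velocity is exactly zero.
Relative velocities have a spike-and-slab prior

    v_rel ~ α δ(0) + (1 − α) N(0, σ_prior² I),

(friction makes most relative motion exactly zero; what moves is slow);
velocities compose down the tree with noise σ_Δ, and observations add
per-element noise σ_obs.  Because everything is linear-Gaussian given the
structure, the posterior over an element's perceived velocity is an exact
mixture of Gaussians — one component per structure, with closed-form
weights — and the percept of an element is the posterior over the first
flagged-moving node on its path to the world.  A two-element scene admits
12 structures, a three-element scene 264.  Direction mixtures are obtained
through a calibrated von Mises approximation (κ = T₂(σ²/‖μ‖²)), a lapse
component, four readout strategies (model averaging, model selection,
structure sampling, posterior sampling), motor bias b and motor noise κ_m;
report distributions marginalize observation noise by Gauss–Hermite
quadrature, giving a deterministic likelihood for fitting (BFGS MLE, AIC,
ensemble MCMC with R̂/ESS diagnostics).

See `docs/methods.md` for assumptions, parameterization, numerics and
limitations.

## Worked example

Posterior over causal structures for a center patch moving at 10° above a
rightward-moving five-patch surround (the classic center–surround
geometry; velocities in deg/s):

```python
import numpy as np
import hiercausal as hc

params = hc.ModelParams()                      # see docs/methods.md
cond = hc.exp1_condition(10.0, surround_moving=True, n_surround_patches=5)
pm = hc.percept_mixture(np.asarray(cond.velocities), params)
structs = hc.enumerate_causal_structures(2)
for i in np.argsort(pm.weights)[::-1][:3]:
    s = structs[i]
    th = np.rad2deg(np.arctan2(pm.means[i][1], pm.means[i][0]))
    print(f"structure {i:2d}  flags={s.moving_flags}  w={pm.weights[i]:.3f}  "
          f"percept_dir={th:5.1f} deg")
```

prints

```
structure  5  flags=(0, 0, 1)  w=0.961  percept_dir=  5.0 deg
structure  9  flags=(1, 0, 1)  w=0.011  percept_dir= 75.0 deg
structure  7  flags=(0, 1, 1)  w=0.011  percept_dir=  9.6 deg
```

At 10° separation the observer overwhelmingly *integrates*: the dominant
structure (flags (0, 0, 1)) has center and surround exactly stationary
inside a moving group, so the percept is the cue-combined group direction
(5.0°), biased from the retinal 10° toward the surround.  The runner-up
(flags (1, 0, 1)) is *segmentation* — the center moving within the
surround-defined frame — whose percept (75°) is pulled toward the vertical
relative velocity.  Predicted mean reports across separations show the
transition between these regimes:

```python
for d in (2.5, 10.0, 45.0):
    rd = hc.response_distribution(hc.exp1_condition(d, True, 5), params,
                                  "posterior_sampling", quad_order=7)
    print(f"center {d:4.1f} deg -> mean report {rd.circular_mean():5.1f} deg")
```

```
center  2.5 deg -> mean report   0.9 deg     # integration (toward 0°)
center 10.0 deg -> mean report   3.9 deg
center 45.0 deg -> mean report  53.1 deg     # segmentation (toward 90°)
```

Synthetic observers and fitting:

```python
grid = [hc.exp1_condition(d, True, 5) for d in (0, 2.5, 5, 10, 20, 45)]
trials = hc.simulate_trials(grid, params, "posterior_sampling", 300, rng=1)
fit = hc.fit_mle(trials, "posterior_sampling", free=("alpha",))
post = hc.sample_posterior(trials, "posterior_sampling", free=("alpha",),
                           n_chains=6, n_samples=500, seed=2)
```

recovers the generating delta mass α = 0.9 with a calibrated credible
interval; `hc.aic_compare` ranks readout strategies (ΔAIC), and
`hc.variance_explained` scores the CDF-level goodness of fit.

A thin CLI wraps the same functions:

```bash
hiercausal structures --n 3 --count      # 264
hiercausal --seed 7 --out trials.csv simulate --trials-per-condition 22
hiercausal --out fit.json fit trials.csv --free alpha --mcmc
```

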