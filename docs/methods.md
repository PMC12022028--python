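# Methods

## The model

`hiercausal` implements a hierarchical Bayesian observer for visual motion.
The generative claim is that visual elements move inside nested reference
frames: elements belong to groups, groups to supergroups, and the top frame
is the stationary world (the observer is assumed stationary; the world
velocity is a fixed constant (0, 0), not a free parameter).  A scene
interpretation is a *causal structure*: a grouping tree over the n elements
plus one binary flag per node saying whether that node's velocity relative
to its parent frame is exactly zero or not.

Relative velocities carry a spike-and-slab prior

    v_rel ~ alpha * delta(0) + (1 - alpha) * N(0, sigma_prior^2 I),

reflecting two facts about the physical world: friction makes most relative
motion exactly zero (the delta, with role-specific mass `alpha_center`,
`alpha_surround`, `alpha_group`), and what does move tends to move slowly
(the Gaussian slab, `sigma_prior`, deg/s).  Absolute velocities compose
down the tree, child = parent + relative, with isotropic composition noise
`sigma_delta`; retinal observations add per-element observation noise
(`sigma_center`, `sigma_surround`, optionally scaled per condition).  A
sharing probability `beta` sets the prior that elements join a common
structure.

### Grouping-tree grammar

The enumeration generates trees as chains of partitions: level 1 partitions
the elements, level 2 the level-1 blocks, and so on.  Every block at every
level is a node with its own relative velocity; each level must contain at
least one merge; and a singleton chain hanging directly off the world frame
is pruned, because a group with a single child and nothing above it is
indistinguishable from that child moving in the world frame.  Chains that
build the same tree are removed by label-respecting canonical
deduplication.  Under this grammar a single element admits 2 causal
structures, two elements 12, three elements 264, and the largest tree over
n elements has exactly n(n+1)/2 nodes.  Alternative grammars considered
(groups restricted to >= 2 children; unrestricted singleton groups) produce
168 or unboundedly many three-element structures and were rejected; the
partition-chain grammar is the one frozen as the default.

### Exact inference

Conditional on a structure, everything is linear-Gaussian and the x and y
axes decouple (all covariances are isotropic).  The stacked observations
are zero-mean Gaussian per axis with

    Sigma[e, f] = sum over nodes k shared by the world-paths of e and f of
                  (flag_k * sigma_prior^2 + sigma_delta^2)
                  + delta_ef * sigma_obs_e^2,

so each structure's marginal likelihood is a closed-form multivariate
normal and the posterior over the percept-defining relative velocity (the
first flag-1 node on the element's path to the world; exactly stationary if
there is none) is scalar-Gaussian per axis by conjugate conditioning.  The
posterior over the percept is therefore an exact mixture of isotropic
Gaussians, one component per structure, with log-domain weights normalized
by log-sum-exp (weights span hundreds of orders of magnitude across the
264 three-element structures).  We implement this with dense per-structure
covariance algebra rather than message passing: for n <= 4 the matrices
are at most 4 x 4, the expressions are exact either way, and the dense
form vectorizes over batches of observations, which dominates runtime in
practice.

The prior over trees is parameterized as weight proportional to
beta^(#groups) x (1-beta)^(#roots - 1), normalized over the enumerated
set; for two elements this reduces exactly to P(shared group) = beta.

### From velocities to directions

An isotropic Gaussian velocity component maps to an approximately von
Mises direction distribution whose concentration depends only on the ratio
r = sigma^2 / ||mu||^2.  The mapping r -> kappa is calibrated once by Monte
Carlo (2e5 common-random-number samples per ratio on a 65-point log grid
from 1e-4 to 1e4, mean-resultant-length matching, monotone PCHIP
interpolation in log-log space) and cached.  Outside the grid the exact
small-ratio asymptote kappa ~ 1/r and a 1/sqrt(r) large-ratio tail are
used; kappa is capped at 1e4 and ratios floored at 1e-8 to keep Bessel
evaluations stable.  Components with exactly zero mean speed (stationary
percepts) have no defined direction and are assigned kappa = 0, i.e. a
uniform circular component: this is the r -> infinity limit of the
calibration and preserves their posterior mass instead of dropping it.
A lapse component (weight `lambda_lapse`, mean `theta_lapse_deg`,
concentration `kappa_lapse`) is prepended to every direction mixture.

### Readout and response distributions

Four strategies map the direction mixture to a single-trial estimate:
model averaging (circular mean of the mixture, using resultant-length
weighting), model selection (mean direction of the maximum-weight
component; ties break to the lowest canonical structure index, a
measure-zero event), structure sampling (the mean direction of a component
drawn by weight), and posterior sampling (a draw from the full mixture).

The predicted report distribution marginalizes observation noise with
product Gauss-Hermite quadrature (default 7 nodes per scalar dimension,
4 dimensions for two elements; more than 6 dimensions raises an explicit
error pointing to the Monte-Carlo path).  At each quadrature node the
point-estimate strategies contribute one von Mises centered at the
estimate plus motor bias `motor_bias_deg` with motor concentration
`kappa_motor`.  For the sampling strategies the estimate at a node is a
distribution, not a point; each of its components is convolved with the
motor von Mises analytically, approximating the convolution of two von
Mises by a von Mises whose mean resultant length is the product of the two
(for structure sampling the components are point masses, so no
approximation is involved).  This keeps the likelihood deterministic, so
optimization and MCMC are well posed.  The self-consistency tests compare
these analytic densities against full forward simulation and bound the
combined quadrature + convolution error at KS < 0.02.

Quadrature convergence: for the sampling strategies raising the order from
5 to 9 changes per-trial log-likelihoods by under 1e-3 on the two-element
geometry.  The point-estimate strategies converge more slowly because the
estimate is a non-smooth function of the observation (the argmax jumps);
their self-consistency checks therefore use order 9, and likelihood-based
comparisons involving them should be read at a ~1e-2 per-trial resolution.

## Fitting

The dataset log-likelihood sums log response densities per trial, caching
one response distribution per condition.  MLE runs BFGS on an
unconstrained parameterization (log sigmas and concentrations, logit
probabilities, untransformed circular means) with optional multi-start;
AIC = 2k - 2 logL.  The finite-difference step is 1e-3: cached likelihood
kernels are stored in single precision, and machine-epsilon steps would
fall below their noise floor.  MCMC uses an affine-invariant ensemble
sampler (any validated sampler satisfies the contract; correctness is
judged by R-hat <= 1.1, effective sample size, and the coverage tests, not
by the algorithm's name), with 20% burn-in and thinning by 10 by default,
and R-hat/ESS computed per parameter.  Default weakly informative priors:
Beta(1,1) for probabilities, half-normal(5 deg/s) for sigmas, log-normal
(median 20, log-sd 2) for concentrations, uniform for circular means; all
overridable per parameter.

For free parameters that only reweight mixture components — the delta
masses, the sharing probability and the lapse rate — `WeightLikelihood`
precomputes per-structure marginal likelihoods and von Mises response
kernels once and re-evaluates the full dataset likelihood in milliseconds.
This exact cache is what makes the 20-observer recovery study run at desk
scale; it applies to the sampling strategies (whose component set is the
full mixture).  A role-tied pseudo-parameter `alpha` (one delta mass for
center, surround and group) is available for one-dimensional recovery
studies.

Variance explained compares, per condition with at least two trials, the
model CDF (measured from 0 deg) at the sorted reports against empirical
CDF levels (i - 1/2)/n, pooled as VE = 100 (1 - SS_res / SS_tot).
Bootstrap p-values use the conservative (t+1)/(N+2) convention, the MAP
estimate under a uniform prior given finite resamples.

## Stimulus geometries

Two-element scenes: the surround moves rightward at 1 deg/s (or is
stationary); the center direction is drawn from {0, ±2.5, ±5, ±10, ±20,
±45} deg with its horizontal velocity component matched to the surround,
making the center–surround relative velocity exactly vertical.  The number
of surround patches k in {1, 2, 3, 5, 10} enters the model by scaling the
surround observation noise as 1/sqrt(k): k patches act as independent
measurements of the common surround velocity.  This scaling is a modeling
choice of this package (it reproduces the qualitative strengthening of
integration and segmentation with patch count); other uncertainty-pooling
rules are conceivable.

Three-element scenes: concentric center (0.5 deg/s), inner ring and outer
ring, in a canonical frame with the center at 0 deg.  Inner-ring direction
offsets {0, -3, -10, -30, -45} deg (clockwise); ring speeds are solved so
every ring-minus-center relative velocity is perpendicular to the center
direction (pinning each ring's horizontal component to 0.5 deg/s), and the
outer ring maintains a constant outer-minus-inner relative velocity
anchored at the configuration (inner at 0 deg, outer at 60 deg
counter-clockwise).  The ring observation-noise scales (1/sqrt(5), 1/5)
follow the 5-fold dot-count increases from center to inner to outer ring.
The real experiment randomizes the center direction over 360 deg and
derotates before analysis; the generator works directly in the canonical
frame because the model is exactly rotation-equivariant (a tested
invariant).

The modulation index w in [-1, 1] summarizes the surround's influence:
percept = o_center - w o_surround for w >= 0 (partial segmentation) and
(1+w) o_center - w o_surround for w <= 0 (partial integration), so +1 is
the full relative velocity, 0 the unmodified center, -1 the surround.  The
noise-aware posterior over w marginalizes observation noise by quadrature
and models motor bias and motor von Mises noise explicitly, on a flat grid
prior over [-1, 1]; the naive per-trial algebraic inversion is also
exposed but flagged as biased.  When a reported direction is unreachable
under any w the noise model keeps the likelihood positive; the grid is
never clipped.

## Synthetic observers

The synthetic observer runs the full forward pass per trial: sample noisy
observations, exact structure inference, strategy readout, motor bias,
motor noise, lapse.  Default parameters used throughout the tests:
`alpha = 0.9` for all roles (most prior mass in the delta component, as
fitted observers show), `sigma_prior = 1` deg/s (stimulus speeds are
~1 deg/s), `sigma_delta = 0.1` deg/s, `sigma_center = sigma_surround =
0.2` deg/s (a ~20% Weber-like fraction of the 1 deg/s stimulus speed,
and the regime in which the observer both integrates at small
separations and segments at large ones), `beta = 0.5`,
`lambda_lapse = 0.02` with a uniform lapse
(kappa 0), no motor bias, `kappa_motor = 50` (~8 deg motor sd).  With
these values the predicted center reports reproduce the signature
transition: integration (reports pulled toward the surround) for small
center directions, segmentation (reports pushed toward the vertical
relative direction) for large ones, with maximal variability in between.

What the generator emulates and what it does not: it produces data with
the model's own assumed structure (Gaussian observation noise,
structure-conditional percepts, von Mises motor noise, constant lapse).
Passing recovery and self-consistency tests therefore demonstrates
correctness and internal calibration of the machinery, not that human
data follow the model; they say nothing about model misspecification,
sequential effects, learning, or eye-movement artifacts present in real
experiments.

## Problem sizes in the shipped tests

The test suite scales the study down to desk size as its own design
choice: oracle equivalence uses two randomized two-element cases with 1e6
importance-sampling particles; distributional self-consistency uses the
six positive center directions with a moving 5-patch surround, 1e4
simulated trials per case and all four strategies (negative directions are
covered by the tested mirror symmetry); parameter recovery uses 20
synthetic observers spanning alpha in {0.5, 0.9, 0.99}, ~2000 trials each
over six directions, with the one-dimensional tied-alpha posterior sampled
by 6 walkers for 180 steps; the model-comparison mirror uses 5 replicates
of 600 trials with a four-model factorial (posterior sampling with and
without the delta component, selection, averaging).  The MCMC budget is
deliberately small and is validated by the calibration test itself; the
full-scale budget (144 chains x 25000 samples) remains available through
the API.

## Known limitations

* Enumeration is exact only up to n = 4 elements (24496 structures); the
  package deliberately has no sampling-based structure search.
* The quantitative three-element model is exposed (the 264-structure
  engine runs), but fitting it to data is not attempted; the pure-structure
  filter exists to support qualitative predictions.
* The von Mises approximation to the direction distribution of a Gaussian
  velocity degrades when the component mean speed is comparable to its
  standard deviation and the true direction distribution becomes bimodal;
  the calibration absorbs this only on average.
* The Gaussian slab implies a Rayleigh speed distribution; heavier-tailed
  speed priors are out of scope.
* Self-motion / optic-flow extensions (a nonzero top-level velocity) are
  not implemented; the world frame is fixed at zero.
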