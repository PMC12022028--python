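"""Stimulus geometry, the modulation index, and observer preprocessing/QC.

Experiment 1: a center patch moving at 1 deg/s in a direction chosen from
{0, +-2.5, +-5, +-10, +-20, +-45} deg, surrounded by k in {1,2,3,5,10}
patches that are either stationary or move rightward at 1 deg/s.  The
horizontal velocity component of the center matches the surround, so the
center-surround relative velocity is exactly vertical (+-90 deg).

Experiment 2: concentric center / inner ring / outer ring.  The center
moves at 0.5 deg/s (canonical frame: at 0 deg); the inner ring direction is
offset clockwise by {0, -3, -10, -30, -45} deg with its speed solved so the
ring-minus-center relative velocity is perpendicular to the center; the
outer ring keeps a constant outer-minus-inner relative velocity anchored at
the (inner 0 deg, outer 60 deg CCW) configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._circ import circ_sd_deg, vm_logpdf_deg, wrap_deg, wrap_signed_deg, logsumexp
from .model import ModelParams

EXP1_CENTER_DIRECTIONS = (0.0, 2.5, -2.5, 5.0, -5.0, 10.0, -10.0, 20.0, -20.0, 45.0, -45.0)
EXP1_PATCH_COUNTS = (1, 2, 3, 5, 10)
EXP1_SPEED = 1.0  # deg/s
EXP2_INNER_OFFSETS = (0.0, -3.0, -10.0, -30.0, -45.0)
EXP2_CENTER_SPEED = 0.5  # deg/s
EXP2_OUTER_ANCHOR_DEG = 60.0  # outer direction when the inner offset is 0

QC_MAX_CIRC_SD_DEG = 30.0


@dataclass(frozen=True)
class StimulusCondition:
    """Experimenter-defined velocities per element plus a condition label."""

    label: str
    velocities: tuple[tuple[float, float], ...]
    roles: tuple[str, ...]
    obs_scale: tuple[float, ...] = ()
    #: generator metadata (experiment factors), not part of identity
    meta: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if len(self.roles) != len(self.velocities):
            raise ValueError("one role per element required")
        if not self.obs_scale:
            object.__setattr__(self, "obs_scale", (1.0,) * len(self.roles))
        if len(self.obs_scale) != len(self.velocities):
            raise ValueError("one obs_scale per element required")
        for v in self.velocities:
            if not np.all(np.isfinite(v)):
                raise ValueError("velocities must be finite")

    @property
    def n_elements(self) -> int:
        return len(self.velocities)

    def velocity_array(self) -> np.ndarray:
        return np.asarray(self.velocities, dtype=float)


# ---------------------------------------------------------------------------
# geometry


def exp1_velocities(
    center_direction_deg: float, surround_moving: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Center and surround retinal velocities for an Experiment-1 trial.

    The surround moves rightward at 1 deg/s (or is stationary); the center
    keeps its horizontal component matched to the moving surround, so its
    velocity is (1, tan(direction)) and the relative velocity is vertical.
    """
    if abs(center_direction_deg) >= 90.0:
        raise ValueError("center direction must satisfy |direction| < 90 deg")
    center = np.array(
        [EXP1_SPEED, EXP1_SPEED * np.tan(np.deg2rad(center_direction_deg))]
    )
    surround = np.array([EXP1_SPEED, 0.0]) if surround_moving else np.zeros(2)
    return center, surround


def exp1_condition(
    center_direction_deg: float,
    surround_moving: bool = True,
    n_surround_patches: int = 5,
) -> StimulusCondition:
    """Build an Experiment-1 stimulus condition.

    The surround's observation noise shrinks with the number of patches k
    as 1/sqrt(k): k independent patches act as repeated measurements of the
    common surround velocity.
    """
    if n_surround_patches < 1:
        raise ValueError("need at least one surround patch")
    c, s = exp1_velocities(center_direction_deg, surround_moving)
    label = (
        f"c{center_direction_deg:+g}_"
        f"{'mov' if surround_moving else 'stat'}_k{n_surround_patches}"
    )
    return StimulusCondition(
        label=label,
        velocities=(tuple(c), tuple(s)),
        roles=("center", "surround"),
        obs_scale=(1.0, 1.0 / np.sqrt(n_surround_patches)),
        meta={
            "center_dir_deg": float(center_direction_deg),
            "surround_moving": bool(surround_moving),
            "n_surround_patches": int(n_surround_patches),
        },
    )


def exp1_grid(
    directions: Sequence[float] = EXP1_CENTER_DIRECTIONS,
    patch_counts: Sequence[int] = EXP1_PATCH_COUNTS,
    stationary_patch_count: int = 5,
    include_stationary: bool = True,
) -> list[StimulusCondition]:
    """The full Experiment-1 condition grid (duplicate-free)."""
    grid = [
        exp1_condition(d, True, k) for d in directions for k in patch_counts
    ]
    if include_stationary:
        grid += [exp1_condition(d, False, stationary_patch_count) for d in directions]
    labels = [c.label for c in grid]
    if len(set(labels)) != len(labels):
        raise ValueError("condition grid contains duplicates")
    return grid


def exp2_velocities(inner_offset_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center, inner-ring and outer-ring velocities (canonical frame).

    The center moves at (0.5, 0).  Perpendicularity of the ring-minus-center
    relative velocity to the center direction pins every ring's horizontal
    component to 0.5; the inner speed follows from its direction offset and
    the outer velocity from the constant outer-minus-inner relative velocity
    anchored at the (0 deg, 60 deg CCW) configuration.
    """
    if not -45.0 <= inner_offset_deg <= 0.0:
        raise ValueError("inner offset must lie in [-45, 0] deg")
    center = np.array([EXP2_CENTER_SPEED, 0.0])
    if abs(inner_offset_deg) >= 90.0:  # unreachable given the bound above
        raise ValueError("perpendicularity constraint infeasible")
    inner = np.array(
        [EXP2_CENTER_SPEED, EXP2_CENTER_SPEED * np.tan(np.deg2rad(inner_offset_deg))]
    )
    outer_anchor = np.array(
        [EXP2_CENTER_SPEED, EXP2_CENTER_SPEED * np.tan(np.deg2rad(EXP2_OUTER_ANCHOR_DEG))]
    )
    rel_outer_inner = outer_anchor - np.array([EXP2_CENTER_SPEED, 0.0])
    outer = inner + rel_outer_inner
    return center, inner, outer


def exp2_condition(inner_offset_deg: float, report_target: str = "center") -> StimulusCondition:
    c, i, o = exp2_velocities(inner_offset_deg)
    # dot densities: 10 center, 50 inner, 250 outer dots -> noise ~ 1/sqrt(N)
    return StimulusCondition(
        label=f"inner{inner_offset_deg:+g}_{report_target}",
        velocities=(tuple(c), tuple(i), tuple(o)),
        roles=("center", "inner", "outer"),
        obs_scale=(1.0, 1.0 / np.sqrt(5.0), 1.0 / 5.0),
        meta={
            "inner_offset_deg": float(inner_offset_deg),
            "report_target": report_target,
        },
    )


def exp2_grid(
    offsets: Sequence[float] = EXP2_INNER_OFFSETS,
    report_targets: Sequence[str] = ("center",),
) -> list[StimulusCondition]:
    return [exp2_condition(o, t) for t in report_targets for o in offsets]


# ---------------------------------------------------------------------------
# modulation index


def modulation_percept(w_mi: float, o_center, o_surround) -> np.ndarray:
    """Predicted center percept under modulation index w_MI in [-1, 1].

    w = +1 is complete segmentation (center-minus-surround relative
    velocity), w = 0 no surround effect (center velocity), w = -1 complete
    integration (the surround velocity).
    """
    if not -1.0 <= w_mi <= 1.0:
        raise ValueError("w_MI must lie in [-1, 1]")
    oc = np.asarray(o_center, dtype=float)
    os_ = np.asarray(o_surround, dtype=float)
    if w_mi >= 0.0:
        return oc - w_mi * os_
    return (1.0 + w_mi) * oc - w_mi * os_


def invert_modulation_index(
    percept_direction_deg: float, o_center, o_surround, grid_size: int = 4001
) -> float:
    """Noiseless algebraic inversion: the w_MI whose predicted percept
    direction matches the given direction (nearest match if unreachable)."""
    ws = np.linspace(-1.0, 1.0, grid_size)
    oc = np.asarray(o_center, dtype=float)
    os_ = np.asarray(o_surround, dtype=float)
    pos = oc[None, :] - ws[:, None] * os_[None, :]
    neg = (1.0 + ws[:, None]) * oc[None, :] - ws[:, None] * os_[None, :]
    percepts = np.where(ws[:, None] >= 0.0, pos, neg)
    dirs = np.rad2deg(np.arctan2(percepts[:, 1], percepts[:, 0]))
    err = np.abs(wrap_signed_deg(dirs - percept_direction_deg))
    best = int(np.argmin(err))
    # refine around the grid minimum by local quadratic of the wrapped error
    if 0 < best < grid_size - 1 and err[best] < 90.0:
        from scipy.optimize import minimize_scalar

        def f(w):
            p = modulation_percept(float(w), oc, os_)
            return abs(
                wrap_signed_deg(
                    np.rad2deg(np.arctan2(p[1], p[0])) - percept_direction_deg
                )
            )

        res = minimize_scalar(f, bounds=(ws[best - 1], ws[best + 1]), method="bounded")
        return float(res.x)
    return float(ws[best])


@dataclass
class ModulationPosterior:
    """Grid posterior over the modulation index for one condition."""

    grid: np.ndarray
    log_posterior: np.ndarray
    mean: float
    sd: float
    ci95: tuple[float, float]
    mode: float
    naive_estimates: np.ndarray | None = None  # biased per-trial inversion


def infer_modulation_index(
    reports_deg: Sequence[float],
    condition: StimulusCondition,
    params: ModelParams,
    grid: np.ndarray | None = None,
    quad_order: int = 7,
) -> ModulationPosterior:
    """Noise-aware posterior over w_MI given reported directions.

    Forward model per trial: observations are the condition velocities
    corrupted by observation noise (marginalized by Gauss-Hermite
    quadrature), the percept follows the piecewise modulation map, and the
    report adds motor bias and von Mises motor noise.  The flat grid prior
    makes the posterior proportional to the likelihood; the naive per-trial
    algebraic inversion is also returned, flagged as biased.
    """
    reports = np.asarray(reports_deg, dtype=float)
    if reports.size == 0:
        raise ValueError("reports must be nonempty")
    if condition.n_elements < 2:
        raise ValueError("condition needs center and surround elements")
    ws = np.linspace(-1.0, 1.0, 201) if grid is None else np.asarray(grid, dtype=float)
    nu = condition.velocity_array()[:2]
    sigma = np.array(
        [
            params.sigma_for(r) * s
            for r, s in zip(condition.roles[:2], condition.obs_scale[:2])
        ]
    )
    x, wq = np.polynomial.hermite.hermgauss(quad_order)
    # product nodes over 4 scalar dimensions (2 elements x 2 axes)
    grids = np.meshgrid(*([x] * 4), indexing="ij")
    wgrid = np.ones_like(grids[0])
    for g in np.meshgrid(*([wq] * 4), indexing="ij"):
        wgrid = wgrid * g
    wgrid = (wgrid / np.pi**2).ravel()
    oc = nu[0][None, :] + np.sqrt(2.0) * sigma[0] * np.stack(
        [grids[0].ravel(), grids[1].ravel()], axis=1
    )
    os_ = nu[1][None, :] + np.sqrt(2.0) * sigma[1] * np.stack(
        [grids[2].ravel(), grids[3].ravel()], axis=1
    )
    logpost = np.empty_like(ws)
    for i, w in enumerate(ws):
        p = (
            oc - w * os_
            if w >= 0.0
            else (1.0 + w) * oc - w * os_
        )
        theta = np.rad2deg(np.arctan2(p[:, 1], p[:, 0])) + params.motor_bias_deg
        comp = vm_logpdf_deg(reports[:, None], theta[None, :], params.kappa_motor)
        logpost[i] = float(
            np.sum(logsumexp(np.log(wgrid)[None, :] + comp, axis=1))
        )
    logpost -= logsumexp(logpost)
    prob = np.exp(logpost)
    prob /= prob.sum()
    mean = float(np.sum(ws * prob))
    sd = float(np.sqrt(np.sum((ws - mean) ** 2 * prob)))
    cdf = np.cumsum(prob)
    lo = float(ws[np.searchsorted(cdf, 0.025)])
    hi = float(ws[min(np.searchsorted(cdf, 0.975), len(ws) - 1)])
    naive = np.array(
        [invert_modulation_index(r, nu[0], nu[1]) for r in reports]
    )
    return ModulationPosterior(
        grid=ws,
        log_posterior=logpost,
        mean=mean,
        sd=sd,
        ci95=(lo, hi),
        mode=float(ws[int(np.argmax(prob))]),
        naive_estimates=naive,
    )


# ---------------------------------------------------------------------------
# preprocessing and QC (operate on the TrialTable from hiercausal.io)


def preprocess_reports(trials):
    """Reflect trials with negative center directions about the x-axis.

    Responses for center direction -d become 360 - R at center direction
    +d, matching the symmetric-response convention used when collapsing the
    two sides of the direction set.  Returns a new TrialTable; applying the
    operation twice is the identity.
    """
    from .io import TrialTable

    df = trials.df.copy()
    neg = df["center_dir_deg"] < 0
    df.loc[neg, "report_deg"] = wrap_deg(-df.loc[neg, "report_deg"])
    df.loc[neg, "center_dir_deg"] = -df.loc[neg, "center_dir_deg"]
    df["condition"] = [
        exp1_condition(row.center_dir_deg, bool(row.surround_moving), int(row.n_surround_patches)).label
        for row in df.itertuples()
    ]
    return TrialTable.from_frame(df)


def observer_qc(trials, control_condition: str) -> tuple[bool, float]:
    """Keep/exclude decision from control-condition response dispersion.

    Computes the circular standard deviation of control reports around the
    identity prediction (the center's retinal direction) and excludes the
    observer when it exceeds 30 deg (strict inequality: exactly 30 keeps).
    Returns (keep, circular_sd_deg).
    """
    df = trials.df
    ctrl = df[df["condition"] == control_condition]
    if len(ctrl) == 0:
        raise ValueError(f"no trials for control condition {control_condition!r}")
    residual = wrap_signed_deg(ctrl["report_deg"].to_numpy() - ctrl["center_dir_deg"].to_numpy())
    sd = float(circ_sd_deg(residual))
    return sd <= QC_MAX_CIRC_SD_DEG, sd
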