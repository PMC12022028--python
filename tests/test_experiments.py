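import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiercausal._circ import wrap_signed_deg
from hiercausal.experiments import (
    EXP1_CENTER_DIRECTIONS,
    EXP2_INNER_OFFSETS,
    exp1_condition,
    exp1_grid,
    exp1_velocities,
    exp2_velocities,
    infer_modulation_index,
    invert_modulation_index,
    modulation_percept,
    observer_qc,
    preprocess_reports,
)
from hiercausal.io import TrialTable, simulate_trials
from hiercausal.model import ModelParams
from hiercausal.readout import POSTERIOR_SAMPLING

import pandas as pd


class TestExp1Geometry:
    def test_zero_direction_matches_surround(self):
        c, s = exp1_velocities(0.0, True)
        assert np.allclose(c, [1.0, 0.0])
        assert np.allclose(s, [1.0, 0.0])

    def test_relative_velocity_is_vertical(self):
        for d in EXP1_CENTER_DIRECTIONS:
            c, s = exp1_velocities(d, True)
            rel = c - s
            assert abs(rel[0]) < 1e-12
            if d != 0:
                assert np.sign(rel[1]) == np.sign(d)
                rel_dir = np.rad2deg(np.arctan2(rel[1], rel[0]))
                assert np.isclose(abs(rel_dir), 90.0)

    def test_forty_five_degrees(self):
        c, s = exp1_velocities(45.0, True)
        assert np.allclose(c, [1.0, 1.0])
        c2, s2 = exp1_velocities(45.0, False)
        assert np.allclose(c2, c)
        assert np.allclose(s2, [0.0, 0.0])

    def test_steep_directions_rejected(self):
        with pytest.raises(ValueError):
            exp1_velocities(90.0, True)

    def test_grid_complete_and_duplicate_free(self):
        grid = exp1_grid()
        assert len(grid) == 11 * 5 + 11
        assert len({c.label for c in grid}) == len(grid)

    def test_patch_count_scales_surround_reliability(self):
        c1 = exp1_condition(10.0, True, 1)
        c9 = exp1_condition(10.0, True, 9)
        assert np.isclose(c9.obs_scale[1], c1.obs_scale[1] / 3.0)


class TestExp2Geometry:
    def test_zero_offset_anchor(self):
        c, i, o = exp2_velocities(0.0)
        assert np.allclose(i, c)
        outer_dir = np.rad2deg(np.arctan2(o[1], o[0]))
        assert np.isclose(outer_dir, 60.0)

    def test_inner_speed_at_minus_45(self):
        _, i, _ = exp2_velocities(-45.0)
        assert np.isclose(np.hypot(*i), 0.5 * np.sqrt(2.0))

    def test_ring_relative_velocities_perpendicular_to_center(self):
        for off in EXP2_INNER_OFFSETS:
            c, i, o = exp2_velocities(off)
            assert abs(np.dot(i - c, c)) < 1e-12
            assert abs(np.dot(o - c, c)) < 1e-12

    def test_outer_minus_inner_constant(self):
        rels = [np.subtract(*exp2_velocities(off)[2:0:-1]) for off in EXP2_INNER_OFFSETS]
        rels = [exp2_velocities(off)[2] - exp2_velocities(off)[1] for off in EXP2_INNER_OFFSETS]
        for r in rels[1:]:
            assert np.allclose(r, rels[0], atol=1e-10)

    def test_out_of_range_offset_rejected(self):
        with pytest.raises(ValueError):
            exp2_velocities(-60.0)
        with pytest.raises(ValueError):
            exp2_velocities(5.0)


class TestModulationIndex:
    def test_anchors(self):
        oc, os_ = np.array([1.0, 1.0]), np.array([1.0, 0.0])
        assert np.allclose(modulation_percept(1.0, oc, os_), oc - os_)
        assert np.allclose(modulation_percept(-1.0, oc, os_), os_)
        assert np.allclose(modulation_percept(0.0, oc, os_), oc)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            modulation_percept(1.5, [1, 0], [0, 0])

    @given(w=st.floats(-0.95, 0.95))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_inversion_round_trip(self, w):
        oc, os_ = np.array([1.0, 1.0]), np.array([1.0, 0.0])
        p = modulation_percept(w, oc, os_)
        theta = np.rad2deg(np.arctan2(p[1], p[0]))
        assert abs(invert_modulation_index(theta, oc, os_) - w) < 5e-3

    def test_noiseless_reports_recover_w(self):
        # at (near-)zero noise the posterior collapses onto the algebraic
        # inversion of the piecewise modulation map
        oc, os_ = exp1_velocities(20.0, True)
        p = modulation_percept(0.5, oc, os_)
        theta = float(np.mod(np.rad2deg(np.arctan2(p[1], p[0])), 360.0))
        cond = exp1_condition(20.0, True, 5)
        quiet = ModelParams(
            sigma_center=1e-3, sigma_surround=1e-3, kappa_motor=5e3
        )
        post = infer_modulation_index([theta] * 30, cond, quiet)
        assert abs(post.mode - 0.5) < 0.02
        assert np.allclose(post.naive_estimates, 0.5, atol=5e-3)

    def test_reports_at_surround_direction_give_integration(self):
        cond = exp1_condition(20.0, True, 5)
        quiet = ModelParams(sigma_center=1e-3, sigma_surround=1e-3, kappa_motor=5e3)
        post = infer_modulation_index([0.0] * 30, cond, quiet)
        assert post.mean < -0.9

    def test_recovery_with_motor_noise(self, rng):
        # full forward generation (observation + motor noise) at w_true = 0.3:
        # the true value falls inside the 95% CI in >= 90% of replicates
        w_true = 0.3
        params = ModelParams(kappa_motor=50.0)
        cond = exp1_condition(20.0, True, 5)
        nu = cond.velocity_array()
        sigma = np.array(
            [params.sigma_for(r) * s for r, s in zip(cond.roles, cond.obs_scale)]
        )
        hits = 0
        n_rep = 25
        for _ in range(n_rep):
            o = nu[None, :, :] + rng.normal(size=(40, 2, 2)) * sigma[None, :, None]
            percept = o[:, 0, :] - w_true * o[:, 1, :]
            theta = np.rad2deg(np.arctan2(percept[:, 1], percept[:, 0]))
            reports = np.mod(
                theta + np.rad2deg(rng.vonmises(0.0, 50.0, size=40)), 360.0
            )
            post = infer_modulation_index(reports, cond, params)
            hits += post.ci95[0] <= w_true <= post.ci95[1]
        assert hits >= 0.9 * n_rep

    def test_empty_reports_rejected(self):
        cond = exp1_condition(20.0, True, 5)
        with pytest.raises(ValueError):
            infer_modulation_index([], cond, ModelParams())


def _table(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "observer",
            "session",
            "condition",
            "center_dir_deg",
            "surround_moving",
            "n_surround_patches",
            "report_deg",
        ],
    )
    return TrialTable.from_frame(df)


class TestPreprocess:
    def test_reflection(self):
        t = _table([["o1", "1", "c-20_mov_k5", -20.0, True, 5, 350.0]])
        out = preprocess_reports(t)
        assert out.df.loc[0, "report_deg"] == 10.0
        assert out.df.loc[0, "center_dir_deg"] == 20.0
        assert out.df.loc[0, "condition"] == "c+20_mov_k5"

    def test_positive_rows_unchanged(self):
        t = _table([["o1", "1", "c+20_mov_k5", 20.0, True, 5, 15.0]])
        out = preprocess_reports(t)
        pd.testing.assert_frame_equal(out.df, t.df)

    def test_involution(self):
        t = _table(
            [
                ["o1", "1", "c-10_mov_k5", -10.0, True, 5, 355.0],
                ["o1", "1", "c+10_mov_k5", 10.0, True, 5, 5.0],
            ]
        )
        once = preprocess_reports(t)
        twice = preprocess_reports(once)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestObserverQC:
    def _control_table(self, residual_sd_deg, rng, n=200):
        reports = np.mod(20.0 + rng.normal(0.0, residual_sd_deg, size=n), 360.0)
        return _table(
            [["o1", "1", "ctrl", 20.0, False, 5, float(r)] for r in reports]
        )

    def test_low_dispersion_keeps(self, rng):
        keep, sd = observer_qc(self._control_table(12.0, rng), "ctrl")
        assert keep
        assert 10.0 < sd < 14.0

    def test_high_dispersion_excludes(self, rng):
        keep, sd = observer_qc(self._control_table(40.0, rng), "ctrl")
        assert not keep
        assert sd > 30.0

    def test_exact_boundary_keeps(self):
        # two-point residual distribution tuned to exactly 30 deg circ sd
        x = np.rad2deg(np.arccos(np.exp(-0.5 * np.deg2rad(30.0) ** 2)))
        t = _table(
            [
                ["o1", "1", "ctrl", 0.0, False, 5, float(np.mod(x, 360.0))],
                ["o1", "1", "ctrl", 0.0, False, 5, float(np.mod(-x, 360.0))],
            ]
        )
        keep, sd = observer_qc(t, "ctrl")
        assert np.isclose(sd, 30.0, atol=1e-9)
        assert keep

    def test_missing_control_rejected(self, rng):
        with pytest.raises(ValueError):
            observer_qc(self._control_table(10.0, rng), "nope")
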