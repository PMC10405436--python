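"""Step geometry, movement-distribution fitting, strata, covariates,
standardization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fishssf.errors import EstimationError
from fishssf.steps import (annotate_covariates, build_steps,
                           check_stratum_invariants,
                           fit_movement_distributions,
                           generate_candidate_strata, transform_standardize,
                           MovementDistributions)
from fishssf.terms import GlobalStandardization
from fishssf.tracks import RegularTrack


def track_from_points(points, t0="2018-05-10T09:00:00Z"):
    times = pd.Timestamp(t0) + pd.to_timedelta(
        np.arange(len(points)) * 20.0, unit="s")
    xs, ys = zip(*points)
    seg = pd.DataFrame({"time": times, "x": xs, "y": ys})
    return RegularTrack(fish_id="F001", approach_index=1, segments=[seg],
                        method="linear")


class TestBuildSteps:
    def test_northward_step_geometry(self):
        steps = build_steps(track_from_points([(0, 0), (0, 10)]))
        assert steps["sl"].iloc[0] == pytest.approx(10.0)
        assert steps["heading"].iloc[0] == pytest.approx(0.0)
        assert np.isnan(steps["ta"].iloc[0])  # no previous step

    def test_collinear_points_turn_zero(self):
        steps = build_steps(track_from_points([(0, 0), (0, 10), (0, 20)]))
        assert steps["ta"].iloc[1] == pytest.approx(0.0)
        assert np.cos(np.radians(steps["ta"].iloc[1])) == pytest.approx(1.0)

    def test_north_then_east_turns_ninety(self):
        steps = build_steps(track_from_points([(0, 0), (0, 10), (10, 10)]))
        assert steps["ta"].iloc[1] == pytest.approx(90.0)
        assert np.cos(np.radians(steps["ta"].iloc[1])) == pytest.approx(0.0, abs=1e-12)

    def test_zero_length_step_carries_heading(self):
        steps = build_steps(track_from_points([(0, 0), (0, 10), (0, 10), (0, 20)]))
        assert steps["sl"].iloc[1] == 0.0
        assert steps["zero_length"].iloc[1]
        assert steps["heading"].iloc[1] == steps["heading"].iloc[0]
        assert steps["ta"].iloc[1] == pytest.approx(0.0)


class TestMovementDistributions:
    def test_gamma_parameters_recovered_within_5pct(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"sl": rng.gamma(2.0, 5.0, size=10_000),
                           "ta": np.degrees(rng.vonmises(0.0, 1.5, size=10_000))})
        d = fit_movement_distributions(df)
        assert abs(d.gamma_shape - 2.0) / 2.0 < 0.05
        assert abs(d.gamma_scale - 5.0) / 5.0 < 0.05
        assert abs(d.vm_kappa - 1.5) / 1.5 < 0.05

    def test_uniform_angles_give_near_zero_kappa(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"sl": rng.gamma(2.0, 5.0, size=10_000),
                           "ta": rng.uniform(-180, 180, size=10_000)})
        d = fit_movement_distributions(df)
        assert d.vm_kappa < 0.05

    def test_degenerate_angles_capped_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"sl": rng.gamma(2.0, 5.0, size=100),
                           "ta": np.zeros(100)})
        with pytest.warns(UserWarning, match="capped"):
            d = fit_movement_distributions(df, kappa_max=50.0)
        assert d.vm_kappa == 50.0 and d.capped

    def test_all_equal_step_lengths_rejected(self):
        df = pd.DataFrame({"sl": np.full(50, 3.0), "ta": np.zeros(50)})
        with pytest.raises(EstimationError, match="floor"):
            fit_movement_distributions(df)

    def test_too_few_steps_rejected(self):
        df = pd.DataFrame({"sl": np.arange(10.0) + 1, "ta": np.zeros(10)})
        with pytest.raises(EstimationError):
            fit_movement_distributions(df)


@pytest.fixture(scope="module")
def mid_channel_steps(small_stack):
    """True steps well inside the river, all with a previous heading."""
    pts = [(100 + 3 * i, 20 + (i % 3)) for i in range(12)]
    return build_steps(track_from_points(pts))


class TestCandidateStrata:
    def test_full_stratum_has_eleven_members(self, mid_channel_steps, small_stack):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(mid_channel_steps, dists,
                                           small_stack, seed=5)
        check_stratum_invariants(strata, k=10)
        sizes = strata.groupby("stratum").size()
        assert (sizes == 11).all()
        assert (strata.groupby("stratum")["case"].sum() == 1).all()

    def test_same_seed_reproduces_candidates(self, mid_channel_steps, small_stack):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        a = generate_candidate_strata(mid_channel_steps, dists, small_stack, seed=5)
        b = generate_candidate_strata(mid_channel_steps, dists, small_stack, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_bank_start_with_few_survivors_dropped(self, small_stack):
        # start on the river edge with huge steps: nearly all candidates dry
        edge_y = small_stack.y_max - 1.2
        pts = [(100 + 0.1 * i, edge_y) for i in range(4)]
        steps = build_steps(track_from_points(pts))
        dists = MovementDistributions(100.0, 5.0, 0.0, 0.01)  # ~500 m steps
        audit = []
        strata = generate_candidate_strata(steps, dists, small_stack,
                                           seed=6, audit=audit)
        assert len(strata) == 0
        assert all(a["reason"] == "insufficient_valid_random_steps"
                   for a in audit)

    def test_first_step_without_heading_skipped(self, small_stack):
        steps = build_steps(track_from_points([(100, 20), (103, 20)]))
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(steps, dists, small_stack, seed=7)
        assert len(strata) == 0  # single step has no TA

    def test_random_steps_match_proposal_distributions(self, small_stack):
        # pooled random-step SL/TA should be indistinguishable from the kernel
        pts = [(40 + 0.12 * i, 20 + 0.05 * (i % 7)) for i in range(1100)]
        steps = build_steps(track_from_points(pts))
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.7)
        strata = generate_candidate_strata(steps, dists, small_stack, seed=8)
        rand = strata.loc[~strata["case"]]
        assert len(rand) >= 10_000
        p_sl = sps.kstest(rand["sl"], "gamma", args=(2.0, 0, 1.5)).pvalue
        p_ta = sps.kstest(np.radians(rand["ta"]), "vonmises",
                          args=(0.7, 0.0)).pvalue
        assert p_sl > 0.01 and p_ta > 0.01


class TestAnnotate:
    def test_alignment_cosines(self, small_stack):
        df = pd.DataFrame({
            "stratum": ["s1", "s1"], "case": [True, False],
            "fish_id": "F001", "approach": 1, "segment": 0, "step": [1, 1],
            "t_start": pd.Timestamp("2018-05-10T12:00:00Z"),
            "t_end": pd.Timestamp("2018-05-10T12:00:20Z"),
            "x_start": 100.0, "y_start": 20.0,
            "x_end": [100.0, 100.0], "y_end": [23.0, 17.0],
            "sl": 3.0, "ta": 0.0, "heading": [0.0, 180.0],
            "prev_heading": 0.0,
        })
        out = annotate_covariates(df, small_stack, None, None)
        fd = small_stack.sample("flow_dir", 100.0, 23.0)
        expected = np.cos(np.radians(0.0 - fd))
        assert out["diffvang_end"].iloc[0] == pytest.approx(expected)
        # heading opposed to flow: flow ~90 deg, heading 180 vs 0 flips sign
        h0 = np.cos(np.radians(0.0 - small_stack.sample("flow_dir", 100.0, 17.0)))
        h180 = out["diffvang_end"].iloc[1]
        assert h180 == pytest.approx(
            np.cos(np.radians(180.0 - small_stack.sample("flow_dir", 100.0, 17.0))))
        assert abs(h0 + h180) < 0.2  # near-opposite alignment

    def test_perfect_alignment_and_opposition(self):
        # direct check of the cosine convention
        assert np.cos(np.radians(0.0 - 0.0)) == 1.0
        assert np.cos(np.radians(0.0 - 180.0)) == -1.0

    def test_covariates_at_cell_center_match_grid(self, small_stack, mid_channel_steps):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(mid_channel_steps, dists,
                                           small_stack, seed=9)
        out = annotate_covariates(strata, small_stack, None, None)
        row = out.iloc[3]
        assert row["wv_end"] == small_stack.sample("velocity",
                                                   row["x_end"], row["y_end"])
        assert row["d_start"] == small_stack.sample("depth",
                                                    row["x_start"], row["y_start"])

    def test_temperature_nearest_in_time(self, small_stack, mid_channel_steps):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(mid_channel_steps, dists,
                                           small_stack, seed=10)
        temp = pd.DataFrame({
            "time": pd.to_datetime(["2018-05-10T08:45:00Z",
                                    "2018-05-10T09:00:00Z",
                                    "2018-05-10T09:15:00Z"]),
            "temp_c": [10.0, 11.0, 12.0],
        })
        out = annotate_covariates(strata, small_stack, temp, None)
        # steps start 09:00:00-09:03:40: nearest record is 11.0 throughout
        assert (out["temp"] == 11.0).all()

    def test_stratum_start_columns_constant(self, small_stack, mid_channel_steps):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(mid_channel_steps, dists,
                                           small_stack, seed=11)
        out = annotate_covariates(strata, small_stack, None, None)
        g = out.groupby("stratum")
        for col in ("wv_start", "d_start", "svg_start", "temp", "tod"):
            assert (g[col].nunique(dropna=False) == 1).all()

    def test_cosine_fields_bounded(self, small_stack, mid_channel_steps):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(mid_channel_steps, dists,
                                           small_stack, seed=12)
        out = annotate_covariates(strata, small_stack, None, None)
        for col in ("diffvang_start", "diffvang_end",
                    "diffsvgang_start", "diffsvgang_end", "cos_ta"):
            assert out[col].abs().max() <= 1.0 + 1e-12


class TestStandardize:
    def make_table(self, small_stack, mid_channel_steps, seed=13):
        dists = MovementDistributions(2.0, 1.5, 0.0, 0.5)
        strata = generate_candidate_strata(mid_channel_steps, dists,
                                           small_stack, seed=seed)
        return annotate_covariates(strata, small_stack, None, None)

    def test_mean_value_standardizes_to_zero(self, small_stack, mid_channel_steps):
        table = self.make_table(small_stack, mid_channel_steps)
        out, stz = transform_standardize(table)
        for col in ("wv_end", "d_end", "log_sl"):
            assert out[col + "_z"].mean() == pytest.approx(0.0, abs=1e-10)
            v = stz.stats.loc[col, "mean"]
            z = stz.zscore(col, np.array([v]))
            assert z[0] == pytest.approx(0.0, abs=1e-12)

    def test_log_applied_to_step_length(self, small_stack, mid_channel_steps):
        table = self.make_table(small_stack, mid_channel_steps)
        out, stz = transform_standardize(table)
        i = 4
        expected = (np.log(out["sl"].iloc[i]) - stz.stats.loc["log_sl", "mean"]) \
            / stz.stats.loc["log_sl", "sd"]
        assert out["log_sl_z"].iloc[i] == pytest.approx(expected)

    def test_reapplying_returned_stats_is_identity(self, small_stack,
                                                   mid_channel_steps):
        table = self.make_table(small_stack, mid_channel_steps)
        out1, stz = transform_standardize(table)
        out2, _ = transform_standardize(table, stats_in=stz)
        pd.testing.assert_frame_equal(out1, out2)

    def test_zero_sd_column_raises_with_name(self, small_stack, mid_channel_steps):
        table = self.make_table(small_stack, mid_channel_steps)
        table["temp"] = 12.0
        with pytest.raises(EstimationError, match="temp"):
            transform_standardize(table)
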