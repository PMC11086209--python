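"""Metric-table assembly, synchronization and the tiered correlation screen."""

import math

import numpy as np
import pandas as pd
import pytest

from surgstress.correlation import (
    TABLE_METRICS,
    ManualScores,
    SurgTLX,
    TrialRecord,
    build_metric_table,
    correlation_report,
    pearson_with_p,
    significance_tier,
    synchronize,
)
from surgstress.errors import (
    InsufficientDataError,
    MissingStreamError,
    UndefinedCorrelationError,
)
from surgstress.hrv import RRSeries, per_task_bsi
from surgstress.kinematics import Trajectory, bimanuality_ratios, kinematic_summary
from surgstress.posture import RIGHT_ELBOW, RIGHT_SHOULDER, LandmarkSeries


def line_traj(hand, n=121, step=0.01, hz=10.0, t0=0.0):
    t = t0 + np.arange(n) / hz
    pos = np.column_stack([np.arange(n) * step, np.zeros(n), np.zeros(n)])
    return Trajectory(t, pos, hand=hand)


def ramp_posture(n=121, hz=10.0, t0=0.0, slope=0.02):
    t = t0 + np.arange(n) / hz
    y = slope * np.arange(n) / hz
    return LandmarkSeries(
        t=np.concatenate([t, t]),
        landmark_id=np.concatenate([np.full(n, RIGHT_SHOULDER), np.full(n, RIGHT_ELBOW)]),
        x=np.zeros(2 * n),
        y=np.concatenate([y, 2 * y]),
    )


def hand_built_trial(t0=0.0, dur=12.0):
    rr_pattern = np.tile([800.0, 800.0, 800.0, 850.0], 5)
    t_rr = t0 + np.cumsum(rr_pattern) / 1000.0
    n = int(dur * 10) + 1
    return TrialRecord(
        subject_id="nov01",
        group="novice",
        task_id=1,
        task_window=(t0, t0 + dur),
        rr=RRSeries(t_rr, rr_pattern),
        left=line_traj("left", n=n, step=0.01, t0=t0),
        right=line_traj("right", n=n, step=0.017, t0=t0),
        posture=ramp_posture(n=n, t0=t0),
        tlx=SurgTLX(5, 8, 11, 14, 17, 20),
        manual=ManualScores(1, 2, 8, 1, 0),
    )


class TestSynchronize:
    def test_already_gridded_streams_unchanged(self):
        trial = hand_built_trial()
        sync = synchronize(trial)
        assert np.allclose(sync.left.pos, trial.left.pos[: len(sync.left)])
        assert np.allclose(sync.right.t, trial.right.t[: len(sync.right)])

    def test_half_sample_offset_interpolates_midpoints(self):
        trial = hand_built_trial()
        shifted_left = Trajectory(
            trial.left.t + 0.05, trial.left.pos, hand="left"
        )
        sync = synchronize(
            TrialRecord(**{**trial.__dict__, "left": shifted_left})
        )
        # interior grid points are midpoints of neighbouring samples
        inner = sync.left.pos[1:-1, 0]
        expected = (trial.left.pos[:-1, 0] + trial.left.pos[1:, 0]) / 2.0
        assert np.allclose(inner, expected[: inner.size])

    def test_stream_outside_window_errors(self):
        trial = hand_built_trial()
        early_posture = ramp_posture(t0=-100.0)
        with pytest.raises(MissingStreamError):
            synchronize(TrialRecord(**{**trial.__dict__, "posture": early_posture}))


class TestMetricTable:
    def test_single_trial_row_matches_module_computations(self):
        trial = hand_built_trial()
        table = build_metric_table([trial, hand_built_trial(t0=100.0),
                                    hand_built_trial(t0=200.0)])
        row = table.iloc[0]
        assert row["BSI"] == pytest.approx(
            per_task_bsi(trial.rr, trial.task_window).si
        )
        sync = synchronize(trial)
        left = kinematic_summary(sync.left)
        right = kinematic_summary(sync.right)
        assert row["Lefthand_total_dist"] == pytest.approx(left.total_dist_m)
        assert row["Righthand_std"] == pytest.approx(right.std3d_m)
        assert row["Left_jerk"] == pytest.approx(left.jerk_mps3, abs=1e-9)
        dist_rate, range_rate = bimanuality_ratios(right, left)
        assert row["Total_dist_rate"] == pytest.approx(dist_rate)
        assert row["Range_rate"] == pytest.approx(range_rate)
        assert row["Total_dist_rate"] == pytest.approx(1.7)
        # posture: elbow slope 0.04/s, shoulder 0.02/s
        assert row["Shoulder_vy"] == pytest.approx(0.02, rel=1e-6)
        assert row["Elbow_vy"] == pytest.approx(0.04, rel=1e-6)
        assert row["Physical_fatigue"] == 8 and row["Distractions"] == 20
        assert row["Ring_drops"] == 1

    def test_missing_posture_flags_only_posture(self):
        trials = [hand_built_trial(t0=100.0 * i) for i in range(3)]
        bad = trials[1]
        trials[1] = TrialRecord(
            **{**bad.__dict__, "posture": ramp_posture(t0=-500.0)}
        )
        table = build_metric_table(trials)
        assert np.isnan(table.loc[1, "Elbow_vy"])
        assert np.isnan(table.loc[1, "Shoulder_vy"])
        assert np.isfinite(table.loc[1, "Lefthand_std"])
        assert np.isfinite(table.loc[1, "BSI"])

    def test_degenerate_bsi_flagged_not_zero(self):
        trials = [hand_built_trial(t0=100.0 * i) for i in range(3)]
        const_rr = np.full(20, 800.0)
        trials[2] = TrialRecord(
            **{
                **trials[2].__dict__,
                "rr": RRSeries(200.0 + np.cumsum(const_rr) / 1000.0, const_rr),
            }
        )
        table = build_metric_table(trials)
        assert np.isnan(table.loc[2, "BSI"])

    def test_requires_three_trials(self):
        with pytest.raises(InsufficientDataError):
            build_metric_table([hand_built_trial()])


class TestPearson:
    def test_affine_identity(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and n == 10

    def test_negation(self):
        x = np.arange(10.0)
        assert pearson_with_p(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_direct_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r, p, n = pearson_with_p(x, y)
        # independent oracle: covariance formula + exact t CDF
        xc, yc = x - x.mean(), y - y.mean()
        r_o = float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))
        t_stat = r_o * math.sqrt((n - 2) / (1 - r_o**2))
        from scipy.stats import t as tdist

        p_o = 2.0 * tdist.sf(abs(t_stat), n - 2)
        assert r == pytest.approx(r_o, rel=1e-12)
        assert p == pytest.approx(p_o, rel=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0 = pearson_with_p(x, y)[0]
        assert pearson_with_p(3 * x + 2, 0.5 * y - 1)[0] == pytest.approx(r0)
        assert pearson_with_p(-x, y)[0] == pytest.approx(-r0)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2, np.nan, 4, 5, 6])
        y = np.array([2.0, 4, 6, np.nan, 10, 12])
        r, p, n = pearson_with_p(x, y)
        assert n == 4 and r == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p(np.ones(5), np.arange(5.0))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            pearson_with_p(np.array([1.0, 2]), np.array([3.0, 4]))


class TestTiers:
    @pytest.mark.parametrize(
        "p, tier",
        [
            (0.006, "strong"),
            (0.049999, "strong"),
            (0.05, "weak"),
            (0.061, "weak"),
            (0.08, "weak"),
            (0.081, "none"),
            (0.5, "none"),
        ],
    )
    def test_boundaries(self, p, tier):
        assert significance_tier(p) == tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_tier(1.5)


class TestCorrelationReport:
    def make_table(self, rng, n=40):
        bsi = rng.uniform(20, 400, n)
        table = pd.DataFrame({"BSI": bsi})
        for m in TABLE_METRICS:
            table[m] = rng.normal(size=n)
        return table, bsi

    def test_metric_equal_to_bsi(self, rng):
        table, bsi = self.make_table(rng)
        table["Lefthand_std"] = bsi
        rep = correlation_report(table).set_index("metric")
        row = rep.loc["Lefthand_std"]
        assert row["r"] == pytest.approx(1.0)
        assert row["tier"] == "strong" and row["sign"] == "+"

    def test_negative_limit_case(self, rng):
        table, bsi = self.make_table(rng)
        table["Ring_drops"] = -bsi + rng.normal(0, 1e-9, bsi.size)
        rep = correlation_report(table).set_index("metric")
        assert rep.loc["Ring_drops", "tier"] == "strong"
        assert rep.loc["Ring_drops", "sign"] == "-"

    def test_independent_metric_mostly_untier(self, rng):
        hits = 0
        for _ in range(40):
            table, _ = self.make_table(rng, n=200)
            rep = correlation_report(table).set_index("metric")
            if abs(rep.loc["Complexity", "r"]) < 0.2 and rep.loc[
                "Complexity", "tier"
            ] in ("none", "weak"):
                hits += 1
        assert hits >= 36  # 95%-style bound on clean nulls

    def test_all_flagged_metric_reported_insufficient(self, rng):
        table, _ = self.make_table(rng)
        table["Elbow_vy"] = np.nan
        rep = correlation_report(table).set_index("metric")
        assert rep.loc["Elbow_vy", "tier"] == "insufficient data"

    def test_report_order_and_determinism(self, rng):
        table, _ = self.make_table(rng)
        rep1 = correlation_report(table)
        rep2 = correlation_report(table.copy())
        assert rep1["metric"].tolist() == TABLE_METRICS
        assert rep1.to_csv(index=False) == rep2.to_csv(index=False)
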