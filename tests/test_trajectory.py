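import itertools
import random

import numpy as np
import pytest

from ssp.aaindex import load_default_indices
from ssp.trajectory import (
    DegenerateFitError,
    build_trajectory,
    featurize,
    fit_trend,
    is_eligible,
    predict_site,
    target_position,
)

from conftest import linear_scale, make_path


class TestBuildTrajectory:
    def test_run_length_grouping(self):
        path = make_path(["AALKK"])
        traj = build_trajectory(path, 0)
        assert traj.group_residues == ("A", "L", "K")
        assert traj.n_transitions == 2

    def test_constant_column_single_group(self):
        traj = build_trajectory(make_path(["AAAA"]), 0)
        assert len(traj.groups) == 1
        assert traj.n_transitions == 0

    def test_random_columns_match_rle_oracle(self):
        rng = random.Random(11)
        for _ in range(200):
            col = "".join(rng.choice("AKLV") for _ in range(rng.randint(1, 15)))
            traj = build_trajectory(make_path([col]), 0)
            oracle = tuple(k for k, _ in itertools.groupby(col))
            assert traj.group_residues == oracle
            assert traj.residues == tuple(col)

    def test_gaps_dropped_but_distances_kept(self):
        path = make_path(["A-LK"], edges=[0.1, 0.2, 0.3])
        traj = build_trajectory(path, 0)
        assert traj.residues == ("A", "L", "K")
        assert traj.positions == pytest.approx((0.0, 0.3, 0.6))

    def test_site_out_of_range(self):
        with pytest.raises(IndexError):
            build_trajectory(make_path(["AA"]), 1)


class TestEligibility:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ("AALKK", False),  # 2 transitions: below the threshold
            ("ALKV", True),    # exactly 3: boundary is inclusive
            ("AAAA", False),   # conserved column
            ("ALKV" + "-", False),  # target residue is a gap
        ],
    )
    def test_three_transition_boundary(self, column, expected):
        traj = build_trajectory(make_path([column]), 0)
        assert is_eligible(traj) is expected


class TestFeaturize:
    def test_molecular_weight_order_is_increasing(self, table, mw_scale):
        traj = build_trajectory(make_path(["GAVL"]), 0)
        series = featurize(traj, mw_scale, normalize=False)
        assert (np.diff(series.y) > 0).all()

    def test_one_point_per_group_at_first_node_distance(self, mw_scale):
        traj = build_trajectory(make_path(["AALKK"], edges=[1, 1, 1, 1]), 0)
        series = featurize(traj, mw_scale, normalize=False)
        assert series.x == pytest.approx([0.0, 2.0, 3.0])

    def test_normalisation_divides_x_by_transition_count(self, mw_scale):
        traj = build_trajectory(make_path(["ALKV"], edges=[3, 3, 3]), 0)
        series = featurize(traj, mw_scale, normalize=True)
        assert series.x_divisor == 3
        assert series.x == pytest.approx([0.0, 1.0, 2.0, 3.0])

    def test_recency_weights_rise_from_one_to_two(self, mw_scale):
        traj = build_trajectory(make_path(["ALKV"], edges=[1, 1, 1]), 0)
        series = featurize(traj, mw_scale)
        assert series.weights[0] == pytest.approx(1.0)
        assert series.weights[-1] == pytest.approx(2.0)
        assert np.isfinite(series.weights).all() and (series.weights >= 0).all()

    def test_unknown_residue_group_skipped(self, mw_scale):
        traj = build_trajectory(make_path(["AXLK"]), 0)
        series = featurize(traj, mw_scale, normalize=False)
        assert len(series.y) == 3  # X carries no descriptor value


class TestFitTrend:
    def test_exact_line_recovered(self):
        scale = linear_scale("TEST1", {"A": 1.0, "L": 3.0, "K": 5.0, "V": 7.0})
        traj = build_trajectory(make_path(["ALKV"], edges=[1, 1, 1]), 0)
        for weighting in ("uniform", "linear-recency"):
            series = featurize(traj, scale, normalize=False, weighting=weighting)
            model = fit_trend(series, 1.0, scale, site=0, current_residue="V")
            assert model.slope == pytest.approx(2.0)
            assert model.intercept == pytest.approx(1.0)
            assert model.predicted_value == pytest.approx(9.0)

    def test_constant_series_zero_slope(self, mw_scale):
        # I and L share a molecular weight: two groups, flat descriptor line
        traj = build_trajectory(make_path(["IILL"]), 0)
        series = featurize(traj, mw_scale, normalize=False)
        model = fit_trend(series, 1.0, mw_scale, site=0, current_residue="L")
        assert model.slope == pytest.approx(0.0, abs=1e-9)
        assert model.predicted_residue == "I"  # tie I/L broken alphabetically

    def test_matches_weighted_normal_equations(self):
        rng = random.Random(23)
        scale = linear_scale("TEST2", {"A": 2.0, "L": -1.0, "K": 4.5, "V": 0.5})
        for _ in range(100):
            edges = [rng.uniform(0.1, 2.0) for _ in range(3)]
            traj = build_trajectory(make_path(["ALKV"], edges=edges), 0)
            series = featurize(traj, scale, normalize=False, weighting="linear-recency")
            model = fit_trend(series, 0.5, scale, site=0, current_residue="V")
            # closed-form weighted OLS
            w, x, y = series.weights, series.x, series.y
            xbar = np.sum(w * x) / np.sum(w)
            ybar = np.sum(w * y) / np.sum(w)
            slope = np.sum(w * (x - xbar) * (y - ybar)) / np.sum(w * (x - xbar) ** 2)
            intercept = ybar - slope * xbar
            assert model.slope == pytest.approx(slope, rel=1e-9)
            assert model.intercept == pytest.approx(intercept, rel=1e-9)

    def test_unit_weights_equal_ordinary_least_squares(self):
        scale = linear_scale("TEST3", {"A": 2.0, "L": -1.0, "K": 4.5, "V": 0.5})
        traj = build_trajectory(make_path(["ALKV"], edges=[0.4, 1.1, 0.7]), 0)
        series = featurize(traj, scale, normalize=False, weighting="uniform")
        model = fit_trend(series, 0.1, scale, site=0, current_residue="V")
        slope, intercept = np.polyfit(series.x, series.y, 1)
        assert model.slope == pytest.approx(slope)
        assert model.intercept == pytest.approx(intercept)

    def test_affine_shift_of_scale_shifts_prediction_not_residue(self):
        base = {"A": 1.0, "L": 3.0, "K": 5.0, "V": 7.0}
        scale = linear_scale("TEST4", base)
        shifted = linear_scale(
            "TEST4S", {a: v + 13.0 for a, v in scale.values.items()}
        )
        traj = build_trajectory(make_path(["ALKV"], edges=[1, 1, 1]), 0)
        m1 = fit_trend(
            featurize(traj, scale, normalize=False), 1.0, scale,
            site=0, current_residue="V",
        )
        m2 = fit_trend(
            featurize(traj, shifted, normalize=False), 1.0, shifted,
            site=0, current_residue="V",
        )
        assert m2.predicted_value == pytest.approx(m1.predicted_value + 13.0)
        assert m2.predicted_residue == m1.predicted_residue

    def test_degenerate_identical_positions_rejected(self, mw_scale):
        traj = build_trajectory(make_path(["ALKV"], edges=[0.0, 0.0, 0.0]), 0)
        series = featurize(traj, mw_scale, normalize=False)
        with pytest.raises(DegenerateFitError):
            fit_trend(series, 1.0, mw_scale, site=0, current_residue="V")

    def test_noiseless_planted_slope_recovered_exactly(self):
        # residues placed so descriptor value is exactly a*x + b
        a, b = -4.25, 12.0
        xs = [0.0, 0.8, 1.7, 2.9]
        values = {r: a * x + b for r, x in zip("ALKV", xs)}
        scale = linear_scale("TEST5", values)
        traj = build_trajectory(make_path(["ALKV"], edges=list(np.diff(xs))), 0)
        for weighting in ("uniform", "linear-recency"):
            series = featurize(traj, scale, normalize=False, weighting=weighting)
            model = fit_trend(series, 0.3, scale, site=0, current_residue="V")
            assert model.slope == pytest.approx(a, abs=1e-9)


class TestPredictSite:
    def test_ineligible_site_yields_nothing(self, table):
        assert predict_site(make_path(["AALKK"]), 0, table) == []

    def test_nine_models_on_clean_trajectory(self, table):
        models = predict_site(make_path(["GAVL"]), 0, table)
        assert len(models) == len(table)
        assert {m.accession for m in models} == set(table.accessions)

    def test_planted_weight_trend_predicts_ascending_value(self, table, mw_scale):
        # G<A<V<L in molecular weight: the trend must extrapolate upward
        models = predict_site(make_path(["GAVL"]), 0, table)
        mw_model = next(m for m in models if m.accession == "FASG760101")
        assert mw_model.slope > 0
        assert mw_model.predicted_value > mw_scale["V"]

    def test_self_prediction_flagged(self):
        from ssp.aaindex import AAIndexTable

        scale = linear_scale("TEST6", {"A": 0.0, "L": 1.0, "K": 2.0, "V": 3.0})
        table = AAIndexTable((scale,))
        # step far smaller than group spacing: extrapolation stays on V
        models = predict_site(
            make_path(["ALKV"], edges=[5.0, 5.0, 5.0]), 0, table, normalize=False
        )
        assert models[0].is_self_prediction


class TestTargetPosition:
    def test_ungapped_one_based_numbering(self):
        path = make_path(["MMMM", "A-AA", "KKKK", "-L-L"])  # target row: MAKL
        assert path.aligned_sequences[-1] == "MAKL"
        assert [target_position(path, s) for s in range(4)] == [1, 2, 3, 4]

    def test_gap_in_target_returns_none(self):
        path = make_path(["MMM", "AA-", "KKK"])
        assert target_position(path, 1) is None
        assert target_position(path, 2) == 2
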