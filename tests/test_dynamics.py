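"""Window-capped event counting, track typology, Δ-fragmented series,
trend slopes and chi-squared, with enumeration and closed-form oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from mitodyn.dynamics import (FragmentedSeries, WindowScheme, chi_squared,
                              class_proportions, classify_tracks,
                              delta_fragmented, proportional_difference,
                              trend_slope, window_events)

TRANSITIONS = range(1, 10)  # left frames of a 10-frame recording


def single_track_inputs(event_list):
    """One track holding object 1 at frames 1..10, with the given (t, kind) events."""
    tracks = pd.DataFrame({"frame": range(1, 11), "id": 1, "track_id": 1})
    events = pd.DataFrame(
        [{"transition": t, "kind": kind, "parents": (1,), "children": (1,)}
         for t, kind in event_list],
        columns=["transition", "kind", "parents", "children"],
    )
    return tracks, events


def capped_counting_oracle(event_list, windows=((1, 4), (4, 7), (7, 10))):
    """Independent statement of the cap rule: per window, earliest transition
    wins, fission before fusion at a tie."""
    counted = []
    for a, b in windows:
        in_window = [(t, k) for t, k in event_list if a <= t <= b - 1]
        if in_window:
            in_window.sort(key=lambda e: (e[0], 0 if e[1] == "fission" else 1))
            counted.append(in_window[0][1])
        else:
            counted.append(None)
    return counted


class TestWindowScheme:
    def test_default_partitions_nine_transitions(self):
        scheme = WindowScheme()
        windows = [scheme.window_of_transition(t) for t in TRANSITIONS]
        assert windows == [0, 0, 0, 1, 1, 1, 2, 2, 2]
        assert scheme.window_of_transition(10) is None

    def test_invalid_schemes_rejected(self):
        with pytest.raises(ValueError):
            WindowScheme(((1, 1),))
        with pytest.raises(ValueError):
            WindowScheme(((1, 4), (5, 8)))  # gap between windows


class TestWindowEvents:
    def test_one_event_per_window_totals_three(self):
        tracks, events = single_track_inputs(
            [(2, "fission"), (5, "fusion"), (8, "fission")])
        summary = window_events(tracks, events)
        assert summary.counted_per_track().loc[0, "total"] == 3

    def test_no_events_gives_quiescent_track(self):
        tracks, events = single_track_inputs([])
        classified = classify_tracks(window_events(tracks, events))
        assert classified.loc[0, "track_class"] == "quiescent"

    def test_multiple_events_in_one_window_capped(self):
        tracks, events = single_track_inputs([(1, "fission"), (2, "fission")])
        summary = window_events(tracks, events)
        row = summary.table[(summary.table["track_id"] == 1)
                            & (summary.table["window"] == 0)].iloc[0]
        assert row["counted"] == "fission"
        assert row["raw_fissions"] == 2
        assert summary.counted_per_track().loc[0, "total"] == 1

    def test_cap_rule_matches_enumeration_oracle(self):
        """Every placement of ≤2 events over the 9 transitions × 2 kinds."""
        slots = [(t, k) for t in TRANSITIONS for k in ("fission", "fusion")]
        cases = [[]]
        cases += [[s] for s in slots]
        cases += [list(pair) for pair in itertools.combinations(slots, 2)]
        for event_list in cases:
            tracks, events = single_track_inputs(event_list)
            summary = window_events(tracks, events)
            got = [
                summary.table[(summary.table["track_id"] == 1)
                              & (summary.table["window"] == w)].iloc[0]["counted"]
                for w in range(3)
            ]
            assert got == capped_counting_oracle(event_list), event_list

    def test_counted_events_never_exceed_window_count(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(0, 10)
            event_list = [
                (int(rng.integers(1, 10)),
                 "fission" if rng.random() < 0.5 else "fusion")
                for _ in range(n)
            ]
            tracks, events = single_track_inputs(event_list)
            summary = window_events(tracks, events)
            assert summary.counted_per_track()["total"].max() <= 3

    def test_event_outside_windows_ignored_with_warning(self, caplog):
        tracks, events = single_track_inputs([(2, "fission")])
        scheme = WindowScheme(((1, 4), (4, 7)))
        events.loc[len(events)] = {"transition": 8, "kind": "fusion",
                                   "parents": (1,), "children": (1,)}
        tracks = pd.concat([tracks, pd.DataFrame(
            {"frame": [11], "id": [1], "track_id": [1]})], ignore_index=True)
        with caplog.at_level("WARNING"):
            summary = window_events(tracks, events, scheme)
        assert "outside every window" in caplog.text
        assert summary.counted_per_track().loc[0, "total"] == 1


class TestClassifyTracks:
    @pytest.mark.parametrize("event_list,expected", [
        ([(2, "fission"), (5, "fusion")], "balanced"),
        ([(2, "fission"), (5, "fission")], "fission_dominant"),
        ([(2, "fusion"), (5, "fusion")], "fusion_dominant"),
        ([], "quiescent"),
    ])
    def test_class_assignment(self, event_list, expected):
        tracks, events = single_track_inputs(event_list)
        classified = classify_tracks(window_events(tracks, events))
        assert classified.loc[0, "track_class"] == expected

    def test_tallies_partition_all_tracks(self, noiseless_bundle):
        classified = classify_tracks(
            window_events(noiseless_bundle["tracked"], noiseless_bundle["events"]))
        report = class_proportions(classified)
        assert sum(report["tallies"].values()) == len(classified)
        if report["n_active"]:
            assert sum(report["percentages"].values()) == pytest.approx(100.0)


class TestProportionalDifference:
    def test_symmetry_zero(self):
        assert proportional_difference(5, 5) == 0.0

    def test_arithmetic(self):
        assert proportional_difference(3, 1) == pytest.approx(0.5)

    def test_pure_fusion_is_minus_one(self):
        assert proportional_difference(0, 4) == -1.0

    def test_zero_events_undefined(self):
        with pytest.raises(ValueError):
            proportional_difference(0, 0)

    def test_raw_mode(self):
        assert proportional_difference(3, 1, mode="raw") == 2.0


class TestDeltaFragmented:
    def test_worked_examples(self):
        assert delta_fragmented([1, 2]).delta == (1.0,)
        assert delta_fragmented([2, 1]).delta == (-1.0,)

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=30))
    def test_telescoping(self, counts):
        series = delta_fragmented(counts)
        assert sum(series.delta) == pytest.approx(counts[-1] - counts[0])
        assert len(series.delta) == len(counts) - 1


class TestTrendSlope:
    def test_constant_series_has_zero_slope(self):
        assert trend_slope([3.0] * 8) == pytest.approx(0.0, abs=1e-12)

    def test_linear_series_recovers_slope_exactly(self):
        s = -0.7
        series = s * np.arange(9)
        assert trend_slope(series) == pytest.approx(s)

    def test_per_cell_series_averaged_before_fit(self):
        cells = np.array([[0, 1, 2, 3], [0, 3, 6, 9]], dtype=float)
        assert trend_slope(cells) == pytest.approx(2.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            trend_slope([1.0])

    @pytest.mark.parametrize("fis,fus,sign", [(0.06, 0.01, 1), (0.01, 0.06, -1)])
    def test_sign_recovery_under_biased_dynamics(self, fis, fus, sign):
        """Scenes with a fragment pool straddling the volume threshold: net
        fission grows the fragmented-count series, net fusion shrinks it."""
        from mitodyn.synthetic import SceneConfig, generate_scene

        slopes = []
        for seed in range(20):
            truth = generate_scene(SceneConfig(
                n_objects=60, n_frames=10,
                semiaxes_um=(0.28, 0.23, 0.18), semiaxes_cv=0.2,
                fission_prob=fis, fusion_prob=fus,
                seed=seed + (0 if sign > 0 else 500),
            ))
            slopes.append(trend_slope(truth.fragmented_counts()))
        assert np.sign(np.mean(slopes)) == sign


def pearson_oracle(table):
    """Closed-form Pearson statistic from margins, independent of scipy's
    contingency machinery."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = ((table - expected) ** 2 / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df, chi2_dist.sf(stat, df)


class TestChiSquared:
    def test_proportional_rows_give_zero_statistic(self):
        res = chi_squared([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_uniform_table_zero(self):
        assert chi_squared([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)

    def test_matches_closed_form_oracle_on_tem_table(self):
        table = [[35, 27, 115], [7, 1, 121]]
        res = chi_squared(table)
        stat, df, p = pearson_oracle(table)
        assert res.statistic == pytest.approx(stat)
        assert res.df == df == 2
        assert res.p_value == pytest.approx(p)
        assert res.p_value < 0.001

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 50, size=(rng.integers(2, 4), rng.integers(2, 4)))
        res = chi_squared(table)
        stat, df, p = pearson_oracle(table)
        assert res.statistic == pytest.approx(stat)
        assert res.p_value == pytest.approx(p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared([[0, 5], [0, 7]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            chi_squared([[1, -2], [3, 4]])
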