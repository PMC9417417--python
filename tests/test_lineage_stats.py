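import math

import numpy as np
import pytest
from scipy import stats as sps

from lineagedyn.compartments import StateLabeling
from lineagedyn.errors import NotApplicableError
from lineagedyn.lineage_stats import (
    conversion_fraction,
    g1_metrics,
    g1_table,
    prospective_fate_comparison,
    residence_times,
    survival_table,
    transition_matrix,
    transitions_per_day,
)
from lineagedyn.synthetic_data import (
    DifferentiationConfig,
    ForestSimConfig,
    StateParams,
    nacl_like_config,
    simulate_differentiation_forest,
    simulate_forest,
)
from lineagedyn.tracks_io import LineageForest, division_time, prune_incomplete

from conftest import make_track


def cohort_forest(groups, cycle_h: float = 16.0, dt: float = 1.0):
    """Forest + labeling with exact per-(state, day) survivor/death counts.

    ``groups`` maps (state, day) -> (n_survive, n_die). Cohort cells are
    generation-1 daughters of divided roots, so they survive pruning; divided
    cohort cells get a censored child each.
    """
    tracks = {}
    labels = {}
    idx = 0
    for (state, day), (n_survive, n_die) in groups.items():
        cells = ["s"] * n_survive + ["d"] * n_die
        birth0 = (day - 1) * 24.0
        for i in range(0, len(cells), 2):
            root = f"r{idx}"
            tracks[root] = make_track(root, None, birth0 - cycle_h - dt, birth0 - dt,
                                      "divided", dt=dt)
            for kind in cells[i:i + 2]:
                cid = f"c{idx}"
                idx += 1
                fate = "divided" if kind == "s" else "died"
                tracks[cid] = make_track(cid, root, birth0, birth0 + cycle_h, fate, dt=dt)
                labels[cid] = state
                if fate == "divided":
                    kid = f"k{cid}"
                    tracks[kid] = make_track(kid, cid, birth0 + cycle_h + dt,
                                             birth0 + 2 * cycle_h, "censored", dt=dt)
            idx += 1
    forest = LineageForest(tracks, check_divided_children=False)
    return prune_incomplete(forest), StateLabeling(labels=labels, method="kmeans")


def manual_labeling(mapping, method="quartile"):
    return StateLabeling(labels=dict(mapping), method=method)


class TestSurvivalTable:
    def test_printed_ratio_small_group(self):
        forest, lab = cohort_forest({("PrE", 2): (5, 1)})
        row = survival_table(forest, lab, by_day=True).iloc[0]
        assert row["n_survive"] == 5 and row["n_die"] == 1
        assert round(row["survival_rate"], 2) == 0.83
        assert round(row["death_rate"], 2) == 0.17

    def test_printed_ratio_large_group(self):
        forest, lab = cohort_forest({("High", 1): (127, 12)})
        row = survival_table(forest, lab).iloc[0]
        assert round(row["survival_rate"], 2) == 0.91

    def test_zero_deaths(self):
        forest, lab = cohort_forest({("Mid", 1): (10, 0)})
        row = survival_table(forest, lab).iloc[0]
        assert row["survival_rate"] == 1.0 and row["death_rate"] == 0.0

    def test_rates_sum_to_one_exactly(self):
        forest, lab = cohort_forest(
            {("High", 1): (13, 7), ("Low", 2): (4, 9), ("Mid", 3): (21, 2)}
        )
        df = survival_table(forest, lab, by_day=True)
        assert len(df) == 3
        for _, row in df.iterrows():
            assert row["survival_rate"] + row["death_rate"] == 1.0
            assert row["n_survive"] + row["n_die"] == row["n_total"]

    def test_day_binning(self):
        forest, lab = cohort_forest({("PrE", 2): (3, 1), ("PrE", 4): (6, 2)})
        df = survival_table(forest, lab, by_day=True).set_index("day")
        assert df.loc[2, "n_total"] == 4
        assert df.loc[4, "n_total"] == 8


class TestTransitionMatrix:
    def _two_daughter_forest(self):
        dt = 1.0
        tracks = {
            "M": make_track("M", None, 0.0, 16.0, "divided", dt=dt),
            "A": make_track("A", "M", 17.0, 33.0, "divided", dt=dt),
            "B": make_track("B", "M", 17.0, 33.0, "divided", dt=dt),
        }
        return LineageForest(tracks, check_divided_children=False)

    def test_identity_when_no_switches(self):
        forest = self._two_daughter_forest()
        lab = manual_labeling({"M": "Mid", "A": "Mid", "B": "Mid"})
        probs = transition_matrix(forest, lab).probabilities
        assert probs.loc["Mid", "Mid"] == 1.0

    def test_half_half_split(self):
        forest = self._two_daughter_forest()
        lab = manual_labeling({"M": "Mid", "A": "High", "B": "Mid"})
        probs = transition_matrix(forest, lab).probabilities
        assert probs.loc["Mid", "High"] == 0.5
        assert probs.loc["Mid", "Mid"] == 0.5
        assert probs.loc["Mid", "Low"] == 0.0

    def test_rows_sum_to_one(self, nacl_forest_with_states):
        forest, states = nacl_forest_with_states
        pruned = prune_incomplete(forest)
        lab = manual_labeling({c: states[c] for c in pruned.tracks})
        probs = transition_matrix(pruned, lab).probabilities
        sums = probs.sum(axis=1)
        for s in probs.index:
            assert sums[s] == pytest.approx(1.0)

    def test_generative_probability_in_binomial_ci(self, nacl_forest_with_states):
        forest, states = nacl_forest_with_states
        pruned = prune_incomplete(forest)
        lab = manual_labeling({c: states[c] for c in pruned.tracks})
        # restrict to daughters born well before the movie end: slow-cycling
        # daughters are preferentially censored near the boundary, which
        # biases observed transition proportions
        margin = 115 - 45
        n = k = 0
        for cid, tr in pruned.tracks.items():
            parent = tr.parent_id
            if parent is None or parent not in lab or tr.birth_time >= margin:
                continue
            if lab[parent] == "Mid":
                n += 1
                k += lab[cid] == "High"
        lo, hi = sps.binomtest(k, n).proportion_ci(confidence_level=0.95)
        assert lo <= 0.18 <= hi  # generative Mid -> High probability


class TestTransitionsPerDay:
    def _uniform_cycle_forest(self, cycle_h):
        dt = 1.0
        tracks = {}
        lab = {}
        rng = np.random.default_rng(0)
        for i in range(30):
            m = f"m{i}"
            tracks[m] = make_track(m, None, 0.0, cycle_h, "divided", dt=dt)
            lab[m] = "Mid"
            for j in range(2):
                c = f"c{i}_{j}"
                tracks[c] = make_track(c, m, cycle_h + dt, 2 * cycle_h, "divided", dt=dt)
                lab[c] = "High" if rng.random() < 0.25 else "Mid"
        forest = LineageForest(tracks, check_divided_children=False)
        return forest, manual_labeling(lab)

    def test_24h_cycles_equal_per_generation(self):
        forest, lab = self._uniform_cycle_forest(24.0)
        res = transitions_per_day(forest, lab)
        for s in ("High", "Mid", "Low"):
            a = res.probabilities.loc["Mid", s]
            b = res.per24h.loc["Mid", s]
            assert b == pytest.approx(a)

    def test_12h_cycles_double_the_rate(self):
        forest, lab = self._uniform_cycle_forest(12.0)
        res = transitions_per_day(forest, lab)
        for s in ("High", "Mid", "Low"):
            assert res.per24h.loc["Mid", s] == pytest.approx(
                2 * res.probabilities.loc["Mid", s]
            )

    def test_window_counting_oracle(self):
        # near-constant cycles: compare against counting switch events in
        # consecutive 24-h windows (windows weighted by their event counts,
        # since the population grows exponentially across the movie)
        cfg = ForestSimConfig(
            states={
                "A": StateParams(16.0, 0.3, 0.02, 0.12, 0.01),
                "B": StateParams(16.0, 0.3, 0.02, 0.18, 0.01),
            },
            transition={"A": {"A": 0.8, "B": 0.2}, "B": {"A": 0.2, "B": 0.8}},
            n_roots=25,
            duration_h=120,
            frame_interval_h=1.0,
            seed=21,
        )
        states = {}
        forest = prune_incomplete(simulate_forest(cfg, true_states_out=states))
        lab = manual_labeling({c: states[c] for c in forest.tracks})
        res = transitions_per_day(forest, lab)

        num = den = 0.0
        for w0 in np.arange(0.0, 120 - 24 + 1, 24.0):
            obs = []
            for cid, tr in forest.tracks.items():
                parent = tr.parent_id
                if parent is None or parent not in forest.tracks:
                    continue
                if not (w0 <= tr.birth_time < w0 + 24):
                    continue
                if lab[parent] != "A":
                    continue
                obs.append(
                    (lab[cid] == "B", division_time(forest.tracks[parent]))
                )
            if not obs:
                continue
            frac = np.mean([o[0] for o in obs])
            mean_cycle = np.mean([o[1] for o in obs])
            num += frac * 24.0 / mean_cycle * len(obs)
            den += len(obs)
        oracle = num / den
        assert abs(res.per24h.loc["A", "B"] - oracle) < 0.02


class TestResidenceTimes:
    def _labeled_chain(self, states_seq, cycles):
        dt = 0.1
        tracks = {}
        lab = {}
        birth = 0.0
        parent = None
        for i, (s, cyc) in enumerate(zip(states_seq, cycles)):
            cid = f"n{i}"
            tracks[cid] = make_track(cid, parent, birth, birth + cyc, "divided", dt=dt)
            lab[cid] = s
            parent = cid
            birth += cyc + dt
        forest = LineageForest(tracks, check_divided_children=False)
        return forest, manual_labeling(lab)

    def test_two_generation_run(self):
        forest, lab = self._labeled_chain(["High", "High", "Low"], [17.0, 18.0, 16.0])
        df = residence_times(forest, lab).set_index("state")
        assert df.loc["High", "n_runs"] == 1
        assert df.loc["High", "residence_generations_mean"] == 2.0
        assert df.loc["High", "residence_hours_mean"] == pytest.approx(35.0)

    def test_run_hours_sum_division_times(self):
        forest, lab = self._labeled_chain(["High", "High", "Low"], [17.3, 18.0, 16.0])
        df = residence_times(forest, lab).set_index("state")
        assert df.loc["High", "residence_hours_mean"] == pytest.approx(35.3)

    def test_geometric_mean_run_length(self):
        cfg = ForestSimConfig(
            states={
                "A": StateParams(14.0, 2.0, 0.02, 0.12, 0.01),
                "B": StateParams(14.0, 2.0, 0.02, 0.18, 0.01),
            },
            transition={"A": {"A": 0.5, "B": 0.5}, "B": {"A": 0.5, "B": 0.5}},
            n_roots=10,
            duration_h=120,
            frame_interval_h=1.0,
            seed=9,
        )
        states = {}
        forest = prune_incomplete(simulate_forest(cfg, true_states_out=states))
        lab = manual_labeling({c: states[c] for c in forest.tracks})
        df = residence_times(forest, lab).set_index("state")
        # per-generation exit probability q = 0.5 -> mean run length ~ 1/q = 2
        for s in ("A", "B"):
            assert abs(df.loc[s, "residence_generations_mean"] - 2.0) < 0.3


class TestConversionFraction:
    def _conversion_forest(self, n_pre_window, n_converted, birth):
        dt = 1.0
        tracks = {}
        lab = {}
        idx = 0
        for i in range(math.ceil(n_pre_window / 2)):
            m = f"m{i}"
            tracks[m] = make_track(m, None, birth - 17.0, birth - dt, "divided", dt=dt)
            lab[m] = "NEDiff"
            for j in range(min(2, n_pre_window - 2 * i)):
                c = f"c{idx}"
                tracks[c] = make_track(c, m, birth, birth + 16.0, "divided", dt=dt)
                lab[c] = "PrE" if idx < n_converted else "NEDiff"
                idx += 1
        forest = LineageForest(tracks, check_divided_children=False)
        return forest, manual_labeling(lab, method="kmeans")

    def test_simple_fraction(self):
        forest, lab = self._conversion_forest(16, 2, birth=30.0)
        res = conversion_fraction(forest, lab, n_boot=50, seed=0)
        assert res["pre_fraction"] == pytest.approx(2 / 16)
        assert res["pre_n"] == 16

    def test_no_converters(self):
        forest, lab = self._conversion_forest(10, 0, birth=30.0)
        res = conversion_fraction(forest, lab, n_boot=50, seed=0)
        assert res["pre_fraction"] == 0.0

    def test_generative_rates_recovered(self):
        states = {}
        forest = simulate_differentiation_forest(
            DifferentiationConfig(seed=3, n_roots=40, duration_h=120,
                                  conv_pre=0.12, conv_post=0.02,
                                  frame_interval_h=1.0),
            true_states_out=states,
        )
        pruned = prune_incomplete(forest)
        lab = manual_labeling({c: states[c] for c in pruned.tracks}, method="kmeans")
        res = conversion_fraction(pruned, lab, n_boot=400, seed=1)
        assert abs(res["pre_fraction"] - 0.12) < 3 * res["pre_sd"] + 0.01
        assert abs(res["post_fraction"] - 0.02) < 3 * res["post_sd"] + 0.01


class TestProspectiveFate:
    def _fate_forest(self, n_per_group, shift, seed=0):
        rng = np.random.default_rng(seed)
        dt = 1.0
        tracks = {}
        lab = {}
        for i in range(2 * n_per_group):
            primed = i < n_per_group
            m = f"m{i}"
            intensity = float(rng.normal(0.15 + (shift if primed else 0.0), 0.02))
            root = f"r{i}"
            tracks[root] = make_track(root, None, 10.0, 29.0, "divided", dt=dt)
            tracks[m] = make_track(m, root, 30.0, 46.0, "divided",
                                   intensity=intensity, dt=dt)
            lab[m] = "NEDiff"
            kid = f"k{i}"
            tracks[kid] = make_track(kid, m, 49.0, 62.0, "divided", dt=dt)
            lab[kid] = "PrE" if primed else "NEDiff"
        forest = LineageForest(tracks, check_divided_children=False)
        return prune_incomplete(forest), manual_labeling(lab, method="kmeans")

    def test_shift_detected(self):
        forest, lab = self._fate_forest(25, shift=0.03)
        res = prospective_fate_comparison(forest, lab, at_day=2)
        assert res["PrE_fate_n"] >= 20 and res["NEDiff_fate_n"] >= 20
        assert res["p_value"] < 0.05
        assert res["PrE_fate_median"] > res["NEDiff_fate_median"]

    def test_single_group_no_test(self):
        forest, lab = self._fate_forest(10, shift=0.0)
        # force everyone to have a differentiated descendant
        all_pre = {c: ("PrE" if s == "PrE" or c.startswith("k") else s)
                   for c, s in lab.labels.items()}
        lab2 = manual_labeling(all_pre, method="kmeans")
        res = prospective_fate_comparison(forest, lab2, at_day=2)
        assert res["NEDiff_fate_n"] == 0
        assert math.isnan(res["p_value"])

    def test_summary_fixture_counts_and_medians(self):
        # formatting fixture shaped like the printed parental-cell table
        forest, lab = self._fate_forest(1, shift=0.0)
        rng = np.random.default_rng(5)
        groups = {
            "PrE_fate": 0.18 + rng.normal(0, 1e-4, 20),
            "NEDiff_fate": 0.15 + rng.normal(0, 1e-4, 151),
        }
        # build a forest realizing those intensities
        dt = 1.0
        tracks, labels = {}, {}
        i = 0
        for gname, vals in groups.items():
            for v in vals:
                root, m, kid = f"r{i}", f"m{i}", f"k{i}"
                tracks[root] = make_track(root, None, 10.0, 29.0, "divided", dt=dt)
                tracks[m] = make_track(m, root, 30.0, 46.0, "divided",
                                       intensity=float(v), dt=dt)
                tracks[kid] = make_track(kid, m, 49.0, 62.0, "divided", dt=dt)
                labels[m] = "NEDiff"
                labels[kid] = "PrE" if gname == "PrE_fate" else "NEDiff"
                i += 1
        forest = prune_incomplete(LineageForest(tracks, check_divided_children=False))
        res = prospective_fate_comparison(
            forest, manual_labeling(labels, method="kmeans"), at_day=2
        )
        assert res["PrE_fate_n"] == 20
        assert res["NEDiff_fate_n"] == 151
        assert res["PrE_fate_median"] == pytest.approx(0.18, abs=1e-3)
        assert res["NEDiff_fate_median"] == pytest.approx(0.15, abs=1e-3)


class TestG1Metrics:
    def _phase_track(self, g1_h, cycle_h, dt=1.0 / 3.0, start_high=True):
        n = int(round(cycle_h / dt)) + 1
        times = [i * dt for i in range(n)]
        phase = [1.0 if (t <= g1_h) == start_high else
                 (0.0 if start_high else 1.0) for t in times]
        if not start_high:
            phase = [0.0] * n
            phase[-1] = 1.0  # some dynamic range for normalization
        return make_track("g", None, 0.0, cycle_h, "divided", dt=dt,
                          phase=phase)

    def test_ratio_division(self):
        dt = 1.0 / 3.0
        tr = self._phase_track(g1_h=7.3, cycle_h=18.0, dt=dt)
        m = g1_metrics(tr)
        assert m.division_time == pytest.approx(18.0)
        assert m.g1_length == pytest.approx(7.3, abs=dt + 1e-9)
        assert m.g1_ratio == pytest.approx(7.3 / 18.0, abs=0.03)

    def test_below_threshold_at_birth_flagged(self):
        tr = self._phase_track(g1_h=0.0, cycle_h=10.0, start_high=False)
        m = g1_metrics(tr)
        assert m.short_g1_flag
        assert m.g1_length == pytest.approx(1.0 / 3.0)

    def test_requires_phase_trace(self):
        tr = make_track("x", None, 0.0, 10.0, "divided")
        with pytest.raises(NotApplicableError):
            g1_metrics(tr)

    def test_ratio_bounds_on_simulation(self):
        forest = simulate_forest(
            nacl_like_config(seed=13, n_roots=6, duration_h=90, include_phase=True)
        )
        df = g1_table(prune_incomplete(forest))
        assert len(df) > 30
        assert ((df["g1_ratio"] > 0) & (df["g1_ratio"] <= 1)).all()

    def test_generative_g1_median_recovered(self):
        cfg = ForestSimConfig(
            states={"S": StateParams(15.0, 2.0, 0.02, 0.15, 0.01,
                                     g1_fraction_mean=0.2, g1_fraction_sd=0.0)},
            transition={"S": {"S": 1.0}},
            n_roots=8,
            duration_h=100,
            include_phase=True,
            seed=17,
        )
        forest = prune_incomplete(simulate_forest(cfg))
        df = g1_table(forest)
        # G1 = 0.2 of a ~15 h cycle -> median ~3.0 h, recovered within 1 frame
        med = df["g1_length"].median()
        assert abs(med - 0.2 * df["division_time"].median()) <= 2 * (1 / 3) + 1e-9
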