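import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import murinecg as m


def exact_mw_p(a, b):
    """Independent oracle: two-sided p by full enumeration of rank splits."""
    a, b = list(a), list(b)
    pooled = a + b
    n, na = len(pooled), len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}  # tie-free only

    def u_of(idx):
        ra = sum(ranks[pooled[i]] for i in idx)
        return ra - na * (na + 1) / 2

    u_obs = u_of(range(na))
    m_ = na * (len(b))
    dev = min(u_obs, m_ - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        u = u_of(idx)
        if min(u, m_ - u) <= dev + 1e-9:
            count += 1
        total += 1
    return count / total


def events_frame(times):
    return pd.DataFrame(
        {"animal_id": "a1", "etype": "vpb_isolated", "onset_time_s": times, "n_vpb": 1}
    )


class TestWindowAssignment:
    def test_boundary_goes_to_later_window(self):
        tagged = m.assign_windows(events_frame([900.0]))
        assert tagged["window"].iloc[0] == "15-45min"

    def test_event_after_12h_excluded(self):
        assert len(m.assign_windows(events_frame([13 * 3600.0]))) == 0

    def test_pre_intervention_event_warns_and_drops(self):
        with pytest.warns(UserWarning):
            tagged = m.assign_windows(events_frame([-5.0, 10.0]))
        assert len(tagged) == 1

    def test_intervention_offset_shifts_windows(self):
        tagged = m.assign_windows(events_frame([1000.0]), intervention_time_s=500.0)
        assert tagged["window"].iloc[0] == "0-15min"

    def test_overlapping_scheme_rejected(self):
        with pytest.raises(ValueError):
            m.WindowScheme(windows=(("a", 0.0, 100.0), ("b", 50.0, 200.0)))

    @given(st.lists(st.floats(min_value=0.0, max_value=50_000.0), min_size=1, max_size=60))
    @settings(max_examples=100, derandomize=True)
    def test_subwindow_counts_sum_to_union(self, times):
        tagged = m.assign_windows(events_frame(times))
        animals = pd.DataFrame({"animal_id": ["a1"], "group": ["URI"]})
        ct = m.build_count_table(tagged, animals)
        assert ct.check_additivity()
        d = ct.data
        in_union = sum(0.0 <= t < 43200.0 for t in times)
        got = d.loc[(d["window"] == "0-12h") & (d["etype"] == "vpb_isolated"), "count"]
        assert int(got.iloc[0]) == in_union


class TestCountTable:
    def make_table(self, seed=0, n_per_group=(4, 3)):
        rng = np.random.default_rng(seed)
        animals = pd.DataFrame(
            {"animal_id": [f"u{i}" for i in range(n_per_group[0])]
             + [f"m{i}" for i in range(n_per_group[1])],
             "group": ["URI"] * n_per_group[0] + ["MIC"] * n_per_group[1]}
        )
        ev = pd.DataFrame(
            {"animal_id": rng.choice(animals["animal_id"], 300),
             "etype": rng.choice(["vpb_isolated", "bigeminy", "trigeminy", "salvo", "vt"], 300),
             "onset_time_s": rng.uniform(0, 43200, 300),
             "n_vpb": rng.integers(1, 6, 300)}
        )
        return m.build_count_table(m.assign_windows(ev), animals)

    def test_union_means_are_sums_of_subwindow_means(self):
        ct = self.make_table()
        s = ct.group_summary()
        for (g, e), sub in s.groupby(["group", "etype"]):
            union = sub.loc[sub["window"] == "0-12h", "mean"].iloc[0]
            parts = sub.loc[sub["window"] != "0-12h", "mean"].sum()
            assert union == pytest.approx(parts)

    def test_single_animal_group_flagged_sd_zero(self):
        animals = pd.DataFrame({"animal_id": ["x"], "group": ["SRI"]})
        ev = events_frame([100.0]).assign(animal_id="x")
        ct = m.build_count_table(m.assign_windows(ev), animals)
        s = ct.group_summary()
        assert s["single_animal"].all()
        assert (s["sd"] == 0).all()

    def test_generator_means_recovered_within_standard_error(self):
        df = m.simulate_count_table({"g": {"0-12h/vpb": 5.0}}, {"g": 10_000},
                                    dispersion=1.0, seed=3)
        se = np.sqrt((5.0 + 25.0) / 10_000)
        assert abs(df["count"].mean() - 5.0) < 3 * se

    def test_bg_tg_merged(self):
        ct = self.make_table()
        assert set(ct.data["etype"]) == {"vpb_isolated", "bg_tg", "salvo", "vt"}


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        c = m.mann_whitney([1, 2, 3], [4, 5, 6])
        assert c.u_statistic == 0.0
        assert c.p_value == pytest.approx(0.1, abs=1e-12)
        assert c.method == "exact"

    def test_identical_samples_p_is_one(self):
        assert m.mann_whitney([1, 2, 3], [1, 2, 3]).p_value == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            na = int(rng.integers(2, 6))
            nb = int(rng.integers(2, 10 - na + 1))
            pooled = rng.choice(np.arange(100), size=na + nb, replace=False)
            a, b = pooled[:na], pooled[na:]
            c = m.mann_whitney(a, b)
            assert c.method == "exact"
            assert c.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-9)

    def test_u_plus_u_prime_is_nanb(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            u_ab = m.mann_whitney(a, b).u_statistic
            u_ba = m.mann_whitney(b, a).u_statistic
            assert u_ab + u_ba == pytest.approx(len(a) * len(b))
            assert 0 <= u_ab <= len(a) * len(b)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            m.mann_whitney([1.0], [2.0, 3.0])


class TestCompareAll:
    def test_row_count_covers_all_cells_and_pairs(self):
        rng = np.random.default_rng(9)
        animals = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(9)],
             "group": ["URI"] * 3 + ["SRI"] * 3 + ["MIC"] * 3}
        )
        ev = pd.DataFrame(
            {"animal_id": rng.choice(animals["animal_id"], 400),
             "etype": rng.choice(["vpb_isolated", "salvo", "vt", "bigeminy"], 400),
             "onset_time_s": rng.uniform(0, 43200, 400),
             "n_vpb": 1}
        )
        ct = m.build_count_table(m.assign_windows(ev), animals)
        res = m.compare_all(ct)
        assert len(res) == 4 * 4 * 1 * 3  # etypes x windows x interventions x pairs

    def test_identical_groups_never_significant(self):
        animals = pd.DataFrame(
            {"animal_id": [f"a{i}" for i in range(6)],
             "group": ["URI"] * 3 + ["MIC"] * 3}
        )
        ev = pd.DataFrame(
            {"animal_id": list(animals["animal_id"]) * 2,
             "etype": "vpb_isolated",
             "onset_time_s": 100.0,
             "n_vpb": 1}
        )
        ct = m.build_count_table(m.assign_windows(ev), animals)
        res = m.compare_all(ct, groups=("URI", "MIC"))
        assert not res["significant"].any()

    def test_holm_adjustment_is_monotone_and_conservative(self):
        df = pd.DataFrame({"p_value": [0.001, 0.01, 0.02, 0.04, 0.5]})
        out = m.holm_adjust(df)
        assert (out["p_holm"] >= out["p_value"] - 1e-12).all()
        assert out.sort_values("p_value")["p_holm"].is_monotonic_increasing
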