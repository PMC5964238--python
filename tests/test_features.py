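"""The thirteen measures against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from casig.features import (Baseline, compute_baseline, compute_calcium_measures,
                            compute_motility_measures, compute_prepost_ratios,
                            features_table, filter_tracks, match_controls,
                            MEASURE_COLUMNS)

from conftest import make_track


# ---------------------------------------------------------------- oracles
def oracle_trapezoid_auc(t, r, baseline):
    """Hand trapezoid of max(r - baseline, 0) over t, per second."""
    total = 0.0
    e = [max(v - baseline, 0.0) for v in r]
    for i in range(len(t) - 1):
        total += 0.5 * (e[i] + e[i + 1]) * (t[i + 1] - t[i])
    return total / (t[-1] - t[0])


def oracle_r2b(r, baseline, band=0.20):
    """Count downward crossings from above to at-or-below the band by loop."""
    level = (1 + band) * baseline
    count = 0
    for i in range(len(r) - 1):
        if r[i] > level and r[i + 1] <= level:
            count += 1
    return count


def oracle_motility(t, x, y, ratio, threshold_um_min=2.0):
    steps = [np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) for i in range(len(x) - 1)]
    speeds = [s / (t[i + 1] - t[i]) * 60 for i, s in enumerate(steps)]
    length = sum(steps)
    euclid = np.hypot(x[-1] - x[0], y[-1] - y[0])
    i_max = min(range(len(ratio)), key=lambda i: (-ratio[i], i))
    return {
        "mobile_fraction": np.mean([s > threshold_um_min for s in speeds]),
        "track_length_um": length,
        "euclidean_um": euclid,
        "meandering_index": euclid / length if length > 0 else 1.0,
        "speed_um_s": length / (t[-1] - t[0]),
        "pct_track_length_at_max": 100 * sum(steps[:i_max]) / length if length else 0.0,
    }


def oracle_prepost(t, x, y, ratio):
    i = min(range(len(ratio)), key=lambda j: (-ratio[j], j))
    if i == 0 or i == len(t) - 1:
        return None

    def seg(ts, xs, ys):
        steps = [np.hypot(xs[k + 1] - xs[k], ys[k + 1] - ys[k])
                 for k in range(len(xs) - 1)]
        L = sum(steps)
        E = np.hypot(xs[-1] - xs[0], ys[-1] - ys[0])
        dur = ts[-1] - ts[0]
        return L, L / dur if dur else 0.0, (E / L if L else 1.0), E

    pre = seg(t[:i + 1], x[:i + 1], y[:i + 1])
    post = seg(t[i:], x[i:], y[i:])
    return {k: (a / b if b > 0 else np.nan)
            for k, a, b in zip(("length_ratio", "speed_ratio", "mi_ratio",
                                "euclid_ratio"), pre, post)}


# ------------------------------------------------------------- filtering
def test_duration_filter_boundaries():
    long_track = make_track(np.arange(121) * 10.0, np.zeros(121), np.zeros(121),
                            np.ones(121), track_id=0)
    short_track = make_track(np.arange(20) * 10.0, np.zeros(20), np.zeros(20),
                             np.ones(20), track_id=1)
    exact = make_track(np.arange(31) * 10.0, np.zeros(31), np.zeros(31),
                       np.ones(31), track_id=2)
    tracks = pd.concat([long_track, short_track, exact], ignore_index=True)
    kept, excluded = filter_tracks(tracks)
    assert sorted(kept["track_id"].unique()) == [0, 2]  # 300 s boundary kept
    assert sorted(excluded["track_id"].unique()) == [1]


# -------------------------------------------------------------- baseline
def test_baseline_constant_tracks():
    tracks = pd.concat(
        [make_track([0, 10, 20], [0] * 3, [0] * 3, [0.80] * 3, track_id=i)
         for i in range(10)]
        + [make_track([0, 10, 20], [0] * 3, [0] * 3, [0.5, 1.5, 2.5], track_id=10 + i)
           for i in range(2)],
        ignore_index=True)
    b = compute_baseline(tracks)
    assert b.value == pytest.approx(0.80)
    assert b.n_tracks_used == 10


def test_baseline_pooled_median_of_four_constant_tracks():
    tracks = pd.concat(
        [make_track([0, 10], [0, 0], [0, 0], [v, v], track_id=i)
         for i, v in enumerate([0.7, 0.8, 0.9, 1.0])], ignore_index=True)
    assert compute_baseline(tracks).value == pytest.approx(0.85)


def test_baseline_matches_bruteforce_on_random_tracks(rng):
    tracks = pd.concat(
        [make_track(np.arange(5) * 10.0, np.zeros(5), np.zeros(5),
                    rng.uniform(0.5, 2.5, 5), track_id=i) for i in range(15)],
        ignore_index=True)
    got = compute_baseline(tracks)
    # brute force: sort by range, take 10, pool samples, median
    ranges = {tid: g["ratio"].max() - g["ratio"].min()
              for tid, g in tracks.groupby("track_id")}
    chosen = sorted(ranges, key=lambda k: (ranges[k], k))[:10]
    pooled = np.concatenate([tracks.loc[tracks.track_id == tid, "ratio"].to_numpy()
                             for tid in chosen])
    assert got.value == pytest.approx(np.median(pooled), rel=1e-12)


def test_empty_baseline_rejected():
    with pytest.raises(ValueError):
        compute_baseline(pd.DataFrame(columns=["track_id", "frame", "ratio"]))


# ------------------------------------------------------- calcium measures
def test_constant_trace_calcium_measures():
    tr = make_track(np.arange(5) * 10.0, np.zeros(5), np.zeros(5), [0.8] * 5)
    m = compute_calcium_measures(tr, baseline=0.8)
    assert m["auc_ratio"] == 0.0
    assert m["r2b"] == 0
    assert m["min_ratio"] == m["max_ratio"] == m["median_ratio"] == 0.8


def test_r2b_counts_two_returns():
    r = [0.8, 1.2, 0.8, 1.3, 0.8]  # rises above 1.2*0.8=0.96 and back, twice
    tr = make_track(np.arange(5) * 10.0, np.zeros(5), np.zeros(5), r)
    m = compute_calcium_measures(tr, baseline=0.8)
    assert m["r2b"] == 2 == oracle_r2b(r, 0.8)


def test_square_pulse_auc_matches_hand_trapezoid():
    r = [0.8, 0.8, 1.8, 1.8, 0.8, 0.8]
    t = np.arange(6) * 10.0
    tr = make_track(t, np.zeros(6), np.zeros(6), r)
    m = compute_calcium_measures(tr, baseline=0.8)
    assert m["auc_ratio"] == pytest.approx(oracle_trapezoid_auc(t, r, 0.8), rel=1e-12)


def test_t_max_first_occurrence_on_plateau():
    r = [0.8, 1.5, 1.5, 1.5, 0.8]
    tr = make_track(np.arange(5) * 10.0, np.zeros(5), np.zeros(5), r)
    assert compute_calcium_measures(tr, baseline=0.8)["t_max_s"] == 10.0


# ------------------------------------------------------ motility measures
def test_straight_line_meandering_index_one():
    n = 5
    tr = make_track(np.arange(n) * 10.0, np.arange(n) * 2.0, np.zeros(n),
                    np.ones(n))
    m = compute_motility_measures(tr)
    assert m["meandering_index"] == pytest.approx(1.0)


def test_closed_loop_zero_euclidean():
    x = [0, 1, 1, 0, 0]
    y = [0, 0, 1, 1, 0]
    tr = make_track(np.arange(5) * 10.0, x, y, np.ones(5))
    m = compute_motility_measures(tr)
    assert m["euclidean_um"] == 0.0
    assert m["meandering_index"] == 0.0


def test_mobile_fraction_threshold_conversion():
    # 0.5 um per 10 s frame = 3 um/min > 2 um/min threshold
    n = 7
    tr = make_track(np.arange(n) * 10.0, np.arange(n) * 0.5, np.zeros(n),
                    np.ones(n))
    assert compute_motility_measures(tr)["mobile_fraction"] == 1.0
    # 0.25 um per frame = 1.5 um/min < threshold
    tr2 = make_track(np.arange(n) * 10.0, np.arange(n) * 0.25, np.zeros(n),
                     np.ones(n))
    assert compute_motility_measures(tr2)["mobile_fraction"] == 0.0


@given(st.integers(0, 2 ** 31 - 1))
def test_meandering_index_bounded(seed):
    """Euclidean <= path length, hence MI in [0, 1], for arbitrary tracks."""
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 30)
    tr = make_track(np.arange(n) * 10.0, rng.normal(0, 5, n), rng.normal(0, 5, n),
                    rng.uniform(0.5, 2.5, n))
    m = compute_motility_measures(tr)
    assert m["euclidean_um"] <= m["track_length_um"] + 1e-9
    assert 0.0 <= m["meandering_index"] <= 1.0 + 1e-12


# ------------------------------------------------------- pre/post ratios
def test_symmetric_out_and_back_unit_ratios():
    x = [0, 1, 2, 3, 4, 3, 2, 1, 0]
    r = [0.8, 0.8, 0.8, 0.8, 2.0, 0.8, 0.8, 0.8, 0.8]
    tr = make_track(np.arange(9) * 10.0, x, np.zeros(9), r)
    m = compute_prepost_ratios(tr)
    assert m["length_ratio"] == pytest.approx(1.0)
    assert m["speed_ratio"] == pytest.approx(1.0)
    assert not m["excluded_few_points"]


def test_arrest_euclid_ratio():
    # pre: 30 um straight; post: 3 um straight
    x = [0, 10, 20, 30, 31, 32, 33]
    r = [0.8, 0.8, 0.8, 2.0, 0.8, 0.8, 0.8]
    tr = make_track(np.arange(7) * 10.0, x, np.zeros(7), r)
    assert compute_prepost_ratios(tr)["euclid_ratio"] == pytest.approx(10.0)


def test_few_datapoints_flagged():
    r = [0.8, 2.0, 0.8, 0.8, 0.8, 0.8]
    tr = make_track(np.arange(6) * 10.0, np.arange(6) * 1.0, np.zeros(6), r)
    m = compute_prepost_ratios(tr)
    assert m["excluded_few_points"]  # only 1 point before t_max


def test_zero_post_length_gives_nan_not_inf():
    x = [0, 1, 2, 3, 3, 3, 3]
    r = [0.8, 0.8, 0.8, 2.0, 0.8, 0.8, 0.8]
    tr = make_track(np.arange(7) * 10.0, x, np.zeros(7), r)
    m = compute_prepost_ratios(tr)
    assert np.isnan(m["length_ratio"])
    assert np.isnan(m["euclid_ratio"])


def test_auc_denominator_grows_with_baseline_padding():
    """Appending baseline-valued samples leaves the integral unchanged but
    grows the duration denominator."""
    t1 = np.arange(6) * 10.0
    r1 = [0.8, 0.8, 1.8, 1.8, 0.8, 0.8]
    t2 = np.arange(12) * 10.0
    r2 = r1 + [0.8] * 6
    m1 = compute_calcium_measures(
        make_track(t1, np.zeros(6), np.zeros(6), r1), baseline=0.8)
    m2 = compute_calcium_measures(
        make_track(t2, np.zeros(12), np.zeros(12), r2), baseline=0.8)
    assert m1["auc_ratio"] * (t1[-1] - t1[0]) == pytest.approx(
        m2["auc_ratio"] * (t2[-1] - t2[0]), rel=1e-12)
    assert m2["auc_ratio"] < m1["auc_ratio"]


# ------------------------------------------------- full-oracle equivalence
def test_all_measures_match_bruteforce_on_random_tracks(rng):
    """Every measure agrees with an independent loop-based implementation
    on 50 randomised small tracks."""
    for _ in range(50):
        n = int(rng.integers(8, 30))
        t = np.arange(n) * 10.0
        x = np.cumsum(rng.normal(0, 2, n))
        y = np.cumsum(rng.normal(0, 2, n))
        r = rng.uniform(0.5, 2.5, n)
        tr = make_track(t, x, y, r)
        baseline = 0.8

        cal = compute_calcium_measures(tr, baseline)
        assert cal["auc_ratio"] == pytest.approx(
            oracle_trapezoid_auc(t, r, baseline), rel=1e-9)
        assert cal["r2b"] == oracle_r2b(r, baseline)
        assert cal["min_ratio"] == r.min()
        assert cal["max_ratio"] == r.max()
        assert cal["median_ratio"] == np.median(r)
        i_max = int(np.argmax(r))
        assert cal["t_max_s"] == t[i_max]
        assert cal["track_duration_s"] == t[-1] - t[0]

        mot = compute_motility_measures(tr)
        om = oracle_motility(t, x, y, r)
        for k, v in om.items():
            assert mot[k] == pytest.approx(v, rel=1e-9), k

        pp = compute_prepost_ratios(tr)
        opp = oracle_prepost(t, x, y, r)
        if opp is not None:
            for k, v in opp.items():
                if np.isnan(v):
                    assert np.isnan(pp[k])
                else:
                    assert pp[k] == pytest.approx(v, rel=1e-9), k


def test_features_table_shape_and_columns(rng):
    tracks = pd.concat(
        [make_track(np.arange(31) * 10.0, np.cumsum(rng.normal(0, 1, 31)),
                    np.cumsum(rng.normal(0, 1, 31)), rng.uniform(0.6, 1.4, 31),
                    track_id=i) for i in range(5)],
        ignore_index=True)
    feats = features_table(tracks, baseline=0.8)
    assert list(feats.columns[1:14]) == MEASURE_COLUMNS
    assert len(feats) == 5


# --------------------------------------------------------------- matching
def test_single_basal_candidate_is_matched():
    acute = pd.DataFrame({"track_id": [1], "t_max_s": [100.0]})
    basal = pd.DataFrame({"track_id": [2], "t_max_s": [400.0]})
    out = match_controls(acute, basal)
    assert out.loc[0, "basal_id"] == 2 and out.loc[0, "matched"]


def test_greedy_nearest_matching():
    acute = pd.DataFrame({"track_id": [1, 2], "t_max_s": [100.0, 200.0]})
    basal = pd.DataFrame({"track_id": [3, 4, 5], "t_max_s": [110.0, 190.0, 500.0]})
    out = match_controls(acute, basal).set_index("acute_id")
    assert out.loc[1, "basal_id"] == 3  # 100 <-> 110
    assert out.loc[2, "basal_id"] == 4  # 200 <-> 190


def test_equidistant_tie_lower_track_id():
    acute = pd.DataFrame({"track_id": [1], "t_max_s": [100.0]})
    basal = pd.DataFrame({"track_id": [7, 4], "t_max_s": [90.0, 110.0]})
    out = match_controls(acute, basal)
    assert out.loc[0, "basal_id"] == 4


def test_exhausted_pool_flags_unmatched():
    acute = pd.DataFrame({"track_id": [1, 2, 3], "t_max_s": [100.0, 200.0, 300.0]})
    basal = pd.DataFrame({"track_id": [9], "t_max_s": [150.0]})
    out = match_controls(acute, basal)
    assert out["matched"].sum() == 1
    assert (~out["matched"]).sum() == 2


def test_each_basal_used_at_most_once(rng):
    acute = pd.DataFrame({"track_id": np.arange(20),
                          "t_max_s": rng.uniform(0, 1200, 20)})
    basal = pd.DataFrame({"track_id": 100 + np.arange(25),
                          "t_max_s": rng.uniform(0, 1200, 25)})
    out = match_controls(acute, basal)
    used = out.loc[out["matched"], "basal_id"]
    assert used.is_unique


def test_greedy_beats_random_matching_on_total_delta(rng):
    """Total |delta t_max| of greedy matching is no worse than random
    assignment across 100 random draws."""
    acute = pd.DataFrame({"track_id": np.arange(10),
                          "t_max_s": rng.uniform(0, 1200, 10)})
    basal = pd.DataFrame({"track_id": 100 + np.arange(12),
                          "t_max_s": rng.uniform(0, 1200, 12)})
    greedy_total = match_controls(acute, basal)["delta_t_max_s"].sum()
    b = basal["t_max_s"].to_numpy()
    for _ in range(100):
        perm = rng.permutation(len(b))[:10]
        random_total = np.abs(acute["t_max_s"].to_numpy() - b[perm]).sum()
        assert greedy_total <= random_total + 1e-9
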