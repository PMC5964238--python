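"""Per-cell calcium and motility measures from tracked calcium traces.

Thirteen measures characterise each tracked T cell: mobile fraction, track
duration, time of maximum ratio (t_max), % of track length at t_max,
returns-to-baseline count (R2B), min/max/median ratio, duration-normalized
area under the curve (AUC), and the four pre/post-t_max motility ratios
(track length, speed, meandering index, Euclidean distance). The baseline
is the median sample value of the ten tracks with the smallest ratio range.

Short tracks (<5 min) are excluded up front; tracks with fewer than three
datapoints on either side of t_max carry valid values for the first nine
measures but have their four pre/post ratios flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MEASURE_COLUMNS", "CALCIUM_MEASURES", "MOTILITY_MEASURES", "Baseline",
    "filter_tracks", "compute_baseline", "compute_calcium_measures",
    "compute_motility_measures", "compute_prepost_ratios", "features_table",
    "match_controls",
]

#: The thirteen per-cell measures, in canonical column order.
MEASURE_COLUMNS = [
    "mobile_fraction", "track_duration_s", "t_max_s", "pct_track_length_at_max",
    "r2b", "min_ratio", "max_ratio", "median_ratio", "auc_ratio",
    "length_ratio", "speed_ratio", "mi_ratio", "euclid_ratio",
]

#: The four purely calcium-derived measures (used to read PCA loadings).
CALCIUM_MEASURES = ["min_ratio", "max_ratio", "median_ratio", "auc_ratio"]
MOTILITY_MEASURES = [c for c in MEASURE_COLUMNS if c not in CALCIUM_MEASURES]


@dataclass
class Baseline:
    """Assay baseline ratio and the tracks that defined it."""

    value: float
    n_tracks_used: int
    selection: pd.DataFrame  # track_id, ratio_range per selected track

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("baseline must be positive")
        if self.n_tracks_used > 10:
            raise ValueError("baseline uses at most ten tracks")


def _groups(tracks: pd.DataFrame):
    return tracks.sort_values(["track_id", "frame"]).groupby("track_id", sort=True)


def filter_tracks(tracks: pd.DataFrame,
                  min_duration_s: float = 300.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a track table into (kept, excluded) by duration.

    A track is kept iff its last-minus-first timestamp is at least
    ``min_duration_s`` (5 min default; the boundary is inclusive).
    """
    dur = tracks.groupby("track_id")["t_s"].agg(lambda t: t.max() - t.min())
    keep_ids = dur.index[dur >= min_duration_s]
    kept = tracks[tracks["track_id"].isin(keep_ids)].copy()
    excluded = tracks[~tracks["track_id"].isin(keep_ids)].copy()
    return kept, excluded


def compute_baseline(tracks: pd.DataFrame, n_select: int = 10,
                     per_track_median: bool = False) -> Baseline:
    """Baseline = median sample value of the ``n_select`` lowest-range tracks.

    The default pools every ratio sample of the selected tracks before
    taking the median; ``per_track_median`` instead takes the median of the
    per-track medians (the alternative reading).
    """
    if tracks.empty:
        raise ValueError("cannot compute a baseline from zero tracks")
    rng_ = _groups(tracks)["ratio"].agg(lambda r: r.max() - r.min())
    sel = rng_.sort_values(kind="stable").index[:n_select]
    pool = tracks[tracks["track_id"].isin(sel)]
    if per_track_median:
        value = float(pool.groupby("track_id")["ratio"].median().median())
    else:
        value = float(pool["ratio"].median())
    selection = pd.DataFrame({"track_id": sel, "ratio_range": rng_.loc[sel].values})
    return Baseline(value=value, n_tracks_used=len(sel), selection=selection)


def _t_max_index(t: np.ndarray, r: np.ndarray) -> int:
    """Index of the first occurrence of the maximum ratio."""
    return int(np.argmax(r))


def compute_calcium_measures(track: pd.DataFrame, baseline: float,
                             r2b_band: float = 0.20,
                             signed_auc: bool = False) -> dict:
    """Calcium measures of one track against the assay baseline.

    R2B counts downward crossings from above ``(1 + r2b_band) * baseline``
    back to at or below it. AUC is the trapezoidal integral of the trace's
    excess over baseline (positive part unless ``signed_auc``), divided by
    the track duration.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    t = track["t_s"].to_numpy(dtype=float)
    r = track["ratio"].to_numpy(dtype=float)
    i_max = _t_max_index(t, r)
    band = (1.0 + r2b_band) * baseline
    above = r > band
    r2b = int(np.count_nonzero(above[:-1] & ~above[1:]))
    excess = r - baseline
    if not signed_auc:
        excess = np.maximum(excess, 0.0)
    duration = t[-1] - t[0]
    auc = float(np.trapezoid(excess, t) / duration) if duration > 0 else 0.0
    return {
        "track_duration_s": float(duration),
        "t_max_s": float(t[i_max]),
        "r2b": r2b,
        "min_ratio": float(r.min()),
        "max_ratio": float(r.max()),
        "median_ratio": float(np.median(r)),
        "auc_ratio": auc,
    }


def _step_lengths(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.hypot(np.diff(x), np.diff(y))


def compute_motility_measures(track: pd.DataFrame,
                              mobile_speed_threshold_um_min: float = 2.0) -> dict:
    """Motility measures of one track.

    The mobile fraction is the fraction of steps faster than the threshold
    (2 um/min default). The meandering index is Euclidean displacement over
    path length (defined as 1 for a zero-length path).
    """
    t = track["t_s"].to_numpy(dtype=float)
    x = track["x_um"].to_numpy(dtype=float)
    y = track["y_um"].to_numpy(dtype=float)
    r = track["ratio"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples for motility measures")
    steps = _step_lengths(x, y)
    dts = np.diff(t)
    speeds_um_min = steps / dts * 60.0
    mobile_fraction = float(np.mean(speeds_um_min > mobile_speed_threshold_um_min))
    length = float(steps.sum())
    euclid = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    mi = euclid / length if length > 0 else 1.0
    duration = t[-1] - t[0]
    speed = length / duration if duration > 0 else 0.0
    i_max = _t_max_index(t, r)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    pct_at_max = 100.0 * cum[i_max] / length if length > 0 else 0.0
    return {
        "mobile_fraction": mobile_fraction,
        "track_length_um": length,
        "euclidean_um": euclid,
        "meandering_index": float(mi),
        "speed_um_s": float(speed),
        "pct_track_length_at_max": float(pct_at_max),
    }


def _segment_measures(t, x, y):
    steps = _step_lengths(x, y)
    length = float(steps.sum())
    euclid = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    duration = float(t[-1] - t[0])
    speed = length / duration if duration > 0 else 0.0
    mi = euclid / length if length > 0 else 1.0
    return length, speed, mi, euclid


def compute_prepost_ratios(track: pd.DataFrame, min_points: int = 3) -> dict:
    """Pre/post-t_max ratios of length, speed, MI and Euclidean distance.

    The track splits at the (first) maximum-ratio sample, which terminates
    the pre segment and starts the post segment. Ratios with a zero post
    value are NaN (flagged, never infinity). ``excluded_few_points`` is set
    when fewer than ``min_points`` datapoints exist strictly before or
    after t_max.
    """
    t = track["t_s"].to_numpy(dtype=float)
    x = track["x_um"].to_numpy(dtype=float)
    y = track["y_um"].to_numpy(dtype=float)
    r = track["ratio"].to_numpy(dtype=float)
    i = _t_max_index(t, r)
    n = len(t)
    excluded = (i < min_points) or (n - 1 - i < min_points)
    out = {"excluded_few_points": bool(excluded),
           "length_ratio": np.nan, "speed_ratio": np.nan,
           "mi_ratio": np.nan, "euclid_ratio": np.nan}
    if i == 0 or i == n - 1:
        return out
    pre = _segment_measures(t[:i + 1], x[:i + 1], y[:i + 1])
    post = _segment_measures(t[i:], x[i:], y[i:])
    for name, a, b in zip(("length_ratio", "speed_ratio", "mi_ratio", "euclid_ratio"),
                          pre, post):
        out[name] = a / b if b > 0 else np.nan
    return out


def features_table(tracks: pd.DataFrame, baseline: Baseline | float,
                   r2b_band: float = 0.20,
                   mobile_speed_threshold_um_min: float = 2.0,
                   min_points: int = 3) -> pd.DataFrame:
    """One row of the thirteen measures (plus flags) per kept track."""
    base = baseline.value if isinstance(baseline, Baseline) else float(baseline)
    rows = []
    for tid, g in _groups(tracks):
        row = {"track_id": tid}
        row.update(compute_calcium_measures(g, base, r2b_band=r2b_band))
        row.update(compute_motility_measures(
            g, mobile_speed_threshold_um_min=mobile_speed_threshold_um_min))
        row.update(compute_prepost_ratios(g, min_points=min_points))
        rows.append(row)
    df = pd.DataFrame(rows)
    extras = [c for c in df.columns if c not in MEASURE_COLUMNS and c != "track_id"]
    return df[["track_id"] + MEASURE_COLUMNS + extras]


def match_controls(acute: pd.DataFrame, basal: pd.DataFrame) -> pd.DataFrame:
    """Greedily pair acute cells with basal controls of closest t_max.

    Both inputs need ``track_id`` and ``t_max_s`` columns. Acute cells are
    processed in ascending t_max order (track_id breaks ties) and each
    takes the unused basal cell minimising |delta t_max| (again lower
    track_id on ties). Acute cells left without a control when the basal
    pool runs out are flagged unmatched.
    """
    if acute.empty:
        raise ValueError("no acute cells to match")
    a = acute.sort_values(["t_max_s", "track_id"], kind="stable")
    pool = basal.sort_values(["t_max_s", "track_id"], kind="stable").reset_index(drop=True)
    used = np.zeros(len(pool), dtype=bool)
    rows = []
    for _, cell in a.iterrows():
        free = np.flatnonzero(~used)
        if free.size == 0:
            rows.append({"acute_id": cell["track_id"], "basal_id": pd.NA,
                         "delta_t_max_s": np.nan, "matched": False})
            continue
        cand = pool.loc[free]
        delta = (cand["t_max_s"] - cell["t_max_s"]).abs()
        # stable sort on (|delta|, track_id): lower id wins exact ties
        best = cand.assign(_d=delta).sort_values(["_d", "track_id"], kind="stable").index[0]
        used[best] = True
        rows.append({"acute_id": cell["track_id"],
                     "basal_id": pool.loc[best, "track_id"],
                     "delta_t_max_s": float(abs(pool.loc[best, "t_max_s"] - cell["t_max_s"])),
                     "matched": True})
    return pd.DataFrame(rows)
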