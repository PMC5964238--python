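"""Synthetic T-cell tracks: persistent random walks with arrest on signaling.

Cells are seeded on a jittered grid and perform a persistent random walk
(von Mises turning angles) confined near their seed point. Cells with a
'high' signature — and a configurable fraction of 'low' cells — switch to
the arrest regime at their calcium onset: the confinement radius collapses
around the onset position while the step speed is kept (by default) at the
basal value, so arrested cells are "corralled" rather than frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .traces import jitter_params, simulate_trace, trace_template

__all__ = ["GroundTruth", "simulate_tracks"]


@dataclass
class GroundTruth:
    """Per-cell ground truth for one simulated assay.

    Attributes
    ----------
    cells : DataFrame with one row per T cell: ``track_id``, ``label``,
        ``onset_s`` (NaN for flat), ``arrested`` (bool), ``home_x_um``,
        ``home_y_um``.
    traces : (n_cells, n_frames) noise-free 340:380 templates.
    noisy_traces : (n_cells, n_frames) templates plus measurement noise;
        these are the values written to the track table.
    positions : (n_cells, n_frames, 2) x/y positions in um.
    mdm_positions : (n_mdms, 2) static macrophage centers in um.
    config : the :class:`SimConfig` used.
    """

    cells: pd.DataFrame
    traces: np.ndarray
    noisy_traces: np.ndarray
    positions: np.ndarray
    mdm_positions: np.ndarray
    config: SimConfig

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1] if self.traces.ndim == 2 else 0


def _seed_positions(n: int, field: tuple, rng: np.random.Generator,
                    margin: float) -> np.ndarray:
    """Jittered grid seeding keeping cells ``margin`` from the field edge."""
    if n == 0:
        return np.zeros((0, 2))
    cols = int(np.ceil(np.sqrt(n * field[0] / field[1])))
    rows = int(np.ceil(n / cols))
    xs = np.linspace(margin, field[0] - margin, cols)
    ys = np.linspace(margin, field[1] - margin, rows)
    grid = np.array([(x, y) for y in ys for x in xs])[:n]
    spacing = min((field[0] - 2 * margin) / max(cols - 1, 1),
                  (field[1] - 2 * margin) / max(rows - 1, 1))
    jitter = rng.uniform(-0.1 * spacing, 0.1 * spacing, size=grid.shape)
    return grid + jitter


def _walk(home: np.ndarray, n_frames: int, dt: float, speed_um_min: np.ndarray,
          kappa: float, confine: np.ndarray, centers: np.ndarray,
          rng: np.random.Generator, field: tuple,
          pause_prob: float = 0.0, pause_speed_max: float = 2.0) -> np.ndarray:
    """Persistent random walk of one cell, confined to a disc per frame.

    ``speed_um_min``, ``confine`` and ``centers`` are per-frame arrays so the
    regime can switch at calcium onset. Migration is stop-and-go: with
    probability ``pause_prob`` a step is a pause, its speed drawn uniformly
    below ``pause_speed_max`` um/min.
    """
    pos = np.empty((n_frames, 2))
    pos[0] = home
    theta = rng.uniform(0, 2 * np.pi)
    for i in range(1, n_frames):
        theta += rng.vonmises(0.0, kappa)
        speed = speed_um_min[i]
        if pause_prob > 0 and rng.random() < pause_prob:
            speed = rng.uniform(0.0, min(pause_speed_max, speed))
        step = speed / 60.0 * dt
        cand = pos[i - 1] + step * np.array([np.cos(theta), np.sin(theta)])
        off = cand - centers[i]
        dist = np.hypot(*off)
        if dist > confine[i]:
            # Re-aim toward the confinement center with the full step so
            # confinement never shortens steps (path length preserved).
            inward = centers[i] - pos[i - 1]
            theta = np.arctan2(inward[1], inward[0]) + rng.uniform(-0.5, 0.5)
            cand = pos[i - 1] + step * np.array([np.cos(theta), np.sin(theta)])
            off = cand - centers[i]
            dist = np.hypot(*off)
            if dist > confine[i]:
                cand = centers[i] + off / dist * confine[i]
        cand[0] = np.clip(cand[0], 0.0, field[0])
        cand[1] = np.clip(cand[1], 0.0, field[1])
        pos[i] = cand
    return pos


def simulate_tracks(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate tracked cells with known labels, traces and positions.

    Returns
    -------
    tracks : long-form DataFrame with columns ``track_id, frame, t_s,
        x_um, y_um, ratio`` (ratio includes measurement noise).
    ground_truth : :class:`GroundTruth` with noise-free templates.

    Identical configs (including seed) produce identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tcells
    nf = config.n_frames
    dt = config.frame_interval_s
    field = config.field_size_um

    if n == 0:
        warnings.warn("zero T cells requested; returning empty outputs")
        empty = pd.DataFrame(columns=["track_id", "frame", "t_s", "x_um", "y_um", "ratio"])
        gt = GroundTruth(pd.DataFrame(columns=["track_id", "label", "onset_s",
                                               "arrested", "home_x_um", "home_y_um"]),
                         np.zeros((0, nf)), np.zeros((0, nf)),
                         np.zeros((0, nf, 2)), np.zeros((0, 2)), config)
        return empty, gt

    labels_order = ["flat", "transient", "low", "high"]
    probs = np.array([config.class_mixture.get(k, 0.0) for k in labels_order])
    probs = probs / probs.sum()
    # Exact-count class allocation (largest remainder), then shuffle: the
    # realised mixture matches the configured one as closely as integers allow.
    counts = np.floor(probs * n).astype(int)
    remainder = probs * n - counts
    for j in np.argsort(remainder)[::-1][: n - counts.sum()]:
        counts[j] += 1
    labels = np.repeat(labels_order, counts)
    rng.shuffle(labels)

    margin = config.confine_um + 4.0
    homes = _seed_positions(n, field, rng, margin)
    mdm_positions = rng.uniform([0, 0], list(field), size=(config.n_mdms, 2))

    lo, hi = config.trace.onset_window_s
    onsets = rng.uniform(lo, hi, size=n)
    onsets[labels == "flat"] = np.nan
    arrested = (labels == "high") | ((labels == "low") &
                                     (rng.random(n) < config.arrest_low_fraction))

    # Tracking is imperfect: tracks start late / end early by up to the
    # configured trims, and a small fraction are lost before 5 min.
    n_enter = int(config.enter_trim_max_s / dt)
    n_exit = int(config.exit_trim_max_s / dt)
    start_frame = rng.integers(0, n_enter + 1, size=n)
    end_frame = nf - 1 - rng.integers(0, n_exit + 1, size=n)
    dropout = rng.random(n) < config.dropout_prob
    short_len = max(int(np.ceil(300.0 / dt)) - 1, 2)  # duration just under 5 min
    end_frame[dropout] = np.minimum(start_frame[dropout] + short_len, nf - 1)
    end_frame = np.maximum(end_frame, start_frame + 2)

    traces = np.empty((n, nf))
    noisy = np.empty((n, nf))
    positions = np.empty((n, nf, 2))
    t_axis = np.arange(nf) * dt
    for i in range(n):
        onset = 0.0 if labels[i] == "flat" else float(onsets[i])
        traces[i] = trace_template(labels[i], nf, dt,
                                   jitter_params(config.trace, rng), onset)
        noise = rng.normal(0.0, config.trace.noise_sd, size=nf) \
            if config.trace.noise_sd > 0 else 0.0
        noisy[i] = np.maximum(traces[i] + noise, 1e-6)

        speed = np.full(nf, config.basal_speed_um_min)
        confine = np.full(nf, config.confine_um)
        centers = np.tile(homes[i], (nf, 1))
        pos = _walk(homes[i], nf, dt, speed, config.persistence_kappa,
                    confine, centers, rng, field,
                    pause_prob=config.pause_prob,
                    pause_speed_max=config.pause_speed_max_um_min)
        if arrested[i]:
            onset_idx = int(np.searchsorted(t_axis, onsets[i]))
            if onset_idx < nf:
                # Re-walk the post-onset segment in the arrest regime,
                # corralled around the onset position.
                speed[onset_idx:] = config.arrest_speed_um_min
                confine[onset_idx:] = config.arrest_confine_um
                centers[onset_idx:] = pos[onset_idx]
                tail = _walk(pos[onset_idx], nf - onset_idx, dt,
                             speed[onset_idx:], config.persistence_kappa,
                             confine[onset_idx:], centers[onset_idx:], rng, field,
                             pause_prob=config.pause_prob,
                             pause_speed_max=config.pause_speed_max_um_min)
                pos[onset_idx:] = tail
        positions[i] = pos

    cells = pd.DataFrame({
        "track_id": np.arange(n),
        "label": labels,
        "onset_s": onsets,
        "arrested": arrested,
        "home_x_um": homes[:, 0],
        "home_y_um": homes[:, 1],
        "start_frame": start_frame,
        "end_frame": end_frame,
    })
    pieces = []
    for i in range(n):
        fr = np.arange(start_frame[i], end_frame[i] + 1)
        pieces.append(pd.DataFrame({
            "track_id": i, "frame": fr, "t_s": fr * dt,
            "x_um": positions[i, fr, 0], "y_um": positions[i, fr, 1],
            "ratio": noisy[i, fr],
        }))
    tracks = pd.concat(pieces, ignore_index=True)
    gt = GroundTruth(cells, traces, noisy, positions, mdm_positions, config)
    return tracks, gt
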