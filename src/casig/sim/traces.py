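"""Synthetic single-cell calcium traces for the four signature archetypes."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .config import TraceParams

__all__ = ["simulate_trace", "trace_template", "jitter_params"]


def jitter_params(params: TraceParams, rng: np.random.Generator) -> TraceParams:
    """Per-cell variability: draw signal levels uniformly within
    ``+/- level_jitter`` of the template levels (baseline within
    ``+/- baseline_jitter``). The default jitter keeps every class template
    on its side of the classification thresholds."""
    j = params.level_jitter
    if j <= 0 and params.baseline_jitter <= 0:
        return params
    u = lambda v, w: float(v + rng.uniform(-w, w))
    return replace(params,
                   baseline=u(params.baseline, params.baseline_jitter),
                   transient_peak=u(params.transient_peak, j),
                   low_level=u(params.low_level, j),
                   high_peak=u(params.high_peak, j),
                   high_sustain_level=u(params.high_sustain_level, j))


def _ramp(t, t0, t1, v0, v1):
    """Piecewise-linear ramp from (t0, v0) to (t1, v1), clamped outside."""
    return np.interp(t, [t0, t1], [v0, v1])


def trace_template(label: str, n_frames: int, frame_interval_s: float,
                   params: TraceParams, onset_s: float) -> np.ndarray:
    """Noise-free 340:380 template for one signature class.

    The templates are built so that the deterministic classifier recovers
    the generating label exactly: 'flat' never leaves baseline, 'transient'
    rises and decays fully back, 'low' plateaus below the 'high' onset
    criterion, 'high' peaks above the absolute criterion and settles to a
    sustained level above 1.
    """
    t = np.arange(n_frames) * frame_interval_s
    b = params.baseline
    if label == "flat":
        return np.full(n_frames, b)
    t_rise = onset_s + params.rise_time_s
    if label == "transient":
        peak = params.transient_peak
        t_hold = t_rise + params.transient_hold_s
        t_fall = t_hold + params.transient_fall_s
        return np.interp(t, [0, onset_s, t_rise, t_hold, t_fall],
                         [b, b, peak, peak, b])
    if label == "low":
        return np.interp(t, [0, onset_s, t_rise], [b, b, params.low_level])
    if label == "high":
        out = np.interp(t, [0, onset_s, t_rise], [b, b, params.high_peak])
        post = t > t_rise
        decay = np.exp(-(t[post] - t_rise) / params.high_decay_s)
        out[post] = params.high_sustain_level + (params.high_peak - params.high_sustain_level) * decay
        return out
    raise ValueError(f"unknown signature label: {label!r}")


def simulate_trace(label: str, n_frames: int, frame_interval_s: float,
                   params: TraceParams, rng: np.random.Generator,
                   onset_s: float | None = None,
                   noise_sd: float | None = None) -> np.ndarray:
    """Simulate one calcium trace of class ``label``.

    Parameters
    ----------
    onset_s : onset time; drawn uniformly from ``params.onset_window_s``
        when None (ignored for 'flat').
    noise_sd : additive Gaussian noise SD in ratio units; defaults to
        ``params.noise_sd``.
    """
    if label not in ("flat", "transient", "low", "high"):
        raise ValueError(f"unknown signature label: {label!r}")
    if onset_s is None:
        lo, hi = params.onset_window_s
        onset_s = float(rng.uniform(lo, hi))
    if noise_sd is None:
        noise_sd = params.noise_sd
    trace = trace_template(label, n_frames, frame_interval_s,
                           jitter_params(params, rng), onset_s)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return np.maximum(trace, 1e-6)
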