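"""340:380 ratio stacks and circular-ROI trace extraction.

The ratio image divides the 340 nm excitation channel by the 380 nm channel
pixel-wise; pixels whose 380 signal does not exceed a background threshold
are masked (they carry no ratio). The raw ratio is kept unclipped for
measurement — the conventional 0.5/2.0 min/max applies only to the false-
color display mapping, since measured maxima can exceed 2.

Per-cell calcium traces are extracted along a track with a circular ROI
(default 20 px diameter): at each frame the trace value is the mean ratio
over unmasked pixels whose centers fall within the ROI circle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from matplotlib import colormaps

__all__ = ["RatioStack", "compute_ratio_stack", "render_display",
           "extract_trace", "roi_pixel_offsets", "read_stack"]


@dataclass
class RatioStack:
    """Per-pixel 340:380 ratios with a validity mask.

    ``ratio`` is (T, H, W) float; invalid (masked) pixels hold NaN and are
    False in ``mask``. ``clip_lo``/``clip_hi`` only affect display export.
    """

    ratio: np.ndarray
    mask: np.ndarray
    clip_lo: float = 0.5
    clip_hi: float = 2.0
    pixel_size_um: float = 1.0
    frame_interval_s: float = 10.0

    def __post_init__(self):
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be < clip_hi")
        if self.ratio.shape != self.mask.shape:
            raise ValueError("ratio and mask shapes differ")

    @property
    def n_frames(self) -> int:
        return self.ratio.shape[0]


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a (T, H, W) array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def compute_ratio_stack(ch340: np.ndarray, ch380: np.ndarray,
                        clip_lo: float = 0.5, clip_hi: float = 2.0,
                        bg_threshold: float = 0.0,
                        pixel_size_um: float = 1.0,
                        frame_interval_s: float = 10.0) -> RatioStack:
    """Divide the 340 nm stack by the 380 nm stack where signal exists.

    Pixels with ``ch380 <= bg_threshold`` are masked. Inputs may be 2-D
    (single frame) or (T, H, W); integer or float, non-negative.
    """
    a = np.asarray(ch340, dtype=float)
    b = np.asarray(ch380, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if a.ndim == 2:
        a, b = a[None], b[None]
    if a.ndim != 3:
        raise ValueError("expected 2-D frames or a (T, H, W) stack")
    mask = b > bg_threshold
    ratio = np.full(a.shape, np.nan)
    np.divide(a, b, out=ratio, where=mask)
    return RatioStack(ratio=ratio, mask=mask, clip_lo=clip_lo, clip_hi=clip_hi,
                      pixel_size_um=pixel_size_um, frame_interval_s=frame_interval_s)


def render_display(stack: RatioStack, lut_name: str | None = "nipy_spectral",
                   lut_bins: int = 16,
                   overlay: np.ndarray | None = None):
    """Map ratios linearly to 16-bit for display and optionally false-color.

    ``clip_lo`` maps to 0 and ``clip_hi`` to 65535; values outside are
    clamped, masked pixels map to 0. Returns the uint16 stack and, when a
    LUT is requested, an RGB uint8 preview quantised to ``lut_bins`` colors
    (a 16-step LUT emulates the classic banded false-color display). An
    optional ``overlay`` boolean stack (e.g. the APC channel) is painted
    white on the RGB preview.
    """
    span = stack.clip_hi - stack.clip_lo
    scaled = (np.nan_to_num(stack.ratio, nan=stack.clip_lo) - stack.clip_lo) / span
    scaled = np.clip(scaled, 0.0, 1.0)
    display = np.round(scaled * 65535.0).astype(np.uint16)
    display[~stack.mask] = 0
    if lut_name is None:
        return display, None
    cmap = colormaps[lut_name]
    levels = (np.floor(scaled * lut_bins).clip(max=lut_bins - 1) + 0.5) / lut_bins
    rgb = (cmap(levels)[..., :3] * 255).astype(np.uint8)
    rgb[~stack.mask] = 0
    if overlay is not None:
        rgb[np.asarray(overlay, dtype=bool)] = 255
    return display, rgb


def roi_pixel_offsets(diameter_px: float) -> np.ndarray:
    """Integer (dx, dy) offsets of pixel centers within a circle of the
    given diameter centred on a pixel (center-inclusive: distance <= r)."""
    r = diameter_px / 2.0
    n = int(np.floor(r))
    dy, dx = np.mgrid[-n:n + 1, -n:n + 1]
    keep = dx ** 2 + dy ** 2 <= r ** 2
    return np.column_stack([dx[keep], dy[keep]])


def extract_trace(stack: RatioStack, track: pd.DataFrame,
                  roi_diameter_px: float = 20.0) -> pd.DataFrame:
    """Extract a calcium trace along one track with a circular ROI.

    ``track`` needs columns ``frame``, ``x_um``, ``y_um`` (and is returned
    augmented with ``ratio`` and a boolean ``flagged`` column). Positions
    are converted to pixels via the stack's pixel size and the ROI is
    centred on the nearest pixel. A sample is flagged (ratio NaN) when the
    ROI contains no unmasked pixel, including tracks outside the image.
    """
    offsets = roi_pixel_offsets(roi_diameter_px)
    h, w = stack.ratio.shape[1:]
    out = track.copy()
    ratios = np.full(len(track), np.nan)
    flagged = np.zeros(len(track), dtype=bool)
    frames = track["frame"].to_numpy(dtype=int)
    cx = np.round(track["x_um"].to_numpy(dtype=float) / stack.pixel_size_um).astype(int)
    cy = np.round(track["y_um"].to_numpy(dtype=float) / stack.pixel_size_um).astype(int)
    for i, (f, x0, y0) in enumerate(zip(frames, cx, cy)):
        if not 0 <= f < stack.n_frames:
            flagged[i] = True
            continue
        xs = x0 + offsets[:, 0]
        ys = y0 + offsets[:, 1]
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        if not ok.any():
            flagged[i] = True
            continue
        vals = stack.ratio[f, ys[ok], xs[ok]]
        valid = stack.mask[f, ys[ok], xs[ok]]
        if not valid.any():
            flagged[i] = True
            continue
        ratios[i] = vals[valid].mean()
    out["ratio"] = ratios
    out["flagged"] = flagged
    return out
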