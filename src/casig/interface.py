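"""Quantification of marker accumulation and polarization at cell-cell interfaces.

Two read-outs from annotated conjugate images:

* **Accumulation ratio** (intact staining): mean fluorescence intensity (MFI)
  along a membrane trace covering the T cell-macrophage interface divided by
  the MFI along the remaining T-cell surface. Traces are polylines with a
  width (default 10 px), mirroring manual membrane tracing.
* **Four-ROI polarization** (permeabilized staining): square ROIs (default
  50 px, i.e. 3.37 um at the reference pixel size) at the interface, away
  from it, and on either side; each ROI's MFI is expressed as a percentage
  of the four-ROI sum, and signed front-back / side-side polarities are the
  differences of opposing percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

__all__ = [
    "ConjugateAnnotation",
    "PolarizationResult",
    "polyline_band_pixels",
    "membrane_profile_mfi",
    "accumulation_ratio",
    "polarization_rois",
]

#: Pixel size such that a 50 px ROI spans 3.37 um.
REFERENCE_PIXEL_SIZE_UM = 3.37 / 50.0


@dataclass
class ConjugateAnnotation:
    """Manual annotation of one conjugate image.

    ``interface`` and ``rest`` are (N, 2) arrays of (x, y) polyline vertices
    in pixel coordinates. For polarization, ``center`` is the T-cell center
    and ``direction`` the unit vector pointing from the T cell toward the
    interface.
    """

    interface: np.ndarray | None = None
    rest: np.ndarray | None = None
    width_px: float = 10.0
    center: np.ndarray | None = None
    direction: np.ndarray | None = None
    roi_size_px: float = 50.0
    roi_offset_px: float | None = None  # defaults to roi_size_px
    pixel_size_um: float = REFERENCE_PIXEL_SIZE_UM

    def __post_init__(self):
        for name in ("interface", "rest"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
                    raise ValueError(f"{name} polyline needs >=2 (x, y) vertices")
                setattr(self, name, v)
        if self.width_px < 1:
            raise ValueError("trace width must be >= 1 px")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            n = np.hypot(*d)
            if n == 0:
                raise ValueError("direction vector must be non-zero")
            self.direction = d / n

    # -- JSON round trip ----------------------------------------------
    def to_json(self, path) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        with open(path, "w") as fh:
            json.dump({"interface": arr(self.interface), "rest": arr(self.rest),
                       "width_px": self.width_px, "center": arr(self.center),
                       "direction": arr(self.direction),
                       "roi_size_px": self.roi_size_px,
                       "roi_offset_px": self.roi_offset_px,
                       "pixel_size_um": self.pixel_size_um}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConjugateAnnotation":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("interface", "rest", "center", "direction"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


@dataclass
class PolarizationResult:
    """Four-ROI percentages and signed polarity coordinates."""

    pct_interface: float
    pct_away: float
    pct_side1: float
    pct_side2: float
    front_back: float  # pct_interface - pct_away
    side_side: float   # pct_side1 - pct_side2

    @property
    def percentages(self) -> np.ndarray:
        return np.array([self.pct_interface, self.pct_away,
                         self.pct_side1, self.pct_side2])


def _point_segment_distance(px, py, a, b):
    """Distance of points (px, py) to segment a-b (all vectorised)."""
    ab = b - a
    denom = ab @ ab
    if denom == 0:
        return np.hypot(px - a[0], py - a[1])
    t = ((px - a[0]) * ab[0] + (py - a[1]) * ab[1]) / denom
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (a[0] + t * ab[0]), py - (a[1] + t * ab[1]))


def polyline_band_pixels(shape: tuple, polyline: np.ndarray,
                         width_px: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``width_px/2``
    (perpendicular distance) of the polyline. Each pixel counts once even
    where the band self-overlaps."""
    poly = np.asarray(polyline, dtype=float)
    h, w = shape
    half = width_px / 2.0
    x0 = max(int(np.floor(poly[:, 0].min() - half)) - 1, 0)
    x1 = min(int(np.ceil(poly[:, 0].max() + half)) + 2, w)
    y0 = max(int(np.floor(poly[:, 1].min() - half)) - 1, 0)
    y1 = min(int(np.ceil(poly[:, 1].max() + half)) + 2, h)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dmin = np.full(xx.shape, np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        np.minimum(dmin, _point_segment_distance(xx, yy, a, b), out=dmin)
    mask[y0:y1, x0:x1] = dmin <= half
    return mask


def membrane_profile_mfi(image: np.ndarray, polyline: np.ndarray,
                         width_px: float = 10.0) -> float:
    """MFI over the band of pixels within ``width_px/2`` of the polyline."""
    img = np.asarray(image, dtype=float)
    mask = polyline_band_pixels(img.shape, polyline, width_px)
    if not mask.any():
        raise ValueError("membrane trace covers no pixels")
    return float(img[mask].mean())


def accumulation_ratio(image: np.ndarray,
                       annotation: ConjugateAnnotation,
                       background: float = 0.0) -> float:
    """Interface-band MFI divided by rest-of-surface-band MFI.

    Pixels claimed by both bands are assigned to the interface and excluded
    from the rest band. An optional constant ``background`` is subtracted
    from both MFIs before the ratio (default none).
    """
    if annotation.interface is None or annotation.rest is None:
        raise ValueError("annotation must define interface and rest polylines")
    img = np.asarray(image, dtype=float)
    m_if = polyline_band_pixels(img.shape, annotation.interface, annotation.width_px)
    m_rest = polyline_band_pixels(img.shape, annotation.rest, annotation.width_px)
    m_rest &= ~m_if
    if not m_if.any() or not m_rest.any():
        raise ValueError("empty membrane band")
    mfi_if = img[m_if].mean() - background
    mfi_rest = img[m_rest].mean() - background
    if mfi_rest <= 0:
        raise ValueError("rest-of-surface MFI <= 0; accumulation ratio undefined "
                         "(check background handling)")
    return float(mfi_if / mfi_rest)


def _square_roi_mask(shape, center, u, v, size):
    """Mask of pixels in a square of side ``size`` centred at ``center``,
    aligned with orthonormal axes u, v."""
    h, w = shape
    half = size / 2.0
    reach = int(np.ceil(half * np.sqrt(2))) + 2
    cx, cy = center
    x0, x1 = max(int(cx) - reach, 0), min(int(cx) + reach + 1, w)
    y0, y1 = max(int(cy) - reach, 0), min(int(cy) + reach + 1, h)
    mask = np.zeros(shape, dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    pu = dx * u[0] + dy * u[1]
    pv = dx * v[0] + dy * v[1]
    mask[y0:y1, x0:x1] = (np.abs(pu) <= half) & (np.abs(pv) <= half)
    return mask


def polarization_rois(image: np.ndarray,
                      annotation: ConjugateAnnotation) -> PolarizationResult:
    """Four-ROI polarization analysis of a permeabilized-stain conjugate.

    ROIs sit at ``center +/- offset*direction`` (interface / away) and
    ``center +/- offset*perpendicular`` (side1 = +90 deg from the interface
    direction, side2 = -90 deg); offset defaults to the ROI size. Each ROI's
    MFI is reported as a percentage of the four-ROI MFI sum; ``front_back``
    and ``side_side`` are the signed differences of opposing percentages.
    """
    if annotation.center is None or annotation.direction is None:
        raise ValueError("annotation must define center and interface direction")
    img = np.asarray(image, dtype=float)
    u = annotation.direction
    v = np.array([-u[1], u[0]])  # +90 degrees
    size = annotation.roi_size_px
    offset = annotation.roi_offset_px if annotation.roi_offset_px is not None else size
    centers = [annotation.center + offset * u,   # interface
               annotation.center - offset * u,   # away
               annotation.center + offset * v,   # side1
               annotation.center - offset * v]   # side2
    mfis = []
    for c in centers:
        mask = _square_roi_mask(img.shape, c, u, v, size)
        if not mask.any():
            raise ValueError("polarization ROI falls entirely outside the image")
        mfis.append(img[mask].mean())
    mfis = np.asarray(mfis)
    total = mfis.sum()
    if total <= 0:
        raise ValueError("four-ROI MFI sum is not positive")
    pct = 100.0 * mfis / total
    return PolarizationResult(pct_interface=float(pct[0]), pct_away=float(pct[1]),
                              pct_side1=float(pct[2]), pct_side2=float(pct[3]),
                              front_back=float(pct[0] - pct[1]),
                              side_side=float(pct[2] - pct[3]))
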