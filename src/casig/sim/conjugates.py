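"""Synthetic conjugate images with known interface enrichment.

A T cell is drawn as a circular membrane band; the arc facing the
macrophage (the interface) carries ``k`` times the staining intensity of
the remaining membrane. The image is painted with exactly the same
band-membership rule the quantification uses, so with no noise the
recovered accumulation ratio equals ``k`` to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..interface import ConjugateAnnotation, polyline_band_pixels

__all__ = ["ConjugateGeometry", "simulate_conjugate_image", "simulate_polarized_image"]


@dataclass
class ConjugateGeometry:
    """Geometry of one synthetic conjugate (pixel units)."""

    image_size: tuple = (200, 200)
    center: tuple = (100.0, 120.0)
    radius: float = 30.0
    interface_halfangle_deg: float = 40.0
    interface_angle_deg: float = -90.0  # interface faces "up" (-y) by default
    width_px: float = 10.0
    membrane_intensity: float = 400.0
    interior_intensity: float = 40.0
    n_vertices: int = 180


def _arc(center, radius, a0, a1, n):
    ang = np.linspace(a0, a1, n)
    return np.column_stack([center[0] + radius * np.cos(ang),
                            center[1] + radius * np.sin(ang)])


def simulate_conjugate_image(enrichment_k: float,
                             geometry: ConjugateGeometry | None = None,
                             noise: str | None = None,
                             rng: np.random.Generator | None = None
                             ) -> tuple[np.ndarray, ConjugateAnnotation]:
    """Render a conjugate image whose interface membrane is ``k``-fold enriched.

    Parameters
    ----------
    enrichment_k : true interface/rest intensity ratio; must be > 0.
    noise : None for a noise-free image, or ``"poisson"`` for shot noise on
        the painted intensities (interpreted as photon counts).

    Returns
    -------
    (image, annotation) : float image and the ground-truth annotation whose
        polylines trace the interface arc and the remaining membrane.
    """
    if enrichment_k <= 0:
        raise ValueError("enrichment_k must be positive")
    geo = geometry or ConjugateGeometry()
    rng = rng or np.random.default_rng()

    a_mid = np.deg2rad(geo.interface_angle_deg)
    half = np.deg2rad(geo.interface_halfangle_deg)
    n_if = max(int(geo.n_vertices * half / np.pi), 8)
    n_rest = max(geo.n_vertices - n_if, 8)
    interface = _arc(geo.center, geo.radius, a_mid - half, a_mid + half, n_if)
    rest = _arc(geo.center, geo.radius, a_mid + half, a_mid + 2 * np.pi - half, n_rest)

    shape = geo.image_size
    m_if = polyline_band_pixels(shape, interface, geo.width_px)
    m_rest = polyline_band_pixels(shape, rest, geo.width_px) & ~m_if

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    inside = (xx - geo.center[0]) ** 2 + (yy - geo.center[1]) ** 2 < geo.radius ** 2

    img = np.zeros(shape, dtype=float)
    img[inside] = geo.interior_intensity
    img[m_rest] = geo.membrane_intensity
    img[m_if] = enrichment_k * geo.membrane_intensity
    if noise == "poisson":
        img = rng.poisson(img).astype(float)
    elif noise is not None:
        raise ValueError(f"unknown noise model: {noise!r}")

    ann = ConjugateAnnotation(interface=interface, rest=rest, width_px=geo.width_px)
    return img, ann


def simulate_polarized_image(weights,
                             geometry: ConjugateGeometry | None = None,
                             roi_size_px: float = 50.0,
                             roi_offset_px: float | None = None,
                             noise: str | None = None,
                             rng: np.random.Generator | None = None
                             ) -> tuple[np.ndarray, ConjugateAnnotation]:
    """Render a permeabilized-stain image with known four-ROI weighting.

    ``weights`` are relative mean intensities for the (interface, away,
    side1, side2) ROI positions; uniform Gaussian-free blocks are painted so
    the expected four-ROI percentages are ``100 * w / sum(w)``.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be four non-negative values with positive sum")
    geo = geometry or ConjugateGeometry()
    rng = rng or np.random.default_rng()
    offset = roi_offset_px if roi_offset_px is not None else roi_size_px

    a_mid = np.deg2rad(geo.interface_angle_deg)
    u = np.array([np.cos(a_mid), np.sin(a_mid)])
    v = np.array([-u[1], u[0]])
    center = np.asarray(geo.center, dtype=float)

    img = np.zeros(geo.image_size, dtype=float)
    yy, xx = np.mgrid[0:geo.image_size[0], 0:geo.image_size[1]]
    half = roi_size_px / 2.0
    for wi, c in zip(w, [center + offset * u, center - offset * u,
                         center + offset * v, center - offset * v]):
        pu = (xx - c[0]) * u[0] + (yy - c[1]) * u[1]
        pv = (xx - c[0]) * v[0] + (yy - c[1]) * v[1]
        img[(np.abs(pu) <= half) & (np.abs(pv) <= half)] = wi * 100.0
    if noise == "poisson":
        img = rng.poisson(img).astype(float)
    elif noise is not None:
        raise ValueError(f"unknown noise model: {noise!r}")

    ann = ConjugateAnnotation(center=center, direction=u,
                              roi_size_px=roi_size_px, roi_offset_px=roi_offset_px)
    return img, ann
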