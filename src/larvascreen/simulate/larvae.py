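"""Rendering of single larvae as curved-capsule silhouettes.

A larva is drawn as the set of pixels within ``width/2`` of a quadratic
Bezier spine. With ``curvature = 0`` the shape is a stadium (rectangle plus
two half-discs), whose analytic area ``length*width + pi*width**2/4`` serves
as an oracle for the rasterisation. Larvae image dark against the food
background because bromophenol blue dye accumulates in the gut; the
``intensity_contrast`` field is the fractional darkening relative to the
local background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: spine sample density (points per pixel of arc length)
_SPINE_SAMPLES_PER_PX = 2.0


@dataclass(frozen=True)
class LarvaSpec:
    """Geometry and contrast of one rendered larva.

    ``length`` is the arc length of the spine in pixels; ``width`` the body
    diameter; ``curvature`` the perpendicular offset of the Bezier control
    point as a fraction of length (0 = straight, ~0.5 = strongly bent);
    ``position`` the (row, col) pixel centre of the spine; ``orientation``
    the spine direction in radians.
    """

    length: float
    width: float
    curvature: float = 0.0
    intensity_contrast: float = 0.35
    position: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not (self.length > 0 and self.width > 0):
            raise ValueError("larva length and width must be positive")
        if self.length <= self.width:
            raise ValueError("larva must be longer than it is wide")
        if not (0.0 < self.intensity_contrast < 1.0):
            raise ValueError("intensity_contrast must be in (0, 1)")

    @property
    def bounding_radius(self) -> float:
        """Radius of a disc around ``position`` guaranteed to contain the mask."""
        # chord <= arc length; sagitta of the quadratic spine is curvature*length/2
        return self.length / 2.0 + abs(self.curvature) * self.length / 2.0 + self.width / 2.0 + 1.0


@dataclass(frozen=True)
class LarvaRendering:
    """Binary mask of one larva plus its placement in the parent image."""

    mask: np.ndarray          # bool, local bounding box
    offset: tuple[int, int]   # (row, col) of mask[0, 0] in the parent image
    area: int                 # exact pixel count of the mask
    intensity_contrast: float


def _spine_points(spec: LarvaSpec) -> np.ndarray:
    """Sample the quadratic Bezier spine, rescaled to the requested arc length."""
    n = max(int(spec.length * _SPINE_SAMPLES_PER_PX), 8)
    t = np.linspace(0.0, 1.0, n)[:, None]
    # control polygon in a local frame: endpoints on the x axis, control
    # point lifted perpendicular to produce the bend
    half = spec.length / 2.0
    p0 = np.array([0.0, -half])
    p1 = np.array([spec.curvature * spec.length, 0.0])
    p2 = np.array([0.0, half])
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2  # (n, 2) as (y, x)
    # rescale so the polyline arc length equals spec.length exactly
    seg = np.diff(pts, axis=0)
    arc = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    pts *= spec.length / arc
    # rotate and translate into image coordinates
    c, s = np.cos(spec.orientation), np.sin(spec.orientation)
    rot = np.array([[c, -s], [s, c]])
    pts = pts @ rot.T
    pts += np.asarray(spec.position)
    return pts


def _dist_to_polyline(yy: np.ndarray, xx: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Distance from grid points to a polyline (min over segments, vectorised)."""
    p = np.stack([yy.ravel(), xx.ravel()], axis=1)  # (m, 2)
    a = pts[:-1]                                    # (k, 2)
    d = pts[1:] - a                                 # (k, 2)
    len2 = np.maximum(np.einsum("kj,kj->k", d, d), 1e-12)
    # projection parameter of every point on every segment
    diff = p[:, None, :] - a[None, :, :]            # (m, k, 2)
    t = np.clip(np.einsum("mkj,kj->mk", diff, d) / len2, 0.0, 1.0)
    closest = a[None, :, :] + t[..., None] * d[None, :, :]
    dist2 = np.sum((p[:, None, :] - closest) ** 2, axis=2)
    return np.sqrt(dist2.min(axis=1)).reshape(yy.shape)


def render_larva(spec: LarvaSpec) -> LarvaRendering:
    """Rasterise one larva to a binary mask over its local bounding box.

    The returned ``area`` (exact mask pixel count) is the ground truth used
    by the detection-accuracy oracles downstream.
    """
    pts = _spine_points(spec)
    r = spec.width / 2.0
    y0 = int(np.floor(pts[:, 0].min() - r)) - 1
    y1 = int(np.ceil(pts[:, 0].max() + r)) + 2
    x0 = int(np.floor(pts[:, 1].min() - r)) - 1
    x1 = int(np.ceil(pts[:, 1].max() + r)) + 2
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    mask = _dist_to_polyline(yy, xx, pts) <= r
    if not mask.any():
        raise ValueError("degenerate larva: empty mask after rasterisation")
    return LarvaRendering(mask=mask, offset=(y0, x0), area=int(mask.sum()),
                          intensity_contrast=spec.intensity_contrast)


def stamp_larva(image: np.ndarray, rendering: LarvaRendering,
                background_level: float | None = None) -> None:
    """Darken ``image`` in place under a rendered larva.

    The body is darkened by ``intensity_contrast`` times the local intensity
    (or ``background_level`` if given), emulating the dye-filled gut.
    """
    y0, x0 = rendering.offset
    h, w = rendering.mask.shape
    ys = slice(max(y0, 0), min(y0 + h, image.shape[0]))
    xs = slice(max(x0, 0), min(x0 + w, image.shape[1]))
    my = slice(ys.start - y0, ys.stop - y0)
    mx = slice(xs.start - x0, xs.stop - x0)
    sub = image[ys, xs]
    m = rendering.mask[my, mx]
    base = sub if background_level is None else background_level
    drop = rendering.intensity_contrast * (base[m] if background_level is None else background_level)
    sub[m] = sub[m] - drop
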