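"""Full-plate image synthesis with per-well ground truth.

Emulates the plate imager's single capture of a 96-well plate: a bright food
background (optionally with a gentle illumination gradient), dark well rims,
dye-darkened larvae floated to the focal plane, and the uneaten-food
artifact rendered as a broad grainy darkening of a well.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ..layout import N_COLS, N_ROWS, PlateLayout, well_name
from .larvae import LarvaRendering, LarvaSpec, render_larva, stamp_larva
from .models import ArtifactModel, SizeModel


@dataclass(frozen=True)
class PlateGeometry:
    """Pixel geometry of the rendered plate raster.

    Well (row, col) (0-based, A1 top-left) is centred at
    ``(margin + row*pitch, margin + col*pitch)``.
    """

    pitch: int = 140
    well_radius: int = 65
    margin: int = 90
    rim_width: int = 3
    rim_contrast: float = 0.45
    background_level: float = 0.75
    gradient_amplitude: float = 0.03   # peak-to-peak linear shading across the plate
    noise_sigma: float = 0.008

    def __post_init__(self) -> None:
        if self.pitch < 2 * (self.well_radius + self.rim_width):
            raise ValueError("overlapping well geometry: pitch too small for well radius")
        if self.margin < self.well_radius + self.rim_width:
            raise ValueError("margin must clear the outermost well rims")

    @property
    def image_shape(self) -> tuple[int, int]:
        return (2 * self.margin + (N_ROWS - 1) * self.pitch,
                2 * self.margin + (N_COLS - 1) * self.pitch)

    def well_center(self, row: int, col: int) -> tuple[int, int]:
        return (self.margin + row * self.pitch, self.margin + col * self.pitch)

    @property
    def inner_radius(self) -> float:
        """Radius of the usable well interior (inside the rim)."""
        return self.well_radius - self.rim_width - 1.0


def sample_well_specs(
    n: int,
    mean_area: float,
    cv: float,
    center: tuple[int, int],
    geometry: PlateGeometry,
    rng: np.random.Generator,
    intensity_contrast: float = 0.35,
    max_tries: int = 30,
) -> tuple[list[LarvaSpec], list[LarvaRendering]]:
    """Draw ``n`` non-overlapping larvae for one well.

    Per-larva areas are lognormal(mean_area, cv); shape parameters (aspect,
    curvature, pose) are sampled within the well interior. Placement is
    rejection-sampled so masks are pairwise disjoint (overlaps are accepted
    after ``max_tries`` failures, which is rare at default geometry).
    """
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean_area) - sigma2 / 2.0
    areas = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))
    inner = geometry.inner_radius

    def one(area: float) -> tuple[LarvaSpec, LarvaRendering]:
        aspect = rng.uniform(0.20, 0.26)
        # stadium area = L*W + pi*W^2/4 with W = aspect*L
        length = np.sqrt(area / (aspect + np.pi * aspect ** 2 / 4.0))
        width = aspect * length
        # keep the bounding disc inside the well interior, shrinking the bend
        # (never the body) if the well is tight
        curv = rng.uniform(0.0, 0.40)
        max_curv = max(0.0, (inner - width / 2.0 - 1.0 - length / 2.0) / (length / 2.0 + 1e-9))
        curv = min(curv, max_curv)
        theta = rng.uniform(0.0, 2 * np.pi)
        spec0 = LarvaSpec(length, width, curv, intensity_contrast, (0.0, 0.0), theta)
        slack = max(0.5, inner - spec0.bounding_radius)
        r = slack * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2 * np.pi)
        pos = (center[0] + r * np.sin(phi), center[1] + r * np.cos(phi))
        spec = dataclasses.replace(spec0, position=pos)
        return spec, render_larva(spec)

    for _ in range(max_tries):
        pairs = [one(a) for a in areas]
        if _disjoint([p[1] for p in pairs]):
            return [p[0] for p in pairs], [p[1] for p in pairs]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def _disjoint(rends: list[LarvaRendering]) -> bool:
    for i in range(len(rends)):
        for j in range(i + 1, len(rends)):
            if _masks_overlap(rends[i], rends[j]):
                return False
    return True


def _masks_overlap(a: LarvaRendering, b: LarvaRendering) -> bool:
    ay, ax = a.offset
    by, bx = b.offset
    y0 = max(ay, by)
    x0 = max(ax, bx)
    y1 = min(ay + a.mask.shape[0], by + b.mask.shape[0])
    x1 = min(ax + a.mask.shape[1], bx + b.mask.shape[1])
    if y0 >= y1 or x0 >= x1:
        return False
    sub_a = a.mask[y0 - ay:y1 - ay, x0 - ax:x1 - ax]
    sub_b = b.mask[y0 - by:y1 - by, x0 - bx:x1 - bx]
    return bool(np.any(sub_a & sub_b))


def _base_image(geometry: PlateGeometry, rng: np.random.Generator) -> np.ndarray:
    h, w = geometry.image_shape
    img = np.full((h, w), geometry.background_level, dtype=float)
    if geometry.gradient_amplitude:
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (0.6 * xx / max(w - 1, 1) + 0.4 * yy / max(h - 1, 1))
        img += geometry.gradient_amplitude * (ramp - 0.5)
    if geometry.noise_sigma:
        img += rng.normal(0.0, geometry.noise_sigma, size=img.shape)
    return img


def _draw_rims(img: np.ndarray, geometry: PlateGeometry) -> None:
    r_out = geometry.well_radius
    r_in = geometry.well_radius - geometry.rim_width
    side = 2 * r_out + 3
    yy, xx = np.mgrid[-r_out - 1:r_out + 2, -r_out - 1:r_out + 2]
    dist = np.hypot(yy, xx)
    ring = (dist <= r_out) & (dist >= r_in)
    drop = geometry.rim_contrast * geometry.background_level
    for r in range(N_ROWS):
        for c in range(N_COLS):
            cy, cx = geometry.well_center(r, c)
            sl = (slice(cy - r_out - 1, cy - r_out - 1 + side),
                  slice(cx - r_out - 1, cx - r_out - 1 + side))
            img[sl][ring] -= drop


def _stamp_food_blob(img: np.ndarray, center: tuple[int, int],
                     geometry: PlateGeometry, artifacts: ArtifactModel,
                     rng: np.random.Generator) -> None:
    """Broad grainy darkening emulating uneaten food suspended in a well."""
    R = geometry.well_radius
    cy = center[0] + rng.uniform(-0.3, 0.3) * R
    cx = center[1] + rng.uniform(-0.3, 0.3) * R
    side = 2 * R + 1
    yy, xx = np.mgrid[center[0] - R:center[0] + R + 1,
                      center[1] - R:center[1] + R + 1].astype(float)
    sigma = artifacts.food_blob_extent * R
    profile = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    grain = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (side, side)), 2.0)
    grain /= max(np.abs(grain).max(), 1e-9)
    field = profile * (1.0 + artifacts.food_grain * grain)
    inside = np.hypot(yy - center[0], xx - center[1]) <= geometry.inner_radius
    drop = artifacts.food_blob_contrast * geometry.background_level
    sl = (slice(center[0] - R, center[0] + R + 1),
          slice(center[1] - R, center[1] + R + 1))
    patch = img[sl]
    patch[inside] -= drop * field[inside]


def render_plate(
    layout: PlateLayout,
    specs: dict[tuple[int, int], list[LarvaSpec]],
    artifacts: ArtifactModel | None = None,
    rng: np.random.Generator | None = None,
    geometry: PlateGeometry = PlateGeometry(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a full plate image and its per-well ground truth.

    ``specs`` maps (row, col) to the larvae of that well (absolute image
    coordinates). Wells flagged with the low-DMSO artifact have their larvae
    enlarged by ``low_dmso_size_boost`` before rendering; wells flagged with
    high background receive a food blob. Ground truth records the rendered
    (union) pixel area per well and both artifact flags.

    Returns ``(image, truth)`` with image a float raster in [0, ~1].
    """
    artifacts = artifacts or ArtifactModel.none()
    rng = rng or np.random.default_rng(0)
    img = _base_image(geometry, rng)
    _draw_rims(img, geometry)

    records = []
    for _, wrow in layout.table.iterrows():
        r, c = int(wrow["row"]), int(wrow["col"])
        center = geometry.well_center(r, c)
        well_specs = list(specs.get((r, c), []))
        has_larvae = len(well_specs) > 0

        flag_low = has_larvae and rng.uniform() < artifacts.p_low_dmso \
            and wrow["dmso_pct"] > 0 and wrow["genotype"] == "hom"
        if flag_low:
            scale = np.sqrt(artifacts.low_dmso_size_boost)
            well_specs = [_refit(dataclasses.replace(s, length=s.length * scale,
                                                     width=s.width * scale),
                                 center, geometry)
                          for s in well_specs]
        flag_bg = has_larvae and rng.uniform() < artifacts.p_high_background

        covered = None
        for s in well_specs:
            dy = s.position[0] - center[0]
            dx = s.position[1] - center[1]
            if np.hypot(dy, dx) + s.bounding_radius > geometry.well_radius + 1:
                raise ValueError(
                    f"larva at {s.position} does not fit inside well {well_name(r, c)}")
            rend = render_larva(s)
            stamp_larva(img, rend, background_level=geometry.background_level)
            covered = _accumulate(covered, rend, geometry, center)
        true_area = int(covered.sum()) if covered is not None else 0

        if flag_bg:
            _stamp_food_blob(img, center, geometry, artifacts, rng)

        records.append({
            "plate": layout.plate_id, "row": r, "col": c,
            "well": wrow["well"], "role": wrow["role"],
            "compound_id": wrow["compound_id"], "substance": wrow["substance"],
            "dose_uM": wrow["dose_uM"], "dmso_pct": wrow["dmso_pct"],
            "n_larvae": len(well_specs), "true_area": true_area,
            "center_y": center[0], "center_x": center[1],
            "flag_high_bg": bool(flag_bg), "flag_low_dmso": bool(flag_low),
        })
    np.clip(img, 0.02, 1.0, out=img)
    return img, pd.DataFrame(records)


def _refit(spec: LarvaSpec, center: tuple[int, int],
           geometry: PlateGeometry) -> LarvaSpec:
    """Pull an enlarged larva back toward the well centre so it still fits."""
    dy = spec.position[0] - center[0]
    dx = spec.position[1] - center[1]
    dist = np.hypot(dy, dx)
    allowed = max(0.0, geometry.well_radius + 1 - spec.bounding_radius)
    if dist <= allowed or dist == 0.0:
        return spec
    f = allowed / dist
    return dataclasses.replace(spec, position=(center[0] + dy * f, center[1] + dx * f))


def _accumulate(covered, rend: LarvaRendering, geometry: PlateGeometry,
                center: tuple[int, int]):
    """Union of larval masks on a well-local canvas (ground-truth area)."""
    R = geometry.well_radius
    if covered is None:
        covered = np.zeros((2 * R + 1, 2 * R + 1), dtype=bool)
    oy = rend.offset[0] - (center[0] - R)
    ox = rend.offset[1] - (center[1] - R)
    h, w = rend.mask.shape
    ys = slice(max(oy, 0), min(oy + h, covered.shape[0]))
    xs = slice(max(ox, 0), min(ox + w, covered.shape[1]))
    covered[ys, xs] |= rend.mask[ys.start - oy:ys.stop - oy,
                                 xs.start - ox:xs.stop - ox]
    return covered


def simulate_plate_image(
    layout: PlateLayout,
    size_model: SizeModel = SizeModel(),
    artifacts: ArtifactModel | None = None,
    rng: np.random.Generator | None = None,
    geometry: PlateGeometry = PlateGeometry(),
    rescue_by_compound: dict[str, float] | None = None,
    larvae_per_well: int = 3,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample larvae from the size model for every well and render the plate."""
    rng = rng or np.random.default_rng(0)
    rescue_by_compound = rescue_by_compound or {}
    specs: dict[tuple[int, int], list[LarvaSpec]] = {}
    for _, wrow in layout.table.iterrows():
        r, c = int(wrow["row"]), int(wrow["col"])
        rescue = rescue_by_compound.get(wrow["compound_id"], 0.0)
        mean = size_model.mean_area(wrow["genotype"], wrow["dmso_pct"], rescue)
        sp, _ = sample_well_specs(larvae_per_well, mean, size_model.cv,
                                  geometry.well_center(r, c), geometry, rng)
        specs[(r, c)] = sp
    return render_plate(layout, specs, artifacts, rng, geometry)
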