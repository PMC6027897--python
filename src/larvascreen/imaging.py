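"""Larval detection in full-plate images.

The detection algorithm follows the screen's measurement principle: for each
well, build an estimate of what the well would look like if it were empty by
excluding pixels that are probably larvae (strong local gradients or
dye-dark intensities, dilated by a small margin) and interpolating across
the gaps; then segment the difference between the observed well and that
empty-well estimate, keeping connected components above a minimum area. The
per-well readout is the total segmented area in pixels.

A robust residual metric (scale of observed-minus-estimate outside the
excluded regions) accompanies every measurement; wells where uneaten food
raised the background stand out on this metric and are flagged for triage.

Coordinates are 0-based row-major pixels; well A1 is at the top-left.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve
from skimage import feature, filters, measure, morphology

from .layout import N_COLS, N_ROWS, well_name

#: fraction of the well radius kept for analysis (the outer ring is rim)
INTERIOR_FRACTION = 0.95


@dataclass(frozen=True)
class GridSpec:
    """Nominal geometry of the 8x12 well grid in a plate image."""

    pitch: int = 140
    well_radius: int = 65
    margin: int = 90
    n_rows: int = N_ROWS
    n_cols: int = N_COLS

    @classmethod
    def from_geometry(cls, geometry) -> "GridSpec":
        """Build from any object exposing pitch/well_radius/margin."""
        return cls(pitch=geometry.pitch, well_radius=geometry.well_radius,
                   margin=geometry.margin)


@dataclass(frozen=True)
class WellRegion:
    """One located well: centre, radius and its sub-raster bounds."""

    well: str
    row: int
    col: int
    center: tuple[int, int]   # (y, x) pixels
    radius: int

    def extract(self, image: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        """Square patch around the well and the patch origin in the image."""
        R = self.radius
        y0, x0 = self.center[0] - R, self.center[1] - R
        if y0 < 0 or x0 < 0 or y0 + 2 * R + 1 > image.shape[0] \
                or x0 + 2 * R + 1 > image.shape[1]:
            raise ValueError(f"well {self.well} region falls outside the image")
        return image[y0:y0 + 2 * R + 1, x0:x0 + 2 * R + 1], (y0, x0)


@dataclass
class BackgroundModel:
    """Empty-well estimate for one well patch."""

    estimate: np.ndarray            # same shape as the patch
    excluded_mask: np.ndarray       # pixels treated as probable larvae
    interior_mask: np.ndarray       # analysed disc (rim ring removed)
    residual_metric: float          # robust scale of (observed - estimate)


@dataclass
class WellMeasurement:
    """Detected larval components and total area for one well."""

    well: str
    row: int
    col: int
    components: list[dict] = field(default_factory=list)
    total_area: int = 0
    n_components: int = 0
    residual_metric: float = 0.0


# ---------------------------------------------------------------------------
# grid location


def _ring_template(radius: int, width: int = 4) -> np.ndarray:
    side = 2 * (radius + 2) + 1
    yy, xx = np.mgrid[:side, :side] - (radius + 2)
    dist = np.hypot(yy, xx)
    return np.where((dist <= radius) & (dist >= radius - width), -1.0, 0.0)


def locate_well_grid(image: np.ndarray, geometry: GridSpec,
                     min_score: float = 0.25) -> list[WellRegion]:
    """Locate the 96 wells by matched filtering against a rim ring.

    A normalised cross-correlation map against a dark-ring template is folded
    over all feasible grid offsets; the best offset is refined per well. A
    blank image (no resolvable rims) raises, as does any grid whose wells do
    not all fit in the image; wells whose individual match is too weak are
    reported in the error message.
    """
    image = np.asarray(image, dtype=float)
    g = geometry
    span_y = (g.n_rows - 1) * g.pitch
    span_x = (g.n_cols - 1) * g.pitch
    if image.shape[0] < span_y + 2 * g.well_radius \
            or image.shape[1] < span_x + 2 * g.well_radius:
        raise ValueError("image smaller than the expected well grid")

    resp = feature.match_template(image, _ring_template(g.well_radius),
                                  pad_input=True)
    ny = image.shape[0] - span_y
    nx = image.shape[1] - span_x
    folded = np.zeros((ny, nx))
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            folded += resp[r * g.pitch:r * g.pitch + ny,
                           c * g.pitch:c * g.pitch + nx]
    folded /= g.n_rows * g.n_cols
    y0, x0 = np.unravel_index(np.argmax(folded), folded.shape)
    if folded[y0, x0] < min_score:
        raise ValueError("no well grid found: rim response below threshold "
                         f"({folded[y0, x0]:.3f} < {min_score})")

    regions, missing = [], []
    win = max(3, g.pitch // 20)
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            cy, cx = y0 + r * g.pitch, x0 + c * g.pitch
            ys = slice(max(cy - win, 0), min(cy + win + 1, image.shape[0]))
            xs = slice(max(cx - win, 0), min(cx + win + 1, image.shape[1]))
            local = resp[ys, xs]
            dy, dx = np.unravel_index(np.argmax(local), local.shape)
            score = local[dy, dx]
            if score < min_score * 0.8:
                missing.append(well_name(r, c))
                continue
            regions.append(WellRegion(well_name(r, c), r, c,
                                      (ys.start + dy, xs.start + dx),
                                      g.well_radius))
    if missing:
        raise ValueError(f"fewer than 96 resolvable wells; missing: {missing}")
    return regions


# ---------------------------------------------------------------------------
# empty-well background estimation


def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def _harmonic_infill(values: np.ndarray, fill: np.ndarray,
                     domain: np.ndarray) -> np.ndarray:
    """Diffusion (harmonic) interpolation of ``values`` over ``fill``.

    Solves the fixed point of iterative neighbour-mean infill exactly:
    Laplace's equation on the filled pixels with Dirichlet data from kept
    domain pixels and reflecting boundaries at the domain edge. Linear
    backgrounds are reproduced exactly away from the domain boundary.
    """
    known = domain & ~fill
    if not known.any():
        raise ValueError("cannot interpolate: exclusion covers the entire well")
    est = values.astype(float).copy()
    n = int(fill.sum())
    if n == 0:
        return est
    idx = np.full(values.shape, -1, dtype=int)
    idx[fill] = np.arange(n)
    rows, cols, data = [], [], []
    b = np.zeros(n)
    deg = np.zeros(n)
    fy, fx = np.nonzero(fill)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ny, nx = fy + dy, fx + dx
        ok = (ny >= 0) & (ny < values.shape[0]) & (nx >= 0) & (nx < values.shape[1])
        ok &= domain[ny % values.shape[0], nx % values.shape[1]]
        i = idx[fy[ok], fx[ok]]
        j = idx[ny[ok], nx[ok]]
        deg_add = np.zeros(n)
        np.add.at(deg_add, i, 1.0)
        deg += deg_add
        unknown_nb = j >= 0
        rows.extend(i[unknown_nb])
        cols.extend(j[unknown_nb])
        data.extend(-np.ones(int(unknown_nb.sum())))
        kn = ~unknown_nb
        np.add.at(b, i[kn], values[ny[ok][kn], nx[ok][kn]])
    if np.any(deg == 0):
        # isolated filled pixels with no in-domain neighbours: use the median
        est[fill] = np.median(values[known])
        solvable = deg > 0
        if not solvable.any():
            return est
    A = sparse.coo_matrix(
        (np.concatenate([deg, np.asarray(data)]),
         (np.concatenate([np.arange(n), np.asarray(rows, dtype=int)]),
          np.concatenate([np.arange(n), np.asarray(cols, dtype=int)]))),
        shape=(n, n)).tocsr()
    # guard against singular blocks (unknown components detached from data)
    diag_fix = sparse.diags((deg == 0).astype(float) * 1.0)
    sol = spsolve(A + diag_fix, b + (deg == 0) * np.median(values[known]))
    if not np.all(np.isfinite(sol)):
        raise ValueError("cannot interpolate: background system is singular")
    est[fill] = sol
    return est


def _masked_gaussian(values: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    num = ndimage.gaussian_filter(np.where(mask, values, 0.0), sigma)
    den = ndimage.gaussian_filter(mask.astype(float), sigma)
    out = values.copy()
    good = mask & (den > 1e-9)
    out[good] = num[good] / den[good]
    return out


def estimate_empty_background(
    patch: np.ndarray,
    radius: float | None = None,
    edge_margin: int = 3,
    gradient_k: float = 5.0,
    dark_k: float = 4.0,
    smooth_sigma: float = 2.5,
) -> BackgroundModel:
    """Estimate what one well would look like when empty.

    Probable-larva pixels are excluded by two robust rules (local gradient
    magnitude above median + ``gradient_k`` * MAD-sigma; intensity below
    median - ``dark_k`` * MAD-sigma), dilated by ``edge_margin``; the gaps
    are closed by diffusion interpolation and the result lightly smoothed.
    Both rules scale with the image, so the estimate is equivariant under
    global intensity rescaling.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.size == 0:
        raise ValueError("empty well sub-raster")
    h, w = patch.shape
    if radius is None:
        radius = (min(h, w) - 1) / 2.0
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    interior = np.hypot(yy - cy, xx - cx) <= INTERIOR_FRACTION * radius

    grad = filters.sobel(patch)
    gvals = grad[interior]
    g_thr = np.median(gvals) + gradient_k * 1.4826 * np.median(
        np.abs(gvals - np.median(gvals)))
    ivals = patch[interior]
    i_med = np.median(ivals)
    i_sig = _robust_sigma(ivals)
    excl = (grad > g_thr) | (patch < i_med - dark_k * max(i_sig, 1e-12))
    excl &= interior
    if edge_margin > 0:
        excl = morphology.dilation(excl, morphology.disk(edge_margin))
        excl &= interior
    if excl.all() or not (interior & ~excl).any():
        raise ValueError("cannot interpolate: exclusion covers the entire well")

    est = _harmonic_infill(patch, excl, interior)
    if smooth_sigma > 0:
        est = _masked_gaussian(est, interior, smooth_sigma)

    # residual scale outside detections: strong-difference areas (what the
    # detector will select) are removed, everything else in the interior —
    # including the soft skirt of any food blob — contributes
    diff = patch - est
    kept = interior & ~excl
    sigma0 = _robust_sigma(diff[kept])
    strong = np.abs(diff) > 5.0 * max(sigma0, 1e-12)
    residual = _robust_sigma(diff[interior & ~strong])
    return BackgroundModel(estimate=est, excluded_mask=excl,
                           interior_mask=interior, residual_metric=residual)


# ---------------------------------------------------------------------------
# larval detection


def detect_larvae(
    patch: np.ndarray,
    bg: BackgroundModel,
    diff_threshold: float | None = None,
    min_area: int = 25,
    threshold_k: float = 5.0,
) -> WellMeasurement:
    """Segment larvae as high-difference components against the empty-well estimate.

    ``diff_threshold`` defaults to ``threshold_k`` times the MAD-based robust
    sigma of the difference image over the well interior. Components touching
    the rim are kept; the rim ring itself is outside the analysed interior.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape != bg.estimate.shape:
        raise ValueError("background estimate does not cover the well patch")
    diff = np.abs(patch - bg.estimate)
    if diff_threshold is None:
        diff_threshold = max(threshold_k * _robust_sigma(diff[bg.interior_mask]),
                             1e-9)
    if diff_threshold <= 0:
        raise ValueError("diff_threshold must be positive")

    labels = measure.label(( diff > diff_threshold) & bg.interior_mask,
                           connectivity=2)
    meas = WellMeasurement(well="", row=-1, col=-1,
                           residual_metric=bg.residual_metric)
    for prop in measure.regionprops(labels, intensity_image=diff):
        if prop.area < min_area:
            continue
        meas.components.append({
            "area": int(prop.area),
            "centroid": tuple(float(v) for v in prop.centroid),
            "mean_diff": float(prop.intensity_mean),
        })
    meas.components.sort(key=lambda c: -c["area"])
    meas.n_components = len(meas.components)
    meas.total_area = int(sum(c["area"] for c in meas.components))
    return meas


def flag_high_background(measurement: WellMeasurement,
                         residual_cutoff: float) -> bool:
    """True iff the well's background residual strictly exceeds the cutoff."""
    return measurement.residual_metric > residual_cutoff


def clean_residual_cutoff(residuals, q: float = 0.99) -> float:
    """Default flagging cutoff: the ``q`` quantile of clean-well residuals."""
    residuals = np.asarray(list(residuals), dtype=float)
    if residuals.size == 0:
        raise ValueError("need at least one clean residual")
    return float(np.quantile(residuals, q))


# ---------------------------------------------------------------------------
# plate-level convenience


def measure_plate(
    image: np.ndarray,
    geometry: GridSpec,
    plate_id: str = "",
    diff_threshold: float | None = None,
    min_area: int = 25,
    residual_cutoff: float | None = None,
    **bg_kwargs,
) -> pd.DataFrame:
    """Run grid location, background estimation and detection on a plate image.

    Returns one row per well: plate, row, col, well, n_components,
    total_area_px, residual_metric and (if ``residual_cutoff`` is given)
    flag_high_bg.
    """
    regions = locate_well_grid(image, geometry)
    rows = []
    for reg in regions:
        patch, _ = reg.extract(image)
        bg = estimate_empty_background(patch, radius=reg.radius, **bg_kwargs)
        m = detect_larvae(patch, bg, diff_threshold=diff_threshold,
                          min_area=min_area)
        rec = {"plate": plate_id, "row": reg.row, "col": reg.col,
               "well": reg.well, "n_components": m.n_components,
               "total_area_px": m.total_area,
               "residual_metric": m.residual_metric}
        if residual_cutoff is not None:
            rec["flag_high_bg"] = m.residual_metric > residual_cutoff
        rows.append(rec)
    return pd.DataFrame(rows)


def read_plate_image(path) -> np.ndarray:
    """Read a TIFF/PNG plate image to a float array in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    arr = arr.astype(float)
    if arr.max() > 1.0:
        arr /= np.iinfo(np.uint16).max if arr.max() > 255 else 255.0
    return arr


def write_plate_image(path, image: np.ndarray) -> None:
    """Write a float image as 16-bit grayscale TIFF (or 8-bit PNG by suffix)."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if str(path).lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, (arr * np.iinfo(np.uint16).max).astype(np.uint16))
    else:
        iio.imwrite(path, (arr * 255).astype(np.uint8))
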