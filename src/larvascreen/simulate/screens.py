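"""Area-level simulation of a full triplicate screen (no image rendering).

This is the fast path used to exercise plate QC, Z-scoring, hit calling and
triage at scale: well areas are drawn directly from the size model instead of
being rendered and re-detected. The same compound map is shared by all
replicates; artifact wells are sampled independently per replicate, as they
would be in the real screen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..layout import PlateLayout, default_screen_layout
from .models import ArtifactModel, ScreenConfig, SizeModel

AREA_COLUMNS = ["plate", "row", "col", "well", "role", "compound_id", "substance",
                "dose_uM", "dmso_pct", "replicate", "true_area", "area",
                "flag_high_bg", "flag_low_dmso"]


def make_library(config: ScreenConfig, duplicated_substances: int = 1) -> list[list[tuple[str, str]]]:
    """Compound map shared by all replicates: one id/substance list per plate.

    ``duplicated_substances`` substances are dispensed into two wells each
    (the screened library contained one such duplicate), exercising the
    well-keyed bookkeeping downstream.
    """
    n = config.n_plates * config.n_test_wells_per_plate
    ids = [f"C{i + 1:04d}" for i in range(n)]
    substances = [f"SUBSTANCE-{i + 1:04d}" for i in range(n)]
    for k in range(min(duplicated_substances, n // 2)):
        substances[n - 1 - k] = substances[k]  # same substance, two wells
    pairs = list(zip(ids, substances))
    per = config.n_test_wells_per_plate
    return [pairs[p * per:(p + 1) * per] for p in range(config.n_plates)]


def plate_rng(config: ScreenConfig, replicate: int, plate: int) -> np.random.Generator:
    """Documented substream scheme: one generator per (replicate, plate)."""
    return np.random.default_rng([config.rng_seed, replicate, plate])


def _lognormal(mean: float, cv: float, size: int, rng: np.random.Generator) -> np.ndarray:
    sigma2 = np.log1p(cv ** 2)
    return np.exp(rng.normal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), size=size))


def simulate_screen_areas(
    config: ScreenConfig,
    size_model: SizeModel = SizeModel(),
    artifacts: ArtifactModel | None = None,
    library: list[list[tuple[str, str]]] | None = None,
    rescue_by_compound: dict[str, float] | None = None,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate per-well area tables for every replicate of the screen.

    Returns ``(tables, truth)``: one DataFrame per replicate (columns
    ``AREA_COLUMNS``) and their concatenation as the ground-truth table.
    ``area`` is the observable readout (artifact effects applied);
    ``true_area`` is the artifact-free summed larval area. Compounds in
    ``config.true_hit_ids`` receive ``size_model.hit_rescue`` unless an
    explicit per-compound rescue map is given.
    """
    artifacts = artifacts or ArtifactModel.none()
    library = library if library is not None else make_library(config)
    if len(library) != config.n_plates:
        raise ValueError("library must provide one compound list per plate")
    if rescue_by_compound is None:
        rescue_by_compound = {cid: size_model.hit_rescue for cid in config.true_hit_ids}

    # compounds whose wells retain uneaten food do so in every replicate:
    # the propensity is a property of the compound, not of one dispense
    all_ids = [cid for plate in library for cid, _ in plate if cid]
    prone_rng = np.random.default_rng([config.rng_seed, 999_983])
    n_prone = int(round(artifacts.food_prone_fraction * len(all_ids)))
    food_prone = set(prone_rng.choice(all_ids, size=n_prone, replace=False)) \
        if n_prone else set()

    # reproducibly toxic compounds stunt larvae in every replicate (hits are
    # excluded from the draw)
    tox_rng = np.random.default_rng([config.rng_seed, 999_979])
    candidates = [cid for cid in all_ids if cid not in set(config.true_hit_ids)]
    n_tox = int(round(config.toxic_fraction * len(all_ids)))
    lo, hi = config.toxic_size_range
    toxic_factor = {cid: float(f) for cid, f in zip(
        tox_rng.choice(candidates, size=min(n_tox, len(candidates)), replace=False),
        tox_rng.uniform(lo, hi, size=min(n_tox, len(candidates))))}

    tables = []
    for rep in range(1, config.n_replicates + 1):
        frames = []
        for p in range(config.n_plates):
            layout = default_screen_layout(f"P{p + 1:02d}", library[p])
            frames.append(_simulate_plate_areas(
                layout, rep, config, size_model, artifacts,
                rescue_by_compound, food_prone, toxic_factor,
                plate_rng(config, rep, p)))
        tables.append(pd.concat(frames, ignore_index=True))
    truth = pd.concat(tables, ignore_index=True)
    return tables, truth


def _simulate_plate_areas(layout: PlateLayout, rep: int, config: ScreenConfig,
                          size_model: SizeModel, artifacts: ArtifactModel,
                          rescue: dict[str, float], food_prone: set[str],
                          toxic_factor: dict[str, float],
                          rng: np.random.Generator) -> pd.DataFrame:
    tbl = layout.table.copy()
    k = config.larvae_per_well
    areas = np.zeros(len(tbl))
    for i, wrow in enumerate(tbl.itertuples(index=False)):
        mean = size_model.mean_area(wrow.genotype, wrow.dmso_pct,
                                    rescue.get(wrow.compound_id, 0.0))
        mean *= toxic_factor.get(wrow.compound_id, 1.0)
        areas[i] = _lognormal(mean, size_model.cv, k, rng).sum()

    flag_low = (rng.uniform(size=len(tbl)) < artifacts.p_low_dmso) \
        & (tbl["dmso_pct"].to_numpy() > 0) & (tbl["genotype"] == "hom").to_numpy()
    p_bg = np.where(tbl["compound_id"].isin(food_prone),
                    artifacts.p_high_background_prone,
                    artifacts.p_high_background)
    flag_bg = rng.uniform(size=len(tbl)) < p_bg

    observed = areas.copy()
    observed[flag_low] *= artifacts.low_dmso_size_boost
    n_bg = int(flag_bg.sum())
    if n_bg:
        observed[flag_bg] += artifacts.food_area_inflation_px * rng.lognormal(0.0, 0.3, n_bg)

    out = tbl[["row", "col", "well", "role", "compound_id", "substance",
               "dose_uM", "dmso_pct"]].copy()
    out.insert(0, "plate", layout.plate_id)
    out["replicate"] = rep
    out["true_area"] = areas
    out["area"] = observed
    out["flag_high_bg"] = flag_bg
    out["flag_low_dmso"] = flag_low
    return out[AREA_COLUMNS]
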