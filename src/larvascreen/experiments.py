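"""Seeded end-to-end experiments over the synthetic screen.

Each function generates its own data, runs the relevant pipeline stage and
returns a small summary dict. They are the computations behind the analysis
scripts and the reproducibility checks, kept in the library so tests and
scripts run exactly the same code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import imaging
from . import screen_stats as ss
from . import triage as tr
from .devassay import _four_pl, fit_dose_response
from .layout import N_COLS, N_ROWS, PlateLayout, well_name
from .simulate import (ArtifactModel, PlateGeometry, ScreenConfig, SizeModel,
                       make_library, simulate_plate_image,
                       simulate_screen_areas)


def two_genotype_layout(plate_id: str = "RATIO",
                        dmso_pct: float = 0.0) -> PlateLayout:
    """Half-control, half-mutant plate: heterozygotes in columns 1-6,
    homozygotes in columns 7-12 (48 wells per genotype, no compounds)."""
    rows = []
    for r in range(N_ROWS):
        for c in range(N_COLS):
            het = c < N_COLS // 2
            rows.append({
                "row": r, "col": c, "well": well_name(r, c),
                "role": "POS1" if het else "NEG",
                "compound_id": "", "substance": "", "dose_uM": 0.0,
                "dmso_pct": dmso_pct, "genotype": "het" if het else "hom",
            })
    return PlateLayout(plate_id, pd.DataFrame(rows))


def detection_ratio_experiment(seed: int, size_model: SizeModel = SizeModel(),
                               geometry: PlateGeometry = PlateGeometry()) -> dict:
    """Recover the mutant/control mean-area ratio through the full imaging path.

    Renders one plate with 48 untreated heterozygote and 48 untreated
    homozygote wells (3 larvae each; true mean-area ratio =
    ``size_model.genotype_ratio``), locates the grid, estimates backgrounds,
    detects larvae, and reports the recovered ratio of group mean areas in
    percent.
    """
    layout = two_genotype_layout()
    rng = np.random.default_rng([int(seed), 7])
    img, truth = simulate_plate_image(layout, size_model, ArtifactModel.none(),
                                      rng, geometry)
    meas = imaging.measure_plate(img, imaging.GridSpec.from_geometry(geometry))
    m = meas.merge(truth[["row", "col"]].join(layout.table["genotype"]),
                   on=["row", "col"])
    mean_hom = m.loc[m["genotype"] == "hom", "total_area_px"].mean()
    mean_het = m.loc[m["genotype"] == "het", "total_area_px"].mean()
    truth_hom = truth.loc[layout.table["genotype"].eq("hom").to_numpy(), "true_area"].mean()
    truth_het = truth.loc[layout.table["genotype"].eq("het").to_numpy(), "true_area"].mean()
    return {
        "ratio_pct": 100.0 * mean_hom / mean_het,
        "true_ratio_pct": 100.0 * truth_hom / truth_het,
        "n_wells_per_group": int((m["genotype"] == "hom").sum()),
    }


def detection_oracle_experiment(seed: int, n_plates: int = 3,
                                geometry: PlateGeometry = PlateGeometry()) -> dict:
    """Detected vs ground-truth areas over >= 200 wells spanning the size range.

    Plates use the standard screen layout (well means span homozygote+vehicle
    through heterozygote), artifact-free. Reports the median relative area
    error and the Spearman rank correlation of detected vs true area.
    """
    from scipy.stats import spearmanr

    from .layout import default_screen_layout

    det, true = [], []
    for p in range(n_plates):
        layout = default_screen_layout(f"OR{p}",
                                       [(f"C{p}_{i}", "") for i in range(80)])
        rng = np.random.default_rng([int(seed), 11, p])
        img, truth = simulate_plate_image(layout, SizeModel(),
                                          ArtifactModel.none(), rng, geometry)
        meas = imaging.measure_plate(img, imaging.GridSpec.from_geometry(geometry))
        m = meas.merge(truth[["row", "col", "true_area"]], on=["row", "col"])
        det.extend(m["total_area_px"]); true.extend(m["true_area"])
    det = np.asarray(det, float)
    true = np.asarray(true, float)
    ok = true > 0
    rel = np.abs(det[ok] - true[ok]) / true[ok]
    return {
        "n_wells": int(ok.sum()),
        "median_rel_error": float(np.median(rel)),
        "rank_correlation": float(spearmanr(det[ok], true[ok]).statistic),
    }


def zprime_experiment(seed: int, n_plates: int = 32) -> dict:
    """Fraction of plates with Z' > 0 on a default triplicate screen."""
    cfg = ScreenConfig(n_plates=n_plates, rng_seed=int(seed) % 2 ** 31)
    _, truth = simulate_screen_areas(cfg)
    ps = ss.screen_plate_stats(truth)
    return {"n_plates": len(ps),
            "frac_zprime_positive": float((ps["zprime"] > 0).mean()),
            "median_zprime": float(ps["zprime"].median())}


def _screen_with_hits(seed: int, n_plates: int = 8, n_hits: int = 8,
                      rescue_range: tuple[float, float] = (0.3, 0.9)):
    cfg0 = ScreenConfig(n_plates=n_plates)
    lib = make_library(cfg0)
    ids = [cid for plate in lib for cid, _ in plate]
    rng = np.random.default_rng([int(seed), 23])
    hits = [str(h) for h in rng.choice(ids, size=n_hits, replace=False)]
    rescues = {h: float(r) for h, r in
               zip(hits, rng.uniform(*rescue_range, size=n_hits))}
    cfg = ScreenConfig(n_plates=n_plates, true_hit_ids=tuple(hits),
                       rng_seed=int(seed) % 2 ** 31)
    tables, truth = simulate_screen_areas(cfg, SizeModel(), ArtifactModel(),
                                          library=lib,
                                          rescue_by_compound=rescues)
    merged = ss.merge_replicates([ss.zscore_screen(t) for t in tables])
    return merged, hits, rescues


def r2_enrichment_experiment(seed: int, n_runs: int = 10) -> dict:
    """How often the extreme-subset replicate R^2 beats the full-set R^2.

    Each run simulates a triplicate screen with >= 1% planted true hits of
    mixed strength plus the default artifact and toxicity processes, then
    compares mean pairwise R^2 in full vs extreme (|Z| > 2 in either member)
    mode.
    """
    wins = 0
    fulls, exts = [], []
    for k in range(n_runs):
        merged, _, _ = _screen_with_hits(int(seed) * 1000 + k)
        corr = ss.replicate_correlations(merged)
        fulls.append(corr["r2_full"].mean())
        exts.append(corr["r2_extreme"].mean())
        wins += int(exts[-1] > fulls[-1])
    return {"n_runs": n_runs, "frac_extreme_wins": wins / n_runs,
            "mean_r2_full": float(np.mean(fulls)),
            "mean_r2_extreme": float(np.mean(exts))}


def hit_recovery_experiment(seed: int, n_runs: int = 20) -> dict:
    """Recall of planted strong hits (rescue >= 0.8) under the 2-of-3 rule,
    and triage precision before vs after artifact filtering."""
    recalls, prec_gain = [], 0
    for k in range(n_runs):
        merged, hits, _ = _screen_with_hits(int(seed) * 1000 + k,
                                            rescue_range=(0.8, 1.0))
        pre = tr.call_prehits(merged)
        called = set(pre["compound_id"])
        recalls.append(len(called & set(hits)) / len(hits))
        report = tr.apply_artifact_filters(pre)
        clean = set(report.prehits.loc[report.prehits["status"] == "clean",
                                       "compound_id"])
        p_before = len(called & set(hits)) / max(len(called), 1)
        p_after = len(clean & set(hits)) / max(len(clean), 1)
        prec_gain += int(p_after > p_before)
    return {"n_runs": n_runs, "mean_recall": float(np.mean(recalls)),
            "frac_precision_improved": prec_gain / n_runs}


def ic50_shift_experiment(seed: int, n_sims: int = 20,
                          true_ratio: float = 0.1,
                          doses=(0.0, 1.0, 5.0, 10.0, 25.0),
                          n_larvae_per_dose: int = 20,
                          noise_cv: float = 0.05) -> dict:
    """Fitted mutant/control IC50 ratio on synthetic sensitisation curves.

    Mimics the proteasome-inhibitor design: per-larva sizes at the standard
    dose ladder for a sensitive (IC50 = ``true_ratio`` x 10 uM) and a control
    (IC50 = 10 uM) genotype, 4PL fits to both, ratio of fitted IC50s.
    """
    doses = np.repeat(np.asarray(doses, float), n_larvae_per_dose)
    ratios = []
    for k in range(n_sims):
        rng = np.random.default_rng([int(seed), 31, k])
        sens = _four_pl(doses, 140.0, 10.0, 10.0 * true_ratio, 1.5) \
            * rng.lognormal(0.0, noise_cv, doses.size)
        ctrl = _four_pl(doses, 280.0, 20.0, 10.0, 1.5) \
            * rng.lognormal(0.0, noise_cv, doses.size)
        f_sens = fit_dose_response(doses, sens)
        f_ctrl = fit_dose_response(doses, ctrl)
        ratios.append(f_sens.ic50 / f_ctrl.ic50)
    ratios = np.asarray(ratios)
    return {"n_sims": n_sims,
            "median_ic50_ratio": float(np.median(ratios)),
            "median_rel_error": float(np.median(np.abs(ratios - true_ratio)
                                                / true_ratio))}
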