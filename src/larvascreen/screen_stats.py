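"""Plate quality control and hit-calling statistics.

Per plate: the Z-prime factor ``1 - 3*(sd_pos + sd_neg)/|mu_pos - mu_neg|``
between positive and negative control wells (Z' > 0 marks a screenable
window), and per-well Z-scores of the test wells against the same-plate
negative controls, ``Z = (x - mu_NEG) / sd_NEG``. Replicate Z-tables are
merged keyed by well-level compound id — a substance dispensed in two wells
stays as two rows — and replicate agreement is summarised by pairwise R^2,
either over all test wells or over the extreme subset (|Z| > 2 in at least
one member of the pair), where true modifiers dominate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout import Role


@dataclass(frozen=True)
class PlateStats:
    """Control summary and Z-prime for one plate."""

    plate_id: str
    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    zprime: float


def zprime(pos_areas, neg_areas) -> float:
    """Z-prime factor from control samples (sample means and SDs, ddof=1)."""
    pos = np.asarray(pos_areas, dtype=float)
    neg = np.asarray(neg_areas, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two wells in each control group")
    return zprime_from_moments(pos.mean(), pos.std(ddof=1),
                               neg.mean(), neg.std(ddof=1))


def zprime_from_moments(mu_pos: float, sd_pos: float,
                        mu_neg: float, sd_neg: float) -> float:
    """Z-prime from supplied group moments: 1 - 3(sd_pos+sd_neg)/|mu_pos-mu_neg|."""
    if mu_pos == mu_neg:
        raise ValueError("no separation: control group means are equal")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / abs(mu_pos - mu_neg)


def zscore_wells(test_areas, neg_areas, robust: bool = False) -> np.ndarray:
    """Z-score test wells against same-plate negative controls.

    ``robust=True`` substitutes median/1.4826*MAD for mean/SD (not the
    default scale of the screen).
    """
    x = np.asarray(test_areas, dtype=float)
    neg = np.asarray(neg_areas, dtype=float)
    if neg.size < 2:
        raise ValueError("need at least two negative-control wells")
    if robust:
        center = np.median(neg)
        scale = 1.4826 * np.median(np.abs(neg - center))
    else:
        center = neg.mean()
        scale = neg.std(ddof=1)
    if scale == 0:
        raise ValueError("negative-control scale is zero")
    return (x - center) / scale


def plate_stats(areas: pd.DataFrame, plate_id: str | None = None,
                positive_role: Role | str = Role.POS1,
                value: str = "area") -> PlateStats:
    """Z-prime summary of one plate's well-area table.

    The positive group defaults to control group 1 (heterozygotes + vehicle);
    group 2 (homozygotes without vehicle) is selectable via ``positive_role``.
    """
    if plate_id is not None:
        areas = areas[areas["plate"] == plate_id]
    else:
        ids = areas["plate"].unique()
        if len(ids) != 1:
            raise ValueError("plate_id required for multi-plate tables")
        plate_id = ids[0]
    pos = areas.loc[areas["role"] == Role(positive_role).value, value].to_numpy()
    neg = areas.loc[areas["role"] == Role.NEG.value, value].to_numpy()
    return PlateStats(plate_id, float(pos.mean()), float(pos.std(ddof=1)),
                      float(neg.mean()), float(neg.std(ddof=1)),
                      zprime(pos, neg))


def screen_plate_stats(areas: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Per-plate Z-prime table for a (possibly multi-replicate) area table."""
    keys = ["replicate", "plate"] if "replicate" in areas.columns else ["plate"]
    rows = []
    for key, sub in areas.groupby(keys, sort=True):
        ps = plate_stats(sub, plate_id=sub["plate"].iloc[0], **kwargs)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(plate=ps.plate_id, zprime=ps.zprime, mu_pos=ps.mu_pos,
                   sd_pos=ps.sd_pos, mu_neg=ps.mu_neg, sd_neg=ps.sd_neg)
        rows.append(rec)
    return pd.DataFrame(rows)


def zscore_screen(areas: pd.DataFrame, value: str = "area",
                  robust: bool = False) -> pd.DataFrame:
    """Per-test-well Z-scores for every plate of one replicate's area table.

    Returns rows: plate, row, col, well, compound_id, substance, z plus any
    artifact flag columns present in the input.
    """
    out = []
    flag_cols = [c for c in ("flag_high_bg", "flag_low_dmso") if c in areas.columns]
    for plate_id, sub in areas.groupby("plate", sort=True):
        neg = sub.loc[sub["role"] == Role.NEG.value, value].to_numpy()
        test = sub[sub["role"] == Role.TEST.value]
        z = zscore_wells(test[value].to_numpy(), neg, robust=robust)
        frame = test[["plate", "row", "col", "well", "compound_id", "substance"]
                     + flag_cols].copy()
        frame["z"] = z
        out.append(frame)
    return pd.concat(out, ignore_index=True)


def merge_replicates(ztables: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-replicate Z-tables into one row per library well.

    Rows are keyed by ``compound_id`` (well-level identity: duplicate library
    entries of one substance remain distinct rows sharing the substance
    name). A compound absent from a replicate keeps NaN in that column —
    missing values are never imputed.
    """
    if not ztables:
        return pd.DataFrame(columns=["compound_id", "substance"])
    merged = None
    for i, tbl in enumerate(ztables, start=1):
        cols = {"z": f"z_rep{i}", "well": f"well_rep{i}",
                "plate": f"plate_rep{i}"}
        for fc in ("flag_high_bg", "flag_low_dmso"):
            if fc in tbl.columns:
                cols[fc] = f"{fc}_rep{i}"
        part = tbl[tbl["compound_id"] != ""].rename(columns=cols)
        part = part[["compound_id", "substance"] + list(cols.values())]
        merged = part if merged is None else merged.merge(
            part.drop(columns=["substance"]), on="compound_id", how="outer")
    return merged.reset_index(drop=True)


def pairwise_r2(za, zb, mode: str = "full", extreme_threshold: float = 2.0) -> float:
    """Squared Pearson correlation of two matched Z vectors.

    ``mode='extreme'`` keeps a pair when either member satisfies
    |Z| > ``extreme_threshold`` (strict). Controls must already be excluded
    from the inputs.
    """
    za = np.asarray(za, dtype=float)
    zb = np.asarray(zb, dtype=float)
    if za.shape != zb.shape:
        raise ValueError("Z vectors must be matched")
    ok = np.isfinite(za) & np.isfinite(zb)
    za, zb = za[ok], zb[ok]
    if mode == "extreme":
        keep = (np.abs(za) > extreme_threshold) | (np.abs(zb) > extreme_threshold)
        za, zb = za[keep], zb[keep]
    elif mode != "full":
        raise ValueError("mode must be 'full' or 'extreme'")
    if za.size < 3:
        raise ValueError("need at least three matched pairs after subsetting")
    if np.ptp(za) == 0 or np.ptp(zb) == 0:
        raise ValueError("constant Z vector after subsetting")
    r, _ = stats.pearsonr(za, zb)
    return float(r ** 2)


def replicate_correlations(merged: pd.DataFrame,
                           extreme_threshold: float = 2.0) -> pd.DataFrame:
    """Full- and extreme-mode R^2 for every replicate pair of a merged table."""
    reps = sorted(int(c.split("z_rep")[1]) for c in merged.columns
                  if c.startswith("z_rep"))
    rows = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            za = merged[f"z_rep{reps[i]}"]
            zb = merged[f"z_rep{reps[j]}"]
            rows.append({
                "rep_a": reps[i], "rep_b": reps[j],
                "r2_full": pairwise_r2(za, zb, "full"),
                "r2_extreme": pairwise_r2(za, zb, "extreme", extreme_threshold),
            })
    return pd.DataFrame(rows)
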