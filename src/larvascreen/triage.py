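"""Pre-hit calling and multi-stage artifact triage.

A compound is a pre-hit when its Z-score strictly exceeds the threshold
(default 2) in at least two of three biological replicates. Pre-hits are
partitioned by qualifying replicate pair — a compound above threshold in all
three replicates appears in every pair row, so per-row counts intentionally
double-count triple qualifiers (the screen's own bookkeeping). Each pair row
is then whittled down: pre-hits whose qualifying wells carry a high-background
flag are removed first, then those with a low/no-DMSO flag, leaving the clean
count; manual image inspection is a free-text pass/fail column the analyst
fills in (defaults to pass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

#: pair-row order used in screen reports
PAIR_ORDER = [(1, 3), (1, 2), (2, 3)]


@dataclass
class TriageReport:
    """Stage-by-stage pre-hit accounting per replicate pair plus totals."""

    table: pd.DataFrame                       # pair rows + Total row
    prehits: pd.DataFrame = field(repr=False)  # per (compound, pair) with status

    @property
    def n_clean_total(self) -> int:
        return int(self.table.loc[self.table["pair"] == "Total", "n_clean"].iloc[0])


def _z_columns(reps: pd.DataFrame) -> list[int]:
    ks = sorted(int(c.split("z_rep")[1]) for c in reps.columns
                if c.startswith("z_rep"))
    if len(ks) < 3:
        raise ValueError("need Z-scores for three replicates (z_rep1..z_rep3)")
    return ks


def call_prehits(reps: pd.DataFrame, z_threshold: float = 2.0,
                 min_reps: int = 2) -> pd.DataFrame:
    """Call pre-hits under the strict Z > threshold, >= min_reps-of-3 rule.

    ``reps`` is a merged replicate table (one row per library well, columns
    ``z_rep1..z_rep3`` plus ``compound_id``/``substance``). Returns one row
    per (pre-hit, qualifying pair): compound_id, substance, the Z triple,
    ``n_reps_above`` and the qualifying pair ``(rep_a, rep_b)``. Missing
    replicate values never qualify; the compound is evaluated on the pairs
    that are present.
    """
    ks = _z_columns(reps)
    flag_cols = [c for c in reps.columns if c.startswith("flag_")]
    rows = []
    for rec in reps.itertuples(index=False):
        z = {k: getattr(rec, f"z_rep{k}") for k in ks}
        above = {k for k in ks if pd.notna(z[k]) and z[k] > z_threshold}
        if len(above) < min_reps:
            continue
        for a, b in combinations(ks, 2):
            if a in above and b in above:
                rows.append({
                    "compound_id": getattr(rec, "compound_id", ""),
                    "substance": rec.substance,
                    **{f"z_rep{k}": z[k] for k in ks},
                    **{fc: getattr(rec, fc) for fc in flag_cols},
                    "n_reps_above": len(above),
                    "pair": (a, b),
                })
    cols = ["compound_id", "substance"] + [f"z_rep{k}" for k in ks] \
        + flag_cols + ["n_reps_above", "pair"]
    return pd.DataFrame(rows, columns=cols)


def apply_artifact_filters(prehits: pd.DataFrame,
                           flags: pd.DataFrame | None = None) -> TriageReport:
    """Subtractive artifact bookkeeping per replicate pair.

    ``flags`` has one row per library well (``compound_id``) with boolean
    columns ``flag_high_bg_rep<k>`` / ``flag_low_dmso_rep<k>``; if None, the
    flag columns are taken from ``prehits`` itself. A pre-hit is removed from
    a pair row as high-background if either qualifying replicate well is
    flagged, otherwise as low/no DMSO if either is flagged; the remainder is
    clean. Each row satisfies clean = prehit - high_bg - low_dmso, and the
    Total row is the column sum over pair rows.
    """
    df = prehits.copy()
    if flags is not None:
        fcols = [c for c in flags.columns if c.startswith("flag_")]
        df = df.merge(flags[["compound_id"] + fcols], on="compound_id",
                      how="left", suffixes=("", "_flags"))

    def well_flag(rec, kind: str, rep: int) -> bool:
        v = getattr(rec, f"flag_{kind}_rep{rep}", False)
        return bool(v) and pd.notna(v)

    status = []
    for rec in df.itertuples(index=False):
        a, b = rec.pair
        if well_flag(rec, "high_bg", a) or well_flag(rec, "high_bg", b):
            status.append("high_background")
        elif well_flag(rec, "low_dmso", a) or well_flag(rec, "low_dmso", b):
            status.append("low_dmso")
        else:
            status.append("clean")
    df["status"] = status
    df["manual_pass"] = np.where(df["status"] == "clean", "pass", "")

    rows = []
    pairs_present = [p for p in PAIR_ORDER if p in set(df["pair"])] or PAIR_ORDER
    for pair in pairs_present:
        sub = df[df["pair"] == pair]
        n = len(sub)
        nbg = int((sub["status"] == "high_background").sum())
        ndm = int((sub["status"] == "low_dmso").sum())
        rows.append({"pair": f"Replicates {pair[0]} and {pair[1]}",
                     "n_prehit": n, "n_high_background": nbg,
                     "n_low_dmso": ndm, "n_clean": n - nbg - ndm,
                     "n_manual_pass": n - nbg - ndm})
    total = {k: sum(r[k] for r in rows) for k in rows[0] if k != "pair"}
    rows.append({"pair": "Total", **total})
    return TriageReport(table=pd.DataFrame(rows), prehits=df)


def unique_substances(names) -> list[str]:
    """Case-insensitive deduplication of substance names, order-preserving.

    Accepts an iterable of names or a DataFrame with a ``substance`` column;
    duplicate library wells of the same substance collapse to one entry.
    """
    if isinstance(names, pd.DataFrame):
        names = names["substance"]
    seen: dict[str, str] = {}
    for name in names:
        key = str(name).strip().casefold()
        if key and key not in seen:
            seen[key] = str(name).strip()
    return list(seen.values())


def hit_rate(n_validated: int, n_library: int) -> float:
    """Validated-hit rate as a percentage, reported to two decimals."""
    if n_library <= 0:
        raise ValueError("library size must be positive")
    if n_validated < 0:
        raise ValueError("validated-hit count cannot be negative")
    return round(100.0 * n_validated / n_library, 2)
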