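"""Published screen tables, packaged as analysis inputs.

The primary screen's printed outputs — the replicate Z-score triples of the
19 library wells carried into validation, and the per-stage triage counts —
are small enough to ship as data. They serve as worked examples and as fixed
inputs for the hit-calling and triage bookkeeping.
"""

from __future__ import annotations

import pandas as pd

#: unique compounds in the screened library
LIBRARY_SIZE = 2532
#: compounds validated through all retest phases (20-hydroxyecdysone)
N_VALIDATED_HITS = 1
#: replicate-1-vs-2 Z-score R^2, all test wells vs the |Z| > 2 subset
R2_FULL_EXAMPLE = 0.05977
R2_EXTREME_EXAMPLE = 0.48171
#: plates with Z' factor > 0, out of all screening plates
N_PLATES_ZPRIME_POSITIVE = 73
N_PLATES_TOTAL = 96

_PREHIT_ROWS = [
    ("CRUSTECDYSONE", 3.36, 2.24, 3.03),
    ("TETRACYCLINE HUDROCHLORIDE", 2.84, 1.01, 2.39),
    ("HARMINE", 3.37, 1.92, 2.41),
    ("SULFLURAMID", 4.45, 6.22, -0.01),
    ("URSOCHOLANIC ACID", 8.61, 7.51, 1.85),
    ("5a-ANDROSTANE", 6.46, -1.10, 2.44),
    ("IRIGENIN TRIMETHYLETHER", 0.73, 5.62, 4.90),
    ("PATULIN", -0.43, 2.22, 2.63),
    ("ANTIMONY POTASSIUM TARTRATE TRIHYDRATE", 2.30, 0.57, 2.66),
    ("ALOGLIPTIN BENZOATE", 2.23, 8.26, -2.26),
    ("CEFEPIME HYDROCHLORIDE", 3.25, -0.12, 3.85),
    ("PALMIDROL (5mM)", 3.95, 1.01, 5.46),
    ("THIOGUANINE, TIOGUANINE", 3.51, -0.91, 0.80),
    ("THIOGUANINE, TIOGUANINE", 0.91, -0.02, 4.97),
    ("CAPTAN", 4.11, -3.41, 3.36),
    ("AGARIC ACID", 3.16, 1.90, 4.05),
    ("ZONISAMIDE", 0.42, 3.19, 2.55),
    ("BROXALDINE", 2.05, -1.05, 6.62),
    ("PICEID", 2.66, 3.04, 2.06),
]


def published_prehit_table() -> pd.DataFrame:
    """The 19 library wells carried into validation, with their Z triples.

    One row per library well: the drug library held thioguanine in two
    different wells, so that substance appears twice under distinct
    ``compound_id``s.
    """
    return pd.DataFrame(
        [{"compound_id": f"T2-{i + 1:02d}", "substance": name,
          "z_rep1": z1, "z_rep2": z2, "z_rep3": z3}
         for i, (name, z1, z2, z3) in enumerate(_PREHIT_ROWS)])


def published_triage_counts() -> pd.DataFrame:
    """Per-stage pre-hit counts of the primary screen, by replicate pair.

    Columns: the pre-hit count of the pair row, how many were removed for
    high image background, how many for low/no DMSO, and how many passed
    manual well-image inspection (recorded, not recomputable).
    """
    rows = [
        {"rep_a": 1, "rep_b": 3, "n_prehit": 44, "n_high_background": 30,
         "n_low_dmso": 3, "n_manual_pass": 5},
        {"rep_a": 1, "rep_b": 2, "n_prehit": 42, "n_high_background": 12,
         "n_low_dmso": 5, "n_manual_pass": 12},
        {"rep_a": 2, "rep_b": 3, "n_prehit": 76, "n_high_background": 64,
         "n_low_dmso": 3, "n_manual_pass": 5},
    ]
    return pd.DataFrame(rows)


def reconstruct_triage_wells(counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Synthetic per-well replicate table consistent with the published triage counts.

    The screen's per-well flag assignments were never published, only the
    per-stage marginals; this builds a minimal merged Z-table (one row per
    well, Z triple plus per-replicate artifact flags) whose pre-hit calling
    and artifact filtering reproduce those marginals exactly. Each
    reconstructed well qualifies in exactly one replicate pair.
    """
    counts = counts if counts is not None else published_triage_counts()
    rows = []
    k = 0
    for rec in counts.itertuples(index=False):
        a, b = int(rec.rep_a), int(rec.rep_b)
        for i in range(int(rec.n_prehit)):
            k += 1
            z = {f"z_rep{r}": 0.0 for r in (1, 2, 3)}
            z[f"z_rep{a}"] = 3.0
            z[f"z_rep{b}"] = 3.0
            flags = {f"flag_{kind}_rep{r}": False
                     for kind in ("high_bg", "low_dmso") for r in (1, 2, 3)}
            if i < rec.n_high_background:
                flags[f"flag_high_bg_rep{a}"] = True
            elif i < rec.n_high_background + rec.n_low_dmso:
                flags[f"flag_low_dmso_rep{b}"] = True
            rows.append({"compound_id": f"W{k:04d}",
                         "substance": f"WELL-{k:04d}", **z, **flags})
    return pd.DataFrame(rows)
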