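"""Plate quality control and replicate agreement for the simulated screen.

Recreates the screen of 01_simulate_screen.py (same seed), computes the
Z-prime factor of every plate, Z-scores every test well against its
same-plate negative controls, merges the three replicates and compares
full-set vs extreme-subset (|Z| > 2) pairwise correlations.
"""

from pathlib import Path

import numpy as np

from larvascreen import screen_stats as ss
from larvascreen.simulate import (ArtifactModel, ScreenConfig, SizeModel,
                                  make_library, simulate_screen_areas)

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def simulate():
    cfg0 = ScreenConfig(n_plates=32)
    library = make_library(cfg0)
    ids = [cid for plate in library for cid, _ in plate]
    rng = np.random.default_rng([SEED, 23])
    hits = [str(h) for h in rng.choice(ids, size=8, replace=False)]
    rescues = {h: float(r) for h, r in zip(hits, rng.uniform(0.3, 0.9, 8))}
    cfg = ScreenConfig(n_plates=32, true_hit_ids=tuple(hits), rng_seed=SEED)
    return simulate_screen_areas(cfg, SizeModel(), ArtifactModel(),
                                 library=library, rescue_by_compound=rescues)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tables, truth = simulate()

    plate_stats = ss.screen_plate_stats(truth)
    plate_stats.round(4).to_csv(RESULTS / "plate_stats.csv", index=False)
    frac = (plate_stats["zprime"] > 0).mean()
    print(f"{int((plate_stats.zprime > 0).sum())} of {len(plate_stats)} "
          f"plates have Z' > 0 ({100 * frac:.0f}%)")

    merged = ss.merge_replicates([ss.zscore_screen(t) for t in tables])
    scratch = RESULTS.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    merged.round(4).to_csv(scratch / "replicate_zscores.csv", index=False)

    corr = ss.replicate_correlations(merged)
    corr.round(5).to_csv(RESULTS / "replicate_correlations.csv", index=False)
    print("pairwise replicate R^2 (full set vs |Z|>2 subset):")
    print(corr.round(4).to_string(index=False))
    if (corr["r2_extreme"] > corr["r2_full"]).all():
        print("extreme-subset correlation exceeds the full-set correlation "
              "for every replicate pair, as in the original screen")


if __name__ == "__main__":
    main()
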