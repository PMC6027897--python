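"""Validation-stage developmental analyses on simulated vial data.

Covers the assays used to confirm screen hits: pupation/eclosion
timecourses (mutant delay and its rescue), the eclosion-fraction fold
change under hormone treatment, the larval size-ratio comparison, and the
proteasome-inhibitor IC50 shift between genotypes.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from larvascreen import devassay as da
from larvascreen.experiments import ic50_shift_experiment
from larvascreen.simulate import (HOMOZYGOTE_SURVIVAL, DevArm,
                                  simulate_dev_events)

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)

    # eclosion timecourses: heterozygote, delayed homozygote, rescued homozygote
    arms = [
        DevArm("het", 137, median_day=10.0),
        DevArm("hom", 200, median_day=10.0, delay_days=2.0,
               survival=HOMOZYGOTE_SURVIVAL),
        DevArm("hom_rescued", 200, median_day=10.0, delay_days=0.5,
               survival=0.64),
    ]
    events = simulate_dev_events(arms, day_grid=range(8, 16), rng=rng)
    tc = da.timecourse_table(events)
    tc.round(4).to_csv(RESULTS / "eclosion_timecourses.csv", index=False)
    da.plot_timecourses(tc, RESULTS / "eclosion_timecourses.svg")
    med = {label: da.cumulative_fraction(
        pd.Series(sub["count"].to_numpy(), index=sub["day"].to_numpy()),
        int(sub["n_survivors"].iloc[0])).median_day
        for label, sub in events.groupby("label")}
    print(f"median eclosion day: het {med['het']:.0f}, hom {med['hom']:.0f} "
          f"(delay {med['hom'] - med['het']:.0f} d), rescued "
          f"{med['hom_rescued']:.0f}")

    # hormone-treatment eclosion fold change, 10 vials of ~25 animals per arm
    treated = rng.binomial(25, 0.32, size=10) / 25
    control = rng.binomial(25, 0.08, size=10) / 25
    fold, p = da.eclosion_fold_change(treated, control)
    print(f"eclosion fold change treated/control: {fold:.2f} (p = {p:.2e})")

    # larval size ratio, 19 control vs 20 mutant larvae
    sig = np.sqrt(np.log1p(0.15 ** 2))
    het = np.exp(rng.normal(np.log(280) - sig ** 2 / 2, sig, 19))
    hom = np.exp(rng.normal(np.log(210) - sig ** 2 / 2, sig, 20))
    ratio, p_size = da.compare_sizes(hom, het)
    print(f"mutant/control larval size ratio: {ratio:.3f} (p = {p_size:.2e})")

    # sensitiser IC50 shift between genotypes (true ratio 0.1)
    ic = ic50_shift_experiment(seed=SEED, n_sims=20)
    print(f"median fitted IC50 ratio over {ic['n_sims']} simulations: "
          f"{ic['median_ic50_ratio']:.3f} (true 0.100)")

    pd.DataFrame([{
        "median_delay_days": med["hom"] - med["het"],
        "eclosion_fold_change": fold, "fold_change_p": p,
        "size_ratio": ratio, "size_ratio_p": p_size,
        "median_ic50_ratio": ic["median_ic50_ratio"],
    }]).round(5).to_csv(RESULTS / "validation_summary.csv", index=False)
    print(f"summary -> {RESULTS / 'validation_summary.csv'}")


if __name__ == "__main__":
    main()
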