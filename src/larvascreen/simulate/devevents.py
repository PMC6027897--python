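"""Simulated vial-format developmental-event tables (pupation/eclosion).

Each arm (genotype x treatment) is summarised by a survival fraction and a
discretised event-day distribution; a developmental delay is a rigid shift
of that distribution. Counts are what a scientist records at the bench: how
many animals pupated/eclosed on each day, out of how many dispensed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DevArm:
    """One experimental arm of a developmental-timing assay.

    ``median_day``/``sd_days`` parameterise the (normal, day-discretised)
    event-day distribution; ``delay_days`` shifts it rigidly; ``survival``
    is the fraction of dispensed animals that reach the event at all. The
    default homozygote survival of 0.32 reflects the mutant's pupal
    semi-lethality (32% of homozygotes emerge as adults at 25 degrees).
    """

    label: str
    n_individuals: int
    median_day: float = 10.0
    sd_days: float = 0.9
    delay_days: float = 0.0
    survival: float = 1.0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        if not (0.0 <= self.survival <= 1.0):
            raise ValueError("survival must be in [0, 1]")


HOMOZYGOTE_SURVIVAL = 0.32


def simulate_dev_events(
    arms: list[DevArm],
    day_grid: np.ndarray | list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily event counts for each arm.

    Returns a tidy frame with columns ``label, day, count, n_total,
    n_survivors``; days outside ``day_grid`` are clamped to its ends so
    counts are conserved. Counts are non-negative by construction.
    """
    rng = rng or np.random.default_rng(0)
    day_grid = np.asarray(day_grid if day_grid is not None else np.arange(7, 16))
    frames = []
    for arm in arms:
        n_surv = int(rng.binomial(arm.n_individuals, arm.survival)) \
            if arm.survival < 1.0 else arm.n_individuals
        days = np.round(rng.normal(arm.median_day + arm.delay_days,
                                   arm.sd_days, size=n_surv))
        days = np.clip(days, day_grid.min(), day_grid.max()).astype(int)
        counts = pd.Series(days).value_counts().reindex(day_grid, fill_value=0)
        frames.append(pd.DataFrame({
            "label": arm.label, "day": day_grid, "count": counts.to_numpy(),
            "n_total": arm.n_individuals, "n_survivors": n_surv,
        }))
    return pd.concat(frames, ignore_index=True)
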