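"""Validation-stage developmental analyses.

Covers the vial-format assays used to confirm screen hits: cumulative
pupation/eclosion timecourses normalised to surviving animals, eclosion-
fraction fold changes between treatment arms with Student's t-test,
larval-size ratio comparisons, and four-parameter logistic (4PL)
dose-response fitting for IC50-shift estimates (e.g. the bortezomib
sensitisation of the mutant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class DevTimecourse:
    """Cumulative event fractions on a day grid for one arm."""

    label: str
    days: np.ndarray
    cumulative_fraction: np.ndarray
    n_survivors: int

    @property
    def median_day(self) -> float:
        """First day on which the cumulative fraction reaches one half."""
        idx = np.searchsorted(self.cumulative_fraction, 0.5)
        return float(self.days[min(idx, len(self.days) - 1)])


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL fit y = bottom + (top - bottom) / (1 + (x/ic50)^slope)."""

    doses: np.ndarray
    responses: np.ndarray
    top: float
    bottom: float
    ic50: float
    slope: float
    rss: float
    extrapolated: bool      # ic50 outside the tested dose range
    unreliable: bool        # flat or non-monotone response

    def predict(self, x) -> np.ndarray:
        return _four_pl(np.asarray(x, dtype=float),
                        self.top, self.bottom, self.ic50, self.slope)


def cumulative_fraction(events: pd.Series | dict, n_survivors: int,
                        label: str = "") -> DevTimecourse:
    """Normalised cumulative timecourse from daily event counts.

    ``events`` maps day -> count. Fractions are cumulative counts divided by
    ``n_survivors``; for survivor-normalised curves the terminal value is 1.
    """
    if n_survivors <= 0:
        raise ValueError("n_survivors must be positive")
    ser = pd.Series(dict(events) if isinstance(events, dict) else events)
    ser = ser.sort_index()
    if (ser < 0).any():
        raise ValueError("daily counts cannot be negative")
    cum = ser.cumsum().to_numpy(dtype=float) / n_survivors
    if cum.size and cum[-1] > 1.0 + 1e-9:
        raise ValueError("cumulative events exceed the number of survivors")
    return DevTimecourse(label, ser.index.to_numpy(), cum, int(n_survivors))


def timecourse_table(events: pd.DataFrame) -> pd.DataFrame:
    """Tidy cumulative-fraction table from a simulated/recorded event frame.

    Expects columns ``label, day, count, n_survivors`` (as written by the
    developmental-event simulator) and returns ``label, day, fraction``.
    """
    frames = []
    for label, sub in events.groupby("label", sort=False):
        tc = cumulative_fraction(pd.Series(sub["count"].to_numpy(),
                                           index=sub["day"].to_numpy()),
                                 int(sub["n_survivors"].iloc[0]), label=label)
        frames.append(pd.DataFrame({"label": label, "day": tc.days,
                                    "fraction": tc.cumulative_fraction}))
    return pd.concat(frames, ignore_index=True)


def eclosion_fold_change(treated_fractions, control_fractions,
                         welch: bool = False) -> tuple[float, float]:
    """Fold change of mean eclosion fraction, treated over control, with p-value.

    Per-vial eclosed/total fractions are the replicates; the test is the
    classical equal-variance two-sample Student's t-test (``welch=True``
    switches to the unequal-variance variant).
    """
    t = np.asarray(treated_fractions, dtype=float)
    c = np.asarray(control_fractions, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("need at least two replicate vials per arm")
    if c.mean() == 0:
        raise ValueError("fold change undefined: control mean is zero")
    fold = float(t.mean() / c.mean())
    if np.array_equal(np.sort(t), np.sort(c)):
        return fold, 1.0
    res = stats.ttest_ind(t, c, equal_var=not welch)
    return fold, float(res.pvalue)


def compare_sizes(group_a, group_b, welch: bool = False) -> tuple[float, float]:
    """Ratio of mean areas (a over b) with a two-sided Student's t-test p-value.

    Identical groups short-circuit to (ratio, p=1) so degenerate zero-variance
    comparisons are well defined.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two larvae per group")
    ratio = float(a.mean() / b.mean())
    if np.array_equal(np.sort(a), np.sort(b)):
        return ratio, 1.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return ratio, float(res.pvalue)


def _four_pl(x, top, bottom, ic50, slope):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / ic50) ** slope, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_dose_response(doses, responses,
                      monotone_tolerance: float = 0.15) -> DoseResponseFit:
    """Least-squares 4PL fit of a size-vs-dose curve.

    Initialisation from data quantiles: top/bottom from the response range,
    IC50 from the dose whose mean response is nearest to the half-way point,
    slope 1. Replicated doses are allowed (fit on all points). The fit is
    flagged unreliable when the response is essentially flat or rises with
    dose by more than ``monotone_tolerance`` of its range; the IC50 is
    flagged extrapolated when it falls outside the tested positive doses.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses must be matched")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least four distinct dose levels")

    by_dose = pd.Series(y).groupby(pd.Series(x)).mean()
    top0 = float(by_dose.iloc[0])
    bottom0 = float(by_dose.min())
    span = max(top0 - bottom0, 1e-12)
    half = bottom0 + span / 2.0
    pos = by_dose.index[by_dose.index > 0]
    ic0 = float(pos[np.argmin(np.abs(by_dose.loc[pos] - half))]) if len(pos) else 1.0

    flat = (by_dose.max() - by_dose.min()) < 0.1 * max(abs(by_dose.mean()), 1e-12)
    rises = float(by_dose.diff().clip(lower=0).sum())
    non_monotone = rises > monotone_tolerance * max(by_dose.max() - by_dose.min(), 1e-12)

    try:
        popt, _ = optimize.curve_fit(
            _four_pl, x, y, p0=[top0, bottom0, max(ic0, 1e-6), 1.0],
            bounds=([-np.inf, -np.inf, 1e-9, 0.05], [np.inf, np.inf, 1e6, 20.0]),
            maxfev=20000)
        top, bottom, ic50, slope = (float(v) for v in popt)
    except RuntimeError:
        top, bottom, ic50, slope = top0, bottom0, ic0, 1.0
        flat = True
    if top < bottom:  # enforce top >= bottom by the curve's symmetry
        top, bottom, slope = bottom, top, -slope
    rss = float(np.sum((_four_pl(x, top, bottom, ic50, slope) - y) ** 2))
    extrapolated = not (pos.min() <= ic50 <= pos.max()) if len(pos) else True
    return DoseResponseFit(x, y, top, bottom, ic50, slope, rss,
                           extrapolated=bool(extrapolated),
                           unreliable=bool(flat or non_monotone))


def ic50_ratio(fit_a: DoseResponseFit, fit_b: DoseResponseFit) -> float:
    """IC50 ratio between two fitted genotype curves (a over b)."""
    return fit_a.ic50 / fit_b.ic50


def plot_timecourses(table: pd.DataFrame, path) -> None:
    """Write a cumulative-fraction timecourse plot (SVG/PNG by suffix).

    ``table`` is tidy with columns ``label, day, fraction`` as produced by
    :func:`timecourse_table`.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, sub in table.groupby("label", sort=False):
        ax.step(sub["day"], sub["fraction"], where="post", marker="o",
                markersize=3, label=str(label))
    ax.set_xlabel("day")
    ax.set_ylabel("cumulative fraction eclosed")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
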