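"""Xenograft growth and cohort statistics.

Tumor volume from caliper measurements (width^2 x length / 2), two-arm
growth-curve comparison via per-timepoint Welch t tests with Holm-Sidak
adjustment across days, Fisher's exact test for take-rate associations
(exact integer hypergeometric arithmetic), and Kaplan-Meier / log-rank
survival comparison.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tumor_volume",
    "read_measurements",
    "growth_curve_test",
    "fisher_exact",
    "SurvivalComparison",
    "survival_compare",
    "plot_growth_curves",
]

logger = logging.getLogger(__name__)

GROUPS = ("TIL", "no_TIL", "NOG_control", "other")


def tumor_volume(width, length):
    """Caliper-based tumor volume in mm^3: width x width x length / 2."""
    width = np.asarray(width, dtype=float)
    length = np.asarray(length, dtype=float)
    if (width <= 0).any() or (length <= 0).any():
        raise ValueError("caliper dimensions must be positive")
    volume = width * width * length / 2.0
    return float(volume) if volume.ndim == 0 else volume


def read_measurements(path) -> pd.DataFrame:
    """Read a caliper table (animal_id, group, day, width_mm, length_mm).

    By convention length >= width; rows violating it are swapped with a
    warning.  A ``volume_mm3`` column is added.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "group": str})
    required = {"animal_id", "group", "day", "width_mm", "length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement file lacks columns: {sorted(missing)}")
    swapped = df["width_mm"] > df["length_mm"]
    if swapped.any():
        logger.warning("swapping width/length on %d rows (width > length)", swapped.sum())
        w = df.loc[swapped, "width_mm"].copy()
        df.loc[swapped, "width_mm"] = df.loc[swapped, "length_mm"]
        df.loc[swapped, "length_mm"] = w
    df["day"] = df["day"].astype(int)
    df["volume_mm3"] = tumor_volume(df["width_mm"], df["length_mm"])
    return df


def growth_curve_test(
    measurements: pd.DataFrame,
    groups: tuple[str, str],
    equal_var: bool = False,
    adjust: str = "holm-sidak",
) -> pd.DataFrame:
    """Per-day two-sample t tests on tumor volumes with multiplicity control.

    For every day shared by both arms with >= 2 animals per arm, a Welch
    t test (or pooled-variance test with ``equal_var=True``) compares the
    volumes; p-values are adjusted across days by Holm-Sidak
    (``adjust="none"`` disables the correction).  Days failing the
    two-animal precondition are skipped with a warning.

    Returns a DataFrame indexed by day with columns n_<group>,
    mean_<group>, t, p_raw, p_adj.
    """
    if adjust not in ("holm-sidak", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    g1, g2 = groups
    df = measurements.copy()
    if "volume_mm3" not in df.columns:
        df["volume_mm3"] = tumor_volume(df["width_mm"], df["length_mm"])
    sub = {g: df[df["group"] == g] for g in (g1, g2)}
    for g in (g1, g2):
        if sub[g].empty:
            raise ValueError(f"no measurements for group {g!r}")
    shared_days = sorted(set(sub[g1]["day"]) & set(sub[g2]["day"]))
    if not shared_days:
        raise ValueError("the two groups share no measurement days")

    rows = []
    for day in shared_days:
        v1 = sub[g1].loc[sub[g1]["day"] == day, "volume_mm3"].to_numpy()
        v2 = sub[g2].loc[sub[g2]["day"] == day, "volume_mm3"].to_numpy()
        if len(v1) < 2 or len(v2) < 2:
            logger.warning("day %d skipped: fewer than 2 animals in an arm", day)
            continue
        if np.ptp(v1) == 0 and np.ptp(v2) == 0 and v1[0] == v2[0]:
            t, p = 0.0, 1.0  # identical constant arms
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = stats.ttest_ind(v1, v2, equal_var=equal_var)
        rows.append(
            {
                "day": day,
                f"n_{g1}": len(v1), f"n_{g2}": len(v2),
                f"mean_{g1}": float(v1.mean()), f"mean_{g2}": float(v2.mean()),
                "t": float(t), "p_raw": float(p),
            }
        )
    if not rows:
        raise ValueError("no day satisfies the >= 2 animals per arm precondition")
    out = pd.DataFrame(rows).set_index("day")
    if adjust == "holm-sidak":
        out["p_adj"] = multipletests(out["p_raw"].to_numpy(), method="holm-sidak")[1]
    else:
        out["p_adj"] = out["p_raw"]
    return out


def _hypergeom_numerators(r1: int, r2: int, c1: int) -> tuple[range, list[int]]:
    """Integer numerators of the hypergeometric pmf over the support of a.

    With margins fixed (row totals r1, r2; first column total c1), the
    probability of upper-left cell value a is
    C(r1, a) C(r2, c1 - a) / C(r1 + r2, c1); the common denominator is
    dropped so comparisons stay exact.
    """
    a_min = max(0, c1 - r2)
    a_max = min(r1, c1)
    support = range(a_min, a_max + 1)
    return support, [math.comb(r1, a) * math.comb(r2, c1 - a) for a in support]


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Returns ``(one_sided_p, two_sided_p)``.  The one-sided p is the
    hypergeometric tail in the direction of the observed association
    (P(A >= a) when the odds ratio favours the diagonal, P(A <= a)
    otherwise); the two-sided p sums all tables with the observed margins
    whose probability does not exceed the observed table's.  All
    comparisons use exact integer arithmetic, so pmf ties are resolved
    exactly rather than to floating-point tolerance.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("table cells must be non-negative integers")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        raise ValueError("empty table")
    r1, r2, c1 = a + b, c + d, a + c
    support, numerators = _hypergeom_numerators(r1, r2, c1)
    total = sum(numerators)
    obs = numerators[a - support.start]
    if a * d >= b * c:
        one_sided = sum(n for x, n in zip(support, numerators) if x >= a)
    else:
        one_sided = sum(n for x, n in zip(support, numerators) if x <= a)
    two_sided = sum(n for n in numerators if n <= obs)
    return one_sided / total, two_sided / total


@dataclass
class SurvivalComparison:
    """Log-rank comparison plus the per-group Kaplan-Meier estimates."""

    statistic: float
    p_value: float
    km_curves: dict[str, pd.DataFrame]  # columns: time, survival


def survival_compare(
    records: pd.DataFrame, groups: tuple[str, str]
) -> SurvivalComparison:
    """Kaplan-Meier estimates per group and a log-rank test across the pair.

    ``records`` needs columns subject_id, group, time (days > 0) and event
    (True for death/failure, False for censoring).
    """
    required = {"group", "time", "event"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"survival table lacks columns: {sorted(missing)}")
    if (records["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    g1, g2 = groups
    sub = {g: records[records["group"] == g] for g in (g1, g2)}
    for g in (g1, g2):
        if sub[g].empty:
            raise ValueError(f"no subjects in group {g!r}")
    if not records["event"].astype(bool).any():
        logger.warning("no events in either group; log-rank is uninformative")

    km_curves = {}
    for g in (g1, g2):
        fitter = KaplanMeierFitter()
        fitter.fit(sub[g]["time"], event_observed=sub[g]["event"].astype(bool))
        sf = fitter.survival_function_
        km_curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    result = logrank_test(
        sub[g1]["time"], sub[g2]["time"],
        event_observed_A=sub[g1]["event"].astype(bool),
        event_observed_B=sub[g2]["event"].astype(bool),
    )
    return SurvivalComparison(
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        km_curves=km_curves,
    )


def plot_growth_curves(measurements: pd.DataFrame, ax=None):
    """Group mean +/- SEM tumor volume by day (cumulative growth curves)."""
    import matplotlib.pyplot as plt  # optional dependency

    df = measurements.copy()
    if "volume_mm3" not in df.columns:
        df["volume_mm3"] = tumor_volume(df["width_mm"], df["length_mm"])
    if ax is None:
        _, ax = plt.subplots()
    for group, grp in df.groupby("group"):
        by_day = grp.groupby("day")["volume_mm3"]
        mean, sem = by_day.mean(), by_day.sem()
        ax.errorbar(mean.index, mean, yerr=sem, label=str(group), capsize=3)
    ax.set_xlabel("day")
    ax.set_ylabel("tumor volume (mm$^3$)")
    ax.legend()
    return ax
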