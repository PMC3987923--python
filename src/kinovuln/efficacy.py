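"""Downstream efficacy statistics.

Ellipsoid tumor volumes from caliper measurements and two-arm group
comparisons (Welch t or Mann-Whitney U, mean +/- SEM per arm), annexin
positivity percentages from flow-cytometry quadrant counts, gamma-H2AX
foci-positive cell fractions, and relative colony numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "tumor_volume",
    "add_volumes",
    "arm_comparison",
    "QuadrantCounts",
    "apoptosis_percent",
    "foci_positive_fraction",
    "relative_colony_number",
]


def tumor_volume(L: float, W: float, H: float) -> float:
    """Ellipsoid tumor volume pi/6 * L * W * H from caliper dimensions (mm)."""
    if L <= 0 or W <= 0 or H <= 0:
        raise ValueError("caliper dimensions must be positive")
    return math.pi / 6.0 * L * W * H


def add_volumes(caliper: pd.DataFrame) -> pd.DataFrame:
    """Append a volume_mm3 column to a caliper table (L_mm, W_mm, H_mm)."""
    dims = caliper[["L_mm", "W_mm", "H_mm"]].to_numpy(dtype=float)
    if np.any(dims <= 0):
        raise ValueError("caliper dimensions must be positive")
    out = caliper.copy()
    out["volume_mm3"] = math.pi / 6.0 * dims.prod(axis=1)
    return out


def arm_comparison(caliper: pd.DataFrame, day: float,
                   test: str = "welch_t") -> dict:
    """Compare per-animal tumor volumes between arms on one study day.

    Two-sided Welch t (default) or Mann-Whitney U on the per-animal
    volumes, with each arm summarized as mean +/- SEM (sd/sqrt(n)).
    Needs >= 2 animals per arm at that day.
    """
    if test not in ("welch_t", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    table = add_volumes(caliper) if "volume_mm3" not in caliper.columns else caliper
    at_day = table[table["day"] == day]
    arms = {}
    for arm, sub in at_day.groupby("arm"):
        v = sub["volume_mm3"].to_numpy(dtype=float)
        arms[arm] = v
    if len(arms) != 2:
        raise ValueError(f"need exactly 2 arms at day {day}, found {sorted(arms)}")
    (name_a, a), (name_b, b) = sorted(arms.items())
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 animals per arm")

    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    summary = {
        arm: {"n": int(len(v)),
              "mean": float(np.mean(v)),
              "sem": float(np.std(v, ddof=1) / math.sqrt(len(v)))}
        for arm, v in ((name_a, a), (name_b, b))
    }
    return {"day": day, "test": test, "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "arms": summary}


@dataclass(frozen=True)
class QuadrantCounts:
    """Flow-cytometry quadrant event counts (annexin-V on the x axis)."""

    lower_left: int
    lower_right: int
    upper_left: int
    upper_right: int

    def __post_init__(self) -> None:
        for c in (self.lower_left, self.lower_right, self.upper_left, self.upper_right):
            if c < 0:
                raise ValueError("quadrant counts must be non-negative")

    @property
    def total(self) -> int:
        return self.lower_left + self.lower_right + self.upper_left + self.upper_right


def apoptosis_percent(q: QuadrantCounts) -> float:
    """Percent of events in the annexin-positive right quadrants.

    Lower-right (early apoptotic) plus upper-right (late apoptotic /
    dead) over all events, as a percentage.
    """
    if q.total <= 0:
        raise ValueError("total event count must be positive")
    return 100.0 * (q.lower_right + q.upper_right) / q.total


def foci_positive_fraction(counts, threshold: int = 10,
                           control_fraction: float | None = None) -> float:
    """Fraction of cells with strictly more than ``threshold`` foci.

    A cell with exactly ``threshold`` foci does not qualify.  When
    ``control_fraction`` is given, the fraction is normalized to it
    (treated/control ratio).
    """
    counts = np.asarray(list(counts))
    if counts.size == 0:
        raise ValueError("need at least one cell")
    if np.any(counts < 0):
        raise ValueError("foci counts must be non-negative")
    frac = float(np.mean(counts > threshold))
    if control_fraction is not None:
        if control_fraction <= 0:
            raise ValueError("control fraction must be positive for normalization")
        frac /= control_fraction
    return frac


def relative_colony_number(treated_counts, control_counts) -> float:
    """mean(treated colony counts) / mean(control colony counts)."""
    treated = np.asarray(list(treated_counts), dtype=float)
    control = np.asarray(list(control_counts), dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both count lists must be non-empty")
    if control.mean() <= 0:
        raise ValueError("control mean must be positive")
    return float(treated.mean() / control.mean())
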