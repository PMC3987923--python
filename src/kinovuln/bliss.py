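"""Bliss-independence synergy scoring for drug combinations.

Under Bliss independence two drugs act like independent probabilistic
events, so the expected combined inhibition fraction is
f_a + f_b - f_a*f_b.  Observed inhibition above that expectation
(positive excess) indicates synergy.  Single-agent fractions at
arbitrary grid doses are predicted from fitted 4PL viability curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "inhibition_fraction",
    "bliss_expected",
    "bliss_excess",
    "call_synergy",
    "SynergyMatrix",
]


def inhibition_fraction(treated: float, vehicle: float) -> float:
    """Fractional inhibition of a treated reading relative to vehicle.

    f = clip(1 - treated/vehicle, 0, 1); vehicle must be positive.
    """
    if vehicle <= 0:
        raise ValueError("vehicle reading must be positive")
    return float(np.clip(1.0 - treated / vehicle, 0.0, 1.0))


def bliss_expected(f_a: float, f_b: float) -> float:
    """Bliss-independence expected combined inhibition fraction."""
    f_a = np.asarray(f_a, dtype=float)
    f_b = np.asarray(f_b, dtype=float)
    if np.any((f_a < 0) | (f_a > 1)) or np.any((f_b < 0) | (f_b > 1)):
        raise ValueError("inhibition fractions must lie in [0, 1]")
    out = f_a + f_b - f_a * f_b
    return float(out) if out.ndim == 0 else out


@dataclass
class SynergyMatrix:
    """Dose-pair grid of observed vs Bliss-expected inhibition.

    ``grid`` has one row per dose pair with columns dose_a_nM,
    dose_b_nM, f_a, f_b, f_obs, f_bliss, excess.
    """

    grid: pd.DataFrame
    mean_excess: float
    max_excess: float

    @classmethod
    def from_grid(cls, grid: pd.DataFrame) -> "SynergyMatrix":
        return cls(grid=grid,
                   mean_excess=float(grid["excess"].mean()),
                   max_excess=float(grid["excess"].max()))


def bliss_excess(combo: pd.DataFrame, fit_a, fit_b) -> SynergyMatrix:
    """Score a combination grid against the Bliss expectation.

    ``combo`` holds columns dose_a_nM, dose_b_nM, inhibition_fraction
    (observed).  Single-agent fractions at each grid dose are predicted
    from the two converged 4PL fits as 1 - R(d)/100 (percent-of-vehicle
    scale), clipped to [0, 1]; excess = f_obs - f_bliss per cell.
    """
    for f, name in ((fit_a, "fit_a"), (fit_b, "fit_b")):
        if not f.converged:
            raise ValueError(f"{name} did not converge")
    da = combo["dose_a_nM"].to_numpy(dtype=float)
    db = combo["dose_b_nM"].to_numpy(dtype=float)
    f_obs = combo["inhibition_fraction"].to_numpy(dtype=float)
    f_a = np.clip(1.0 - fit_a.predict(da) / 100.0, 0.0, 1.0)
    f_b = np.clip(1.0 - fit_b.predict(db) / 100.0, 0.0, 1.0)
    f_bliss = bliss_expected(f_a, f_b)
    grid = pd.DataFrame(
        {
            "dose_a_nM": da,
            "dose_b_nM": db,
            "f_a": f_a,
            "f_b": f_b,
            "f_obs": f_obs,
            "f_bliss": f_bliss,
            "excess": f_obs - f_bliss,
        }
    )
    return SynergyMatrix.from_grid(grid)


def call_synergy(matrix: SynergyMatrix, delta: float = 0.1) -> dict:
    """Flag synergy when any grid cell's excess exceeds delta.

    Returns the call, the qualifying cells, and the lowest qualifying
    dose of each agent (None when no cell qualifies).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if len(matrix.grid) == 0:
        raise ValueError("synergy matrix is empty")
    cells = matrix.grid[matrix.grid["excess"] > delta]
    return {
        "synergy": bool(len(cells) > 0),
        "delta": delta,
        "n_supporting": int(len(cells)),
        "lowest_dose_a_nM": float(cells["dose_a_nM"].min()) if len(cells) else None,
        "lowest_dose_b_nM": float(cells["dose_b_nM"].min()) if len(cells) else None,
        "supporting_cells": cells.reset_index(drop=True),
    }
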