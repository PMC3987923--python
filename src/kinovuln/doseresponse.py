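"""Four-parameter logistic dose-response fitting and ICx derivation.

The viability model is the standard 4PL curve on percent-of-vehicle
scale::

    R(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

with hill > 0 so response falls with dose.  ``ic50`` is the relative
IC50 (the curve's inflection dose).  Fitting is nonlinear least squares
on the log-dose scale with multi-start initialization over log-spaced
IC50 seeds; ICx doses come from the analytic inversion of the fitted
curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["four_pl", "FourPLFit", "fit_4pl", "icx", "ic50_shift"]


def four_pl(dose, bottom: float, top: float, ic50: float, hill: float):
    """Evaluate the four-parameter logistic viability curve."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


@dataclass
class FourPLFit:
    """A fitted 4PL curve: bottom/top (percent), ic50 (nM), hill slope."""

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FourPLFit":
        with open(path) as fh:
            return cls(**json.load(fh))


def _as_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    doses = table["dose_nM"].to_numpy(dtype=float)
    resp = table["viability_pct"].to_numpy(dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    return doses, resp


def fit_4pl(table: pd.DataFrame, top_fixed_100: bool = True,
            bottom_nonneg: bool = True) -> FourPLFit:
    """Fit the 4PL model to a dose-response table by least squares.

    Requires >= 4 distinct doses.  By default the top plateau is fixed
    at 100 (viability is percent-of-vehicle) and the bottom is
    constrained non-negative.  IC50 and hill are fitted on log scale;
    >= 5 log-spaced IC50 starts spanning the dose range guard against
    local minima.  Degenerate data (all responses equal) yields a
    non-converged sentinel fit with ``converged=False``.
    """
    doses, resp = _as_arrays(table)
    if len(np.unique(doses)) < 4:
        raise ValueError("need >= 4 distinct doses to fit a 4PL curve")

    if np.ptp(resp) == 0:
        return FourPLFit(bottom=float(resp[0]), top=float(resp[0]),
                         ic50=float(np.nan), hill=float(np.nan),
                         rss=0.0, converged=False)

    log_d = np.log(doses)

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        if top_fixed_100:
            bottom, log_ic50, log_hill = theta
            top = 100.0
        else:
            bottom, top, log_ic50, log_hill = theta
        return bottom, top, float(np.exp(log_ic50)), float(np.exp(log_hill))

    def residuals(theta: np.ndarray) -> np.ndarray:
        bottom, top, ic50, hill = unpack(theta)
        pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (log_d - np.log(ic50))))
        return pred - resp

    lo_b = 0.0 if bottom_nonneg else -np.inf
    starts_ic50 = np.exp(np.linspace(np.log(doses.min()), np.log(doses.max()), 5))
    best = None
    for ic50_0 in starts_ic50:
        if top_fixed_100:
            x0 = [max(resp.min(), lo_b if np.isfinite(lo_b) else resp.min()),
                  np.log(ic50_0), 0.0]
            bounds = ([lo_b, -np.inf, np.log(1e-3)], [100.0, np.inf, np.log(50.0)])
        else:
            x0 = [max(resp.min(), 0.0), resp.max(), np.log(ic50_0), 0.0]
            bounds = ([lo_b, -np.inf, -np.inf, np.log(1e-3)],
                      [np.inf, np.inf, np.inf, np.log(50.0)])
        x0 = np.minimum(np.maximum(x0, bounds[0]), bounds[1])
        try:
            sol = least_squares(residuals, x0, bounds=bounds,
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0] - 1e-8 * max(best[0], 1.0):
            best = (rss, sol)
    if best is None:
        return FourPLFit(float("nan"), float("nan"), float("nan"), float("nan"),
                         float("nan"), converged=False)
    rss, sol = best
    bottom, top, ic50, hill = unpack(sol.x)
    converged = bool(sol.success and bottom < top)
    return FourPLFit(bottom=float(bottom), top=float(top), ic50=float(ic50),
                     hill=float(hill), rss=rss, converged=converged)


def icx(fit: FourPLFit, x: float) -> float:
    """Dose giving x percent inhibition of the fitted dynamic range.

    The target response is top - (x/100)(top - bottom); inverting the
    4PL gives d = ic50 * (x / (100 - x))^(1/hill).  icx(fit, 50) is the
    IC50 by definition.  x must lie strictly inside (0, 100).
    """
    if not fit.converged:
        raise ValueError("cannot invert a non-converged fit")
    if not 0.0 < x < 100.0:
        raise ValueError("x must lie strictly between 0 and 100")
    return float(fit.ic50 * (x / (100.0 - x)) ** (1.0 / fit.hill))


def ic50_shift(fit_single: FourPLFit, fit_combo: FourPLFit) -> dict:
    """Potency shift of one agent caused by combination with another.

    ratio = IC50(combination) / IC50(single agent); a ratio below 1
    means the partner drug sensitized the cells (leftward curve shift).
    """
    for f, name in ((fit_single, "single"), (fit_combo, "combo")):
        if not f.converged:
            raise ValueError(f"{name} fit did not converge")
    ratio = fit_combo.ic50 / fit_single.ic50
    return {
        "ic50_single_nM": fit_single.ic50,
        "ic50_combo_nM": fit_combo.ic50,
        "ratio": float(ratio),
        "sensitized": bool(ratio < 1.0),
    }
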