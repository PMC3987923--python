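"""Arrayed siRNA screen scoring.

Processing chain for a viability screen read out by absorbance on
96-well plates: scalar background subtraction, per-plate normalization
to the mean of the on-plate non-silencing controls (percent-of-control),
Z-scoring against the pooled sample-well population, per-gene
aggregation over that gene's siRNAs (the average Z), and hit calling
at mean Z < -2 (stringent: < -3, both strict).

Wells travel as a pandas DataFrame with columns ``plate_id``, ``well``,
``sirna_id``, ``gene``, ``role`` (sample/control/empty), ``absorbance``;
normalization adds ``normalized`` and ``z`` columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "subtract_background",
    "normalize_plates",
    "compute_z",
    "aggregate_genes",
    "call_hits",
    "score_screen",
]

WELL_COLUMNS = ["plate_id", "well", "sirna_id", "gene", "role", "absorbance"]


def _check_wells(wells: pd.DataFrame, required: list[str]) -> None:
    missing = [c for c in required if c not in wells.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")


def subtract_background(wells: pd.DataFrame, background: float) -> pd.DataFrame:
    """Subtract a scalar background absorbance, clipping at zero."""
    if background < 0:
        raise ValueError("background must be non-negative")
    _check_wells(wells, ["absorbance"])
    out = wells.copy()
    out["absorbance"] = np.maximum(out["absorbance"].to_numpy(dtype=float) - background, 0.0)
    return out


def normalize_plates(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize each well to the mean control absorbance on its plate.

    ``normalized`` = absorbance / mean(control absorbances on that plate),
    so controls average exactly 1.0 per plate and values are comparable
    plate to plate.  Raises if any plate lacks controls or has a
    non-positive control mean.
    """
    _check_wells(wells, ["plate_id", "role", "absorbance"])
    out = wells.copy()
    ctrl = out[out["role"] == "control"]
    means = ctrl.groupby("plate_id")["absorbance"].mean()
    for plate in out["plate_id"].unique():
        if plate not in means.index:
            raise ValueError(f"plate {plate} has no control wells")
        if means[plate] <= 0:
            raise ValueError(f"plate {plate} control mean is non-positive")
    out["normalized"] = out["absorbance"].to_numpy(dtype=float) / \
        out["plate_id"].map(means).to_numpy(dtype=float)
    return out


def compute_z(wells: pd.DataFrame, reference: str = "screen_samples",
              robust: bool = False) -> pd.DataFrame:
    """Z-score normalized wells against the sample-well population.

    reference="screen_samples" (default) pools sample wells across the
    whole screen; "per_plate_samples" standardizes within each plate.
    Controls never enter the reference statistics.  ``robust`` swaps
    mean/SD for median/scaled-MAD.
    """
    if reference not in ("screen_samples", "per_plate_samples"):
        raise ValueError(f"unknown reference {reference!r}")
    _check_wells(wells, ["plate_id", "role", "normalized"])
    out = wells.copy()

    def loc_scale(x: np.ndarray) -> tuple[float, float]:
        if len(x) < 2:
            raise ValueError("need >= 2 sample wells in the reference population")
        if robust:
            med = float(np.median(x))
            scale = 1.4826 * float(np.median(np.abs(x - med)))
            return med, scale
        return float(np.mean(x)), float(np.std(x, ddof=1))

    is_sample = out["role"] == "sample"
    if reference == "screen_samples":
        mu, sd = loc_scale(out.loc[is_sample, "normalized"].to_numpy(dtype=float))
        if sd == 0:
            raise ValueError("reference scale is zero")
        out["z"] = (out["normalized"] - mu) / sd
    else:
        z = np.empty(len(out))
        for plate, idx in out.groupby("plate_id").groups.items():
            sub = out.loc[idx]
            mu, sd = loc_scale(
                sub.loc[sub["role"] == "sample", "normalized"].to_numpy(dtype=float))
            if sd == 0:
                raise ValueError(f"plate {plate} reference scale is zero")
            z[out.index.get_indexer(idx)] = (sub["normalized"] - mu) / sd
        out["z"] = z
    return out


def aggregate_genes(wells: pd.DataFrame) -> pd.DataFrame:
    """Average the per-siRNA Z scores of each gene.

    Returns one row per gene with its list of well Zs, the mean Z and
    the hit flags at the default thresholds (mean_z < -2, < -3).
    """
    _check_wells(wells, ["gene", "role", "z"])
    samples = wells[wells["role"] == "sample"]
    if samples["gene"].isna().any():
        raise ValueError("every sample well must carry a gene id")
    grouped = samples.groupby("gene", sort=True)["z"]
    scores = pd.DataFrame(
        {
            "gene": list(grouped.groups.keys()),
            "z_values": [list(v) for _, v in grouped],
            "n_sirnas": grouped.size().to_numpy(),
            "mean_z": grouped.mean().to_numpy(),
        }
    )
    scores["hit"] = scores["mean_z"] < -2.0
    scores["stringent_hit"] = scores["mean_z"] < -3.0
    return scores.reset_index(drop=True)


def call_hits(scores: pd.DataFrame, threshold: float = -2.0,
              stringent: float = -3.0) -> tuple[set[str], set[str]]:
    """Call screen hits at mean_z < threshold (strict inequality).

    Returns (hits, stringent_hits); the stringent set is always a
    subset of the hit set.
    """
    if threshold <= stringent:
        raise ValueError("threshold must exceed the stringent cutoff")
    if len(scores) == 0:
        return set(), set()
    hits = set(scores.loc[scores["mean_z"] < threshold, "gene"])
    stringent_hits = set(scores.loc[scores["mean_z"] < stringent, "gene"])
    return hits, stringent_hits


def score_screen(wells: pd.DataFrame, background: float = 0.0,
                 reference: str = "screen_samples", robust: bool = False,
                 threshold: float = -2.0, stringent: float = -3.0,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, set[str], set[str]]:
    """Run the full scoring chain on a raw well table.

    Convenience wrapper: background subtraction -> plate normalization
    -> Z-scoring -> gene aggregation -> hit calling.  Returns
    (normalized wells, gene scores, hits, stringent hits).
    """
    normalized = compute_z(
        normalize_plates(subtract_background(wells, background)),
        reference=reference, robust=robust,
    )
    scores = aggregate_genes(normalized)
    scores["hit"] = scores["mean_z"] < threshold
    scores["stringent_hit"] = scores["mean_z"] < stringent
    hits, stringent_hits = call_hits(scores, threshold, stringent)
    return normalized, scores, hits, stringent_hits
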