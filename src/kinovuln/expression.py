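"""Differential-expression filtering and annotation-set intersection.

Implements the descriptive half of the target-nomination funnel: a
per-gene two-group test on log2 intensities (pooled Student's t by
default; Welch t and Mann-Whitney available), Benjamini-Hochberg FDR
adjustment, selection
of dysregulated genes at a fold-change/FDR cutoff (two-fold or
greater, q <= 0.1 by default), and intersection with functional
annotation categories (e.g. cell-cycle genes, kinases).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ExpressionStudy

__all__ = [
    "AnnotationSet",
    "differential_expression",
    "select_dysregulated",
    "funnel_intersection",
    "load_annotation",
]


@dataclass(frozen=True)
class AnnotationSet:
    """A named functional gene category (identifiers uppercase-normalized)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "AnnotationSet":
        if not name:
            raise ValueError("annotation set needs a non-empty name")
        return cls(name, frozenset(normalize_gene_id(g) for g in genes))


def normalize_gene_id(gene: str) -> str:
    return str(gene).strip().upper()


def load_annotation(path, name: str | None = None) -> AnnotationSet:
    """Read a one-gene-per-line annotation file."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    from pathlib import Path
    return AnnotationSet.from_iterable(name or Path(path).stem, genes)


def differential_expression(study: ExpressionStudy, test: str = "student_t") -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential expression.

    For each gene: log2fc = mean(tumor) - mean(normal), a two-sided
    p-value from the chosen test, and a Benjamini-Hochberg q-value over
    all genes.  A gene that is constant within both groups and has equal
    means is untestable and gets p = 1 by convention.

    Parameters
    ----------
    study
        Log2 expression matrix with tumor/normal group labels.
    test
        ``"student_t"`` (pooled-variance t, default), ``"welch_t"``
        (unequal variance) or ``"mann_whitney"``.

    Returns
    -------
    DataFrame with columns gene, log2fc, p_value, q_value,
    dysregulated, overexpressed (the flags filled by
    :func:`select_dysregulated` defaults).
    """
    if test not in ("student_t", "welch_t", "mann_whitney"):
        raise ValueError(f"unknown test {test!r}")
    t_cols = study.group_columns("tumor")
    n_cols = study.group_columns("normal")
    if test in ("student_t", "welch_t") and (len(t_cols) < 2 or len(n_cols) < 2):
        raise ValueError("t tests need >= 2 samples per group")

    tumor = study.values[t_cols].to_numpy(dtype=float)
    normal = study.values[n_cols].to_numpy(dtype=float)
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)

    if test in ("student_t", "welch_t"):
        with np.errstate(divide="ignore", invalid="ignore"):
            res = stats.ttest_ind(tumor, normal, axis=1,
                                  equal_var=(test == "student_t"))
        p = np.asarray(res.pvalue, dtype=float)
        p[np.isnan(p)] = 1.0  # zero-variance / untestable genes
    else:
        p = np.empty(tumor.shape[0])
        for i in range(tumor.shape[0]):
            if np.all(tumor[i] == tumor[i][0]) and np.all(normal[i] == tumor[i][0]):
                p[i] = 1.0
            else:
                p[i] = stats.mannwhitneyu(tumor[i], normal[i],
                                          alternative="two-sided").pvalue
    q = multipletests(p, method="fdr_bh")[1]

    records = pd.DataFrame(
        {
            "gene": [normalize_gene_id(g) for g in study.genes],
            "log2fc": log2fc,
            "p_value": p,
            "q_value": q,
        }
    )
    sel = _selection_mask(records, 1.0, 0.1, "both")
    records["dysregulated"] = sel
    records["overexpressed"] = _selection_mask(records, 1.0, 0.1, "up")
    return records


def _selection_mask(records: pd.DataFrame, fc_threshold: float,
                    q_threshold: float, direction: str) -> pd.Series:
    if direction == "both":
        fc_ok = records["log2fc"].abs() >= fc_threshold
    elif direction == "up":
        fc_ok = records["log2fc"] >= fc_threshold
    elif direction == "down":
        fc_ok = records["log2fc"] <= -fc_threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return fc_ok & (records["q_value"] <= q_threshold)


def select_dysregulated(records: pd.DataFrame, fc_threshold: float = 1.0,
                        q_threshold: float = 0.1,
                        direction: str = "both") -> set[str]:
    """Select genes at |log2fc| >= fc_threshold and q <= q_threshold.

    Both cutoffs are inclusive ("two-fold or greater", FDR 0.1).
    ``direction`` restricts to up- or down-regulated genes by the sign
    of log2fc.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    if fc_threshold < 0 or q_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    mask = _selection_mask(records, fc_threshold, q_threshold, direction)
    return set(records.loc[mask, "gene"])


def funnel_intersection(dysregulated: set[str], categories: list[AnnotationSet]) -> set[str]:
    """Intersect the dysregulated set with every annotation category."""
    if not categories:
        raise ValueError("at least one annotation category required")
    result = {normalize_gene_id(g) for g in dysregulated}
    for cat in categories:
        result &= cat.genes
    return result
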