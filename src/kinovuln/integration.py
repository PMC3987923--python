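"""Candidate nomination: intersect over-expressed genes with screen hits.

A gene becomes a therapeutic candidate when it is both significantly
over-expressed in tumors and required for tumor-cell proliferation in
the siRNA screen.  Candidates carry their expression fold-change and
FDR q-value plus the screen's mean Z, and are ranked by the strength
of the proliferation phenotype (most negative mean Z first).
"""

from __future__ import annotations

import pandas as pd

from .expression import normalize_gene_id

__all__ = ["intersect_candidates", "candidate_report", "apply_aliases"]

REPORT_COLUMNS = ["rank", "gene", "log2fc", "q_value", "mean_z"]


def apply_aliases(genes, alias_map: dict[str, str] | None) -> set[str]:
    """Uppercase-normalize identifiers, mapping aliases to canonical ids."""
    norm_map = {normalize_gene_id(a): normalize_gene_id(c)
                for a, c in (alias_map or {}).items()}
    out = set()
    for g in genes:
        g = normalize_gene_id(g)
        out.add(norm_map.get(g, g))
    return out


def intersect_candidates(overexpressed, screen_hits, de: pd.DataFrame,
                         scores: pd.DataFrame,
                         alias_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Genes in both the over-expressed set and the screen hit set.

    Each candidate is annotated with log2fc and q_value from the DE
    table and mean_z from the screen score table, then ranked by
    ascending mean_z; ties break by descending log2fc, then gene id.

    Raises if a candidate is missing from either annotation table.
    """
    oe = apply_aliases(overexpressed, alias_map)
    hits = apply_aliases(screen_hits, alias_map)
    candidates = sorted(oe & hits)
    if not candidates:
        return pd.DataFrame(columns=REPORT_COLUMNS)

    de_idx = de.assign(gene=de["gene"].map(normalize_gene_id)).set_index("gene")
    sc_idx = scores.assign(gene=scores["gene"].map(normalize_gene_id)).set_index("gene")
    missing_de = [g for g in candidates if g not in de_idx.index]
    missing_sc = [g for g in candidates if g not in sc_idx.index]
    if missing_de or missing_sc:
        raise ValueError(
            f"candidates missing from DE table: {missing_de}; "
            f"from score table: {missing_sc}")

    table = pd.DataFrame(
        {
            "gene": candidates,
            "log2fc": [float(de_idx.at[g, "log2fc"]) for g in candidates],
            "q_value": [float(de_idx.at[g, "q_value"]) for g in candidates],
            "mean_z": [float(sc_idx.at[g, "mean_z"]) for g in candidates],
        }
    )
    table = table.sort_values(
        by=["mean_z", "log2fc", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    table.insert(0, "rank", range(1, len(table) + 1))
    return table


def candidate_report(candidates: pd.DataFrame, path=None) -> str:
    """Render the candidate table as a stable TSV (optionally to a file)."""
    out = candidates.reindex(columns=REPORT_COLUMNS)
    text = out.to_csv(sep="\t", index=False, float_format="%.6g")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
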