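"""Cell-type assignment of bulk differentially expressed genes.

Each bulk DEG is attributed to the single-nucleus cell type that best
explains it: the per-type pseudo-bulk stress-minus-control difference is
weighted by the per-type differential-test confidence, only cell types
changing in the same direction as the bulk are candidates, and the top
candidate is accepted only if it dominates the runner-up by at least a
factor of 2 — otherwise the gene is called ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Assignment", "assign_gene", "assign_all", "assignment_summary",
           "AMBIGUOUS", "NO_CONCORDANT"]

logger = logging.getLogger(__name__)

AMBIGUOUS = "AMBIGUOUS"
NO_CONCORDANT = "NO_CONCORDANT"


@dataclass
class Assignment:
    """Outcome of the weighted-difference rule for one gene."""

    gene_id: str
    celltype: str  # a cell type, AMBIGUOUS, or NO_CONCORDANT
    weights: pd.Series  # weighted |difference| per cell type
    bulk_sign: int


def assign_gene(
    gene_id: str,
    pseudobulk_stress: pd.Series,
    pseudobulk_control: pd.Series,
    p_values: pd.Series,
    bulk_sign: int,
    ratio: float = 2.0,
    weighting: str = "linear",
) -> Assignment:
    """Assign one bulk DEG to a cell type.

    ``weighting="linear"`` uses ``w_c = |delta_c| * (1 - p_c)`` (default);
    ``weighting="power"`` uses the alternative reading
    ``w_c = |delta_c| ** (1 - p_c)``. Candidates are cell types whose
    difference shares the bulk sign; the top candidate must exceed the
    second-largest weight over all cell types by ``ratio``, else AMBIGUOUS.
    Missing p-values for a cell type with a nonzero difference are treated
    as 1 (no confidence) and logged.
    """
    if bulk_sign not in (1, -1):
        raise ValueError("bulk_sign must be +1 or -1")
    cts = pseudobulk_stress.index
    if len(cts) < 2:
        raise ValueError("need at least two cell types")
    delta = pseudobulk_stress - pseudobulk_control.loc[cts]
    p = p_values.reindex(cts)
    if p.isna().any():
        bad = p.index[p.isna() & (delta != 0)].tolist()
        if bad:
            logger.warning("gene %s: missing p for %s, treating as 1", gene_id, bad)
        p = p.fillna(1.0)
    if weighting == "linear":
        w = delta.abs() * (1.0 - p)
    elif weighting == "power":
        w = delta.abs() ** (1.0 - p)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    concordant = np.sign(delta) == bulk_sign
    if not concordant.any() or w[concordant].max() <= 0:
        return Assignment(gene_id, NO_CONCORDANT, w, bulk_sign)
    top = w[concordant].idxmax()
    others = w.drop(top)
    second = float(others.max()) if len(others) else 0.0
    if second > 0 and float(w[top]) < ratio * second:
        return Assignment(gene_id, AMBIGUOUS, w, bulk_sign)
    return Assignment(gene_id, str(top), w, bulk_sign)


def assign_all(
    pseudobulk_stress: pd.DataFrame,
    pseudobulk_control: pd.DataFrame,
    p_values: pd.DataFrame,
    bulk_lfc: pd.Series,
    ratio: float = 2.0,
    weighting: str = "linear",
) -> pd.DataFrame:
    """Apply the assignment rule to every gene in ``bulk_lfc``.

    Matrices are genes x cell types; ``bulk_lfc`` gives the bulk direction.
    Returns a per-gene table with the assigned label and top weights.
    """
    rows = []
    for g in bulk_lfc.index:
        sign = 1 if bulk_lfc.loc[g] >= 0 else -1
        a = assign_gene(
            g,
            pseudobulk_stress.loc[g],
            pseudobulk_control.loc[g],
            p_values.loc[g],
            sign,
            ratio=ratio,
            weighting=weighting,
        )
        w = a.weights.sort_values(ascending=False)
        rows.append(
            {
                "gene_id": g,
                "celltype": a.celltype,
                "bulk_sign": sign,
                "w_top": float(w.iloc[0]),
                "w_second": float(w.iloc[1]) if len(w) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def assignment_summary(
    assignments: pd.DataFrame, family_map: dict[str, str]
) -> pd.Series:
    """Percentage of DEGs per cell-type family.

    Percentages are over assigned + ambiguous genes (non-concordant genes
    are excluded from the denominator); ambiguous genes are their own
    category. ``family_map`` maps each cell type to a family label (e.g.
    neuronal / glial / vascular).
    """
    if assignments.empty:
        raise ValueError("no assignments")
    labels = assignments["celltype"]
    kept = labels[labels != NO_CONCORDANT]
    def _family(ct: str) -> str:
        if ct == AMBIGUOUS:
            return "ambiguous"
        if ct not in family_map:
            raise KeyError(f"cell type {ct!r} has no family mapping")
        return family_map[ct]
    fam = kept.map(_family)
    if len(kept) == 0:
        return pd.Series(dtype=float)
    return 100.0 * fam.value_counts() / len(kept)
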