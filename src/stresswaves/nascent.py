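"""Spliced/unspliced gene quantification from read-overlap records.

Three counting schemes are applied to every aligned read:

  i)   exons as features (standard) — all reads;
  ii)  exons as features, non-split reads only;
  iii) transcript bodies as features, non-split reads only.

Scheme i quantifies processed (mature, exonic) transcripts. Scheme iii
counts everything lying within the transcript body without junctions —
mature and nascent signal alike — so the unprocessed (intron-containing)
signal is obtained by subtracting scheme ii from scheme iii.

All schemes share the acceptance filters: primary alignment, strand match
under a reverse-stranded protocol, at most ``non_overlap`` bases outside
any candidate feature, and at least ``frac_overlap`` of the read on the
feature. Reads overlapping several genes are assigned to the gene with the
largest relevant overlap; exact ties are left unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["classify_read", "count_schemes", "derive_gene_counts", "SCHEMES"]

logger = logging.getLogger(__name__)

SCHEMES = ("i", "ii", "iii")

#: column used for the overlap-fraction filter per scheme
_FRAC_COL = {
    "i": "exon_overlap_fraction",
    "ii": "exon_overlap_fraction",
    "iii": "transcript_overlap_fraction",
}


def classify_read(
    record,
    scheme: str,
    frac_overlap: float = 0.9,
    non_overlap: int = 3,
) -> bool:
    """Whether one read-gene candidate passes a counting scheme's filters.

    ``record`` is any mapping (dict, pandas row) with the ReadRecord fields.
    Pure function of its inputs.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if not bool(record["primary"]) or not bool(record["strand_match"]):
        return False
    if int(record["unmatched_bases"]) > non_overlap:
        return False
    if scheme in ("ii", "iii") and bool(record["split"]):
        return False
    return float(record[_FRAC_COL[scheme]]) >= frac_overlap


def count_schemes(
    reads: pd.DataFrame,
    frac_overlap: float = 0.9,
    non_overlap: int = 3,
) -> pd.DataFrame:
    """Tally accepted reads per gene under all three schemes.

    ``reads`` holds one row per read-gene candidate (several rows share a
    ``read_id`` when a read overlaps several genes). For each scheme, a read
    contributes one count to the candidate gene with the largest relevant
    overlap fraction among its accepted candidates; ties are unassigned.

    Returns a genes x (exonic_all, exonic_nonsplit, transcript_nonsplit)
    integer table covering every gene present in the input.
    """
    genes = pd.Index(sorted(reads["gene_id"].unique()) if len(reads) else [], name="gene_id")
    out = pd.DataFrame(
        0,
        index=genes,
        columns=["exonic_all", "exonic_nonsplit", "transcript_nonsplit"],
    )
    if reads.empty:
        return out

    base = (
        reads["primary"].astype(bool)
        & reads["strand_match"].astype(bool)
        & (reads["unmatched_bases"].astype(int) <= non_overlap)
    )
    nonsplit = ~reads["split"].astype(bool)
    for scheme, col in zip(SCHEMES, out.columns):
        ok = base & (reads[_FRAC_COL[scheme]].astype(float) >= frac_overlap)
        if scheme in ("ii", "iii"):
            ok = ok & nonsplit
        cand = reads.loc[ok, ["read_id", "gene_id", _FRAC_COL[scheme]]]
        if cand.empty:
            continue
        # largest-overlap resolution; exact ties -> unassigned
        frac = cand[_FRAC_COL[scheme]].astype(float)
        best = frac.groupby(cand["read_id"]).transform("max")
        at_max = cand[np.isclose(frac, best)]
        n_max = at_max.groupby("read_id")["gene_id"].transform("size")
        assigned = at_max[n_max == 1]
        tallies = assigned.groupby("gene_id").size()
        out.loc[tallies.index, col] = tallies.astype(int)
    return out


@dataclass
class GeneCountReport:
    """Processed/unprocessed counts plus the clamping summary."""

    counts: pd.DataFrame  # genes x (processed, unprocessed, clamped)
    n_clamped: int


def derive_gene_counts(triplets: pd.DataFrame) -> pd.DataFrame:
    """Processed and unprocessed counts from the three scheme tallies.

    processed   = exonic_all (scheme i)
    unprocessed = transcript_nonsplit − exonic_nonsplit (iii − ii),
                  clamped at 0 with a flag when the subtraction is negative
                  (possible only through threshold asymmetries).
    """
    raw = triplets["transcript_nonsplit"].astype(int) - triplets["exonic_nonsplit"].astype(int)
    clamped = raw < 0
    if clamped.any():
        logger.info(
            "derive_gene_counts: clamped %d negative unprocessed counts to 0", int(clamped.sum())
        )
    return pd.DataFrame(
        {
            "processed": triplets["exonic_all"].astype(int),
            "unprocessed": raw.clip(lower=0),
            "clamped": clamped,
        },
        index=triplets.index,
    )
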