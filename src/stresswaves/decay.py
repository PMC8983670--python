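"""Passive mRNA-decay consistency analysis.

Tests whether observed post-stress downregulation is explained by ordinary
first-order mRNA turnover after transcriptional rerouting, rather than by
active degradation. Under passive decay with transcription shut off, the
fraction of a transcript remaining after time ``t`` is ``2^(-t / t_half)``
— e.g. a gene set with median half-life 4.5 h is expected to be down ~11%
45 min after stress. Observed downregulation that tracks this expectation
(and stratifies with half-life) is consistent with passive decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["expected_remaining", "expected_downregulation_pct", "fc_by_halflife",
           "decay_consistency", "DecayReport"]


def expected_remaining(t: float, t_half: float):
    """Fraction of mRNA remaining after ``t`` hours of passive decay.

    Vectorised in either argument; requires ``t >= 0`` and ``t_half > 0``.
    """
    t = np.asarray(t, dtype=float)
    t_half = np.asarray(t_half, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if np.any(t_half <= 0):
        raise ValueError("t_half must be > 0")
    out = np.power(2.0, -t / t_half)
    return float(out) if out.ndim == 0 else out


def expected_downregulation_pct(t: float, t_half: float):
    """Expected passive downregulation in percent: 100 * (1 - 2^(-t/t_half))."""
    return 100.0 * (1.0 - expected_remaining(t, t_half))


@dataclass
class DecayReport:
    """Half-life-stratified fold-change summary."""

    bins: pd.DataFrame  # per bin: n, t_half range/median, median logFC
    cumulative: dict  # bin label -> sorted logFC array (cumulative distribution)
    n_unmatched: int  # genes without a half-life estimate


def fc_by_halflife(fc: pd.Series, hl: pd.Series, bins=4) -> DecayReport:
    """Stratify fold changes by half-life bins.

    ``fc`` maps gene -> logFC at one timepoint; ``hl`` maps gene -> half-life
    in hours. ``bins`` is either an integer (quantile bins, default
    quartiles) or explicit edges. Genes missing from ``hl`` are excluded and
    counted.
    """
    if (hl <= 0).any():
        raise ValueError("half-lives must be > 0")
    common = fc.index.intersection(hl.index)
    n_unmatched = len(fc) - len(common)
    if len(common) == 0:
        raise ValueError("no genes shared between fold changes and half-lives")
    fc_j = fc.loc[common]
    hl_j = hl.loc[common]
    if np.isscalar(bins):
        labels = pd.qcut(hl_j, int(bins), duplicates="drop")
    else:
        labels = pd.cut(hl_j, bins)
    if labels.nunique() < 2:
        raise ValueError("need at least two non-empty half-life bins")
    rows, cumulative = [], {}
    for lab, idx in fc_j.groupby(labels, observed=True).groups.items():
        vals = fc_j.loc[idx]
        rows.append(
            {
                "bin": str(lab),
                "n": len(vals),
                "t_half_median": float(hl_j.loc[idx].median()),
                "median_lfc": float(vals.median()),
            }
        )
        cumulative[str(lab)] = np.sort(vals.to_numpy())
    bins_df = pd.DataFrame(rows).set_index("bin")
    return DecayReport(bins=bins_df, cumulative=cumulative, n_unmatched=n_unmatched)


def decay_consistency(
    down_genes,
    fc: pd.Series,
    hl: pd.Series,
    t: float,
    tolerance: float = 5.0,
    convention: str = "median_lfc",
) -> dict:
    """Compare observed downregulation of a gene set with the passive law.

    expected_pct = 100 * (1 - 2^(-t / median half-life)) and observed_pct is
    either ``100 * (1 - 2^(median logFC))`` (default convention,
    ``"median_lfc"``) or the median of per-gene percent changes
    (``"median_pct"``). Consistency is declared when the two differ by at
    most ``tolerance`` percentage points.
    """
    down_genes = pd.Index(down_genes)
    common = down_genes.intersection(fc.index).intersection(hl.index)
    if len(common) == 0:
        raise ValueError("empty down-regulated gene set after join")
    med_hl = float(hl.loc[common].median())
    expected = expected_downregulation_pct(t, med_hl)
    if convention == "median_lfc":
        observed = 100.0 * (1.0 - 2.0 ** float(fc.loc[common].median()))
    elif convention == "median_pct":
        observed = float(np.median(100.0 * (1.0 - 2.0 ** fc.loc[common])))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return {
        "n_genes": int(len(common)),
        "median_t_half": med_hl,
        "expected_pct": float(expected),
        "observed_pct": float(observed),
        "consistent": bool(abs(expected - observed) <= tolerance),
    }
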