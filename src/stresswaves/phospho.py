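"""Differential analysis of modified-peptide intensity matrices.

The pipeline mirrors standard label-free phosphoproteomic practice:
missing-value filtering by condition, left-censored (MinProb) imputation,
empirical-Bayes moderated two-group tests with Benjamini-Hochberg FDR,
phosphopeptide enrichment statistics, and per-peptide stress x sex two-way
ANOVA.

The moderated test shrinks per-peptide variances toward a pooled prior
(prior df d0 and prior variance s0^2 estimated by moment matching on the
log-variance distribution) and refers the statistic to a t distribution
with ``residual df + d0`` degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PeptideMatrix",
    "DiffResult",
    "filter_missing",
    "impute_minprob",
    "moderated_diff",
    "bh_fdr",
    "enrichment_stats",
    "interaction_anova",
]

logger = logging.getLogger(__name__)


@dataclass
class PeptideMatrix:
    """Peptide x sample log2 intensities with sample and peptide metadata.

    ``values`` uses NaN for missing cells; ``samples`` is indexed by sample
    name and carries at least a ``condition`` column; ``peptides`` is
    indexed like ``values`` and may carry ``is_phospho``, ``protein_id``,
    ``site`` and ``localization_probability`` (site labels are only
    meaningful when the localization probability exceeds 0.75).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.samples = self.samples.set_index("sample") if "sample" in self.samples else self.samples
        if not self.values.columns.equals(pd.Index(self.samples.index)):
            self.samples = self.samples.loc[self.values.columns]
        if "localization_probability" in self.peptides:
            lp = self.peptides["localization_probability"]
            if ((lp < 0) | (lp > 1)).any():
                raise ValueError("localization_probability must lie in [0, 1]")
            if "site" in self.peptides:
                low = (lp <= 0.75) & (self.peptides["site"] != "")
                if low.any():
                    self.peptides = self.peptides.copy()
                    self.peptides.loc[low, "site"] = ""

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing)."""
        return self.values.isna()


def filter_missing(
    pm: PeptideMatrix, thr: int = 2, condition_col: str = "condition"
) -> PeptideMatrix:
    """Keep peptides with at most ``thr`` missing values in >= 1 condition.

    This is the standard missing-value filter of label-free differential
    pipelines: a peptide is retained if there exists a condition in which it
    was observed in all but at most ``thr`` replicates.
    """
    if thr < 0:
        raise ValueError("thr must be >= 0")
    cond = pm.samples[condition_col]
    if cond.nunique() < 2:
        raise ValueError("need at least two conditions")
    miss = pm.values.isna()
    per_cond = miss.T.groupby(cond).sum().T  # peptides x conditions
    keep = (per_cond <= thr).any(axis=1)
    logger.info("filter_missing: kept %d / %d peptides", int(keep.sum()), len(keep))
    return PeptideMatrix(
        values=pm.values.loc[keep],
        samples=pm.samples.reset_index(),
        peptides=pm.peptides.loc[keep] if len(pm.peptides) else pm.peptides,
    )


def impute_minprob(
    pm: PeptideMatrix, q: float = 0.01, sigma_scale: float = 1.0, seed: int | None = None
) -> PeptideMatrix:
    """Left-censored (MinProb) imputation of missing intensities.

    Each missing cell is drawn from a normal centred at its sample's ``q``
    quantile of observed log2 intensities, with standard deviation
    ``sigma_scale`` x the median of per-sample observed standard deviations.
    """
    rng = np.random.default_rng(seed)
    vals = pm.values.to_numpy(copy=True)
    obs_counts = (~np.isnan(vals)).sum(axis=0)
    if (obs_counts == 0).any():
        bad = pm.values.columns[obs_counts == 0].tolist()
        raise ValueError(f"samples with no observed values: {bad}")
    centers = np.nanquantile(vals, q, axis=0)
    sd = sigma_scale * float(np.median(np.nanstd(vals, axis=0, ddof=1)))
    miss = np.isnan(vals)
    if miss.any():
        draws = rng.normal(centers[None, :], sd, size=vals.shape)
        vals[miss] = draws[miss]
    return PeptideMatrix(
        values=pd.DataFrame(vals, index=pm.values.index, columns=pm.values.columns),
        samples=pm.samples.reset_index(),
        peptides=pm.peptides,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (x > 0)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match prior df d0 and prior variance s0^2 from sample variances.

    Works on the log scale: for s^2 ~ s0^2 * F(df, d0), log(s^2) has known
    digamma/trigamma moments; d0 solves a trigamma equation, s0^2 follows
    from the mean. Returns ``(inf, pooled mean)`` when the observed spread
    is no larger than the sampling spread (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def squeeze_var(s2: np.ndarray, df: float, d0: float, s0_2: float) -> np.ndarray:
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, float), s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


@dataclass
class DiffResult:
    """Differential-test results with the shrinkage diagnostics.

    ``table`` holds per-feature log2FC, t, raw p and BH-adjusted p (fdr).
    """

    table: pd.DataFrame
    test: str
    prior_df: float
    prior_var: float
    residual_df: float

    def summary(self, n: int = 10) -> str:
        head = self.table.sort_values("p").head(n)
        lines = [
            f"{self.test}: {len(self.table)} features, "
            f"residual df={self.residual_df:.1f}, prior df={self.prior_df:.2f}, "
            f"prior var={self.prior_var:.4f}",
            f"significant at FDR<0.05: {(self.table['fdr'] < 0.05).sum()}",
            head.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def moderated_diff(
    pm: PeptideMatrix,
    contrast: tuple[str, str],
    condition_col: str = "condition",
    block_col: str | None = None,
    prior_df: float | None = None,
) -> DiffResult:
    """Empirical-Bayes moderated two-group test per peptide.

    log2FC is the group-mean difference (first minus second element of
    ``contrast``). Variances are shrunk toward the moment-matched prior;
    with ``prior_df=0`` the test reduces to the ordinary two-sample t.
    An optional blocking factor is absorbed by within-block centring
    (paired-like adjustment), with the residual df reduced accordingly.
    """
    a, b = contrast
    cond = pm.samples[condition_col]
    sel = cond.isin([a, b])
    if not sel.any():
        raise ValueError(f"contrast levels {contrast} not found")
    y = pm.values.loc[:, sel.to_numpy()].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("matrix must be complete (impute first)")
    cond_sub = cond[sel]
    ga = (cond_sub == a).to_numpy()
    gb = (cond_sub == b).to_numpy()
    n1, n2 = int(ga.sum()), int(gb.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")

    df = n1 + n2 - 2
    if block_col is not None:
        blocks = pm.samples.loc[sel.to_numpy(), block_col]
        for blk in blocks.unique():
            m = (blocks == blk).to_numpy()
            y[:, m] -= y[:, m].mean(axis=1, keepdims=True)
        df -= blocks.nunique() - 1
    if df < 1:
        raise ValueError("zero residual degrees of freedom")

    ma = y[:, ga].mean(axis=1)
    mb = y[:, gb].mean(axis=1)
    lfc = ma - mb
    rss = ((y[:, ga] - ma[:, None]) ** 2).sum(axis=1) + (
        (y[:, gb] - mb[:, None]) ** 2
    ).sum(axis=1)
    s2 = rss / df

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, df)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.median(s2))
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, df)
    s2_post = squeeze_var(s2, df, d0, s0_2) if d0 > 0 else s2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc / se
    df_total = df + (d0 if np.isfinite(d0) else 0.0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    table = pd.DataFrame(
        {"log2fc": lfc, "t": tstat, "p": p, "fdr": bh_fdr(p)}, index=pm.values.index
    )
    return DiffResult(
        table=table,
        test=f"moderated t: {a} vs {b}",
        prior_df=d0,
        prior_var=s0_2,
        residual_df=float(df),
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def enrichment_stats(is_phospho, significant) -> dict:
    """Phosphopeptide enrichment among significant peptides.

    Returns the percentage of significant peptides that are phosphopeptides
    (integer, round-half-up, the convention of the reported counts), plus
    the odds ratio and two-sided Fisher exact p of the 2x2 phospho x
    significant table over all quantified peptides.
    """
    phos = np.asarray(is_phospho, dtype=bool)
    sig = np.asarray(significant, dtype=bool)
    if phos.shape != sig.shape:
        raise ValueError("mask length mismatch")
    n_sig = int(sig.sum())
    n_ps = int((phos & sig).sum())
    table = np.array(
        [
            [n_ps, int((phos & ~sig).sum())],
            [int((~phos & sig).sum()), int((~phos & ~sig).sum())],
        ]
    )
    odds, pval = stats.fisher_exact(table, alternative="two-sided")
    frac = 100.0 * n_ps / n_sig if n_sig else np.nan
    if n_sig == 0:
        logger.warning("enrichment_stats: no significant peptides; fraction undefined")
    return {
        "n_significant": n_sig,
        "n_phospho_significant": n_ps,
        "fraction_phospho_sig": _round_half_up(frac) if n_sig else np.nan,
        "fraction_phospho_sig_raw": frac,
        "odds_ratio": float(odds),
        "fisher_p": float(pval),
    }


def _rss(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Per-row residual sum of squares of y (features x samples) on X."""
    q, _ = np.linalg.qr(x)
    resid = y - (y @ q) @ q.T
    return (resid**2).sum(axis=1)


def interaction_anova(
    pm: PeptideMatrix, stress_col: str = "condition", sex_col: str = "sex"
) -> pd.DataFrame:
    """Per-peptide two-way ANOVA of stress x sex (type II F-tests).

    The interaction is tested by comparing the full two-factor model with
    the additive one; each main effect by dropping it from the additive
    model. Returns per-peptide p-values and the interaction contrast.
    """
    y = pm.values.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("matrix must be complete (impute first)")
    f1 = pd.Categorical(pm.samples[stress_col])
    f2 = pd.Categorical(pm.samples[sex_col])
    if len(f1.categories) != 2 or len(f2.categories) != 2:
        raise ValueError("both factors must have exactly two levels")
    a = (np.asarray(f1.codes) == 1).astype(float)
    b = (np.asarray(f2.codes) == 1).astype(float)
    cells = pd.crosstab(a, b)
    if (cells.to_numpy() == 0).any() or cells.shape != (2, 2):
        raise ValueError("all four stress x sex cells must be populated")

    one = np.ones_like(a)
    x_full = np.column_stack([one, a, b, a * b])
    x_add = np.column_stack([one, a, b])
    n = y.shape[1]
    df_full = n - 4
    if df_full < 1:
        raise ValueError("not enough residual degrees of freedom")

    rss_full = _rss(y, x_full)
    rss_add = _rss(y, x_add)
    rss_no_a = _rss(y, np.column_stack([one, b]))
    rss_no_b = _rss(y, np.column_stack([one, a]))

    def _f_p(rss0, rss1, q, dfres):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (rss0 - rss1) / q / (rss1 / dfres)
        return stats.f.sf(f, q, dfres)

    p_int = _f_p(rss_add, rss_full, 1, df_full)
    p_a = _f_p(rss_no_a, rss_add, 1, n - 3)
    p_b = _f_p(rss_no_b, rss_add, 1, n - 3)

    # interaction contrast (difference of stress effects between sexes)
    beta = np.linalg.lstsq(x_full, y.T, rcond=None)[0]
    return pd.DataFrame(
        {
            "p_interaction": p_int,
            f"p_{stress_col}": p_a,
            f"p_{sex_col}": p_b,
            "interaction_effect": beta[3],
            f"effect_{stress_col}": beta[1],
            f"effect_{sex_col}": beta[2],
        },
        index=pm.values.index,
    )
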