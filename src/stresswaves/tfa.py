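"""Transcription-factor activity from weighted regulons.

A regulon is a TF's set of target genes, each carrying a confidence
category (A best .. E worst), an interaction likelihood weight and a signed
mode of action (+1 activating, -1 repressing). Activity of a TF in a sample
is the likelihood-weighted mean of its targets' signed expression z-scores
on the unprocessed (nascent) fraction — nascent signal reflects ongoing
transcription and hence current TF activity. Category-E interactions are
discarded outright; targets shared by many TFs are down-weighted
(pleiotropy guard).

Differential activity over a region + timepoint design uses a moderated
F-test for dropping the timepoint terms, with the thresholds used for the
stress course: FDR < 0.005, max |activity logFC| > 0.2 and the TF's own
transcript at mean logCPM >= 2.

Finally, DEGs can be co-clustered on regulon membership merged with their
temporal logFC profiles using partitioning around medoids (PAM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phospho import bh_fdr, estimate_prior, squeeze_var

__all__ = [
    "Regulon",
    "build_regulons",
    "score_activity",
    "differential_activity",
    "build_tf_target_matrix",
    "pam",
    "cocluster",
    "DEFAULT_CATEGORY_WEIGHTS",
]

logger = logging.getLogger(__name__)

DEFAULT_CATEGORY_WEIGHTS = {"A": 1.0, "B": 0.8, "C": 0.6, "D": 0.4}


@dataclass
class Regulon:
    """One TF's signed, confidence-weighted target set."""

    tf: str
    targets: pd.DataFrame  # target, category, weight, mode

    def __len__(self) -> int:
        return len(self.targets)


def build_regulons(
    raw: pd.DataFrame,
    category_weights: dict[str, float] | None = None,
    min_targets: int = 5,
) -> list[Regulon]:
    """Build weighted regulons from a (tf, target, category, mode) table.

    Category E interactions are discarded; remaining categories receive the
    configured likelihood weights. TFs left with fewer than ``min_targets``
    targets are dropped (logged).
    """
    if category_weights is None:
        category_weights = DEFAULT_CATEGORY_WEIGHTS
    cats = set(raw["category"].unique())
    unknown = cats - set("ABCDE")
    if unknown:
        raise ValueError(f"unknown confidence categories: {sorted(unknown)}")
    kept = raw[raw["category"] != "E"].copy()
    kept["weight"] = kept["category"].map(category_weights).astype(float)
    if (kept["weight"] <= 0).any():
        raise ValueError("category weights must be positive")
    regulons = []
    for tf, grp in kept.groupby("tf"):
        if len(grp) < min_targets:
            logger.info("build_regulons: dropping %s (%d < %d targets)", tf, len(grp), min_targets)
            continue
        regulons.append(
            Regulon(tf=str(tf), targets=grp[["target", "category", "weight", "mode"]].reset_index(drop=True))
        )
    return regulons


def score_activity(
    expr: pd.DataFrame,
    regulons: list[Regulon],
    min_targets: int = 5,
    p_max: int = 10,
    standardize: bool = True,
) -> pd.DataFrame:
    """Sample-wise TF activity scores from unprocessed-fraction expression.

    ``expr`` is a genes x samples log-CPM matrix. Each gene is z-scored
    across samples (unless ``standardize=False``, in which case rows are
    assumed standardized already); activity(tf, sample) =
    sum_t w_t * mode_t * z(target_t, sample) / sum_t w_t. Targets belonging
    to more than ``p_max`` regulons are down-weighted by 1 / #regulons
    (pleiotropy guard). TFs with fewer than ``min_targets`` measured
    targets are dropped.
    """
    if standardize:
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1, ddof=1).replace(0.0, np.nan)
        z = expr.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    else:
        z = expr
    membership = pd.Series(0, index=z.index, dtype=int)
    for r in regulons:
        tg = pd.Index(r.targets["target"]).intersection(z.index)
        membership.loc[tg] += 1

    rows, names = [], []
    for r in regulons:
        t = r.targets[r.targets["target"].isin(z.index)]
        if len(t) < min_targets:
            logger.info("score_activity: dropping %s (%d measured targets)", r.tf, len(t))
            continue
        w = t["weight"].to_numpy(dtype=float)
        shared = membership.loc[t["target"]].to_numpy()
        w = np.where(shared > p_max, w / shared, w)
        signed = w * t["mode"].to_numpy(dtype=float)
        sub = z.loc[t["target"]].to_numpy()
        rows.append(signed @ sub / w.sum())
        names.append(r.tf)
    if not rows:
        raise ValueError("no regulon has enough measured targets")
    return pd.DataFrame(rows, index=names, columns=expr.columns)


def differential_activity(
    activity: pd.DataFrame,
    design: pd.DataFrame,
    tf_logcpm: pd.Series,
    fdr_threshold: float = 0.005,
    lfc_threshold: float = 0.2,
    logcpm_threshold: float = 2.0,
    region_col: str = "region",
    time_col: str = "timepoint_h",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Test each TF for temporal activity change (~region + timepoint).

    A moderated F-test compares the full model against the one without the
    timepoint factor; the activity "logFC" per timepoint is the difference
    of mean activity versus the earliest timepoint (scores are already on a
    log-like scale). A TF passes when FDR < ``fdr_threshold``, max |logFC|
    > ``lfc_threshold`` and its own transcript's mean logCPM >=
    ``logcpm_threshold``.
    """
    design = design.loc[activity.columns] if design.index.size else design
    tps = pd.Categorical(design[time_col])
    if len(tps.categories) < 2:
        raise ValueError("need at least two timepoints")
    regions = pd.get_dummies(design[region_col], drop_first=True, dtype=float)
    times = pd.get_dummies(design[time_col], drop_first=True, dtype=float)
    one = np.ones((len(design), 1))
    x_full = np.column_stack([one, regions.to_numpy(), times.to_numpy()])
    x_red = np.column_stack([one, regions.to_numpy()])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("rank-deficient design")

    y = activity.to_numpy(dtype=float)
    n = y.shape[1]
    q_t = times.shape[1]
    df_res = n - x_full.shape[1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    def _rss(x):
        qm, _ = np.linalg.qr(x)
        r = y - (y @ qm) @ qm.T
        return (r**2).sum(axis=1)

    rss_full = _rss(x_full)
    rss_red = _rss(x_red)
    s2 = rss_full / df_res
    if prior_df == 0:
        d0, s0_2 = 0.0, float(np.median(s2))
        s2_post, df_tot = s2, df_res
    else:
        d0, s0_2 = estimate_prior(s2, df_res)
        s2_post = squeeze_var(s2, df_res, d0, s0_2)
        df_tot = df_res + (d0 if np.isfinite(d0) else 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (rss_red - rss_full) / q_t / s2_post
    if np.isinf(df_tot):
        p = stats.chi2.sf(fstat * q_t, q_t)
    else:
        p = stats.f.sf(fstat, q_t, df_tot)

    # max |activity logFC| vs earliest timepoint
    t0 = tps.categories[0]
    base = y[:, (design[time_col] == t0).to_numpy()].mean(axis=1)
    max_lfc = np.zeros(len(y))
    for t in tps.categories[1:]:
        m = y[:, (design[time_col] == t).to_numpy()].mean(axis=1) - base
        max_lfc = np.maximum(max_lfc, np.abs(m))

    fdr = bh_fdr(p)
    logcpm = tf_logcpm.reindex(activity.index)
    passing = (
        (fdr < fdr_threshold)
        & (max_lfc > lfc_threshold)
        & (logcpm.to_numpy() >= logcpm_threshold)
    )
    return pd.DataFrame(
        {
            "F": fstat,
            "p": p,
            "fdr": fdr,
            "max_abs_lfc": max_lfc,
            "mean_logcpm": logcpm.to_numpy(),
            "passing": passing,
        },
        index=activity.index,
    )


def build_tf_target_matrix(
    regulons: list[Regulon], lfc: pd.DataFrame
) -> pd.DataFrame:
    """Merge z-scored signed regulon membership with temporal logFCs.

    The TF part has one column per TF with entry likelihood x mode for the
    TF's targets and 0 elsewhere; each column's nonzero entries are
    standardized (zeros stay zero, so non-targets exert no pull). The
    result is concatenated with the ``lfc`` columns (e.g. logFC at 45, 90
    and 120 min for unprocessed and processed fractions), restricted to the
    genes of ``lfc``.
    """
    genes = lfc.index
    tf_cols = {}
    for r in regulons:
        col = pd.Series(0.0, index=genes)
        t = r.targets[r.targets["target"].isin(genes)]
        col.loc[t["target"]] = (t["weight"] * t["mode"]).to_numpy()
        nz = col != 0
        if nz.sum() > 1 and col[nz].std(ddof=0) > 0:
            col[nz] = (col[nz] - col[nz].mean()) / col[nz].std(ddof=0)
        tf_cols[r.tf] = col
    tf_mat = pd.DataFrame(tf_cols, index=genes)
    return pd.concat([tf_mat, lfc], axis=1)


# ---------------------------------------------------------------------------
# partitioning around medoids


def pam(x: np.ndarray, k: int, max_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids with Euclidean dissimilarity.

    Classic deterministic BUILD initialisation followed by SWAP until no
    improving swap exists. Returns (labels, medoid indices). Suitable for
    the few hundred to few thousand points of a DEG set.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if k < 2 or k > n:
        raise ValueError("need 2 <= k <= n")
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))

    # BUILD: first medoid minimises total distance; then greedy gain
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, d[:, new])

    medoids = np.array(medoids)
    for _ in range(max_iter):
        dm = d[:, medoids]
        order = np.argsort(dm, axis=1)
        near = dm[np.arange(n), order[:, 0]]
        second = dm[np.arange(n), order[:, 1]]
        near_idx = order[:, 0]
        best_delta, best_swap = 0.0, None
        for mi in range(k):
            served = near_idx == mi
            for h in range(n):
                if h in medoids:
                    continue
                dh = d[:, h]
                # cost change of replacing medoid mi by h
                delta = np.where(
                    served,
                    np.minimum(dh, second) - near,
                    np.minimum(dh, near) - near,
                ).sum()
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    labels = np.argmin(d[:, medoids], axis=1)
    return labels, medoids


@dataclass
class CoclusterResult:
    """PAM co-clustering of DEGs on regulon membership + temporal profiles."""

    assignments: pd.Series  # gene -> cluster id
    medoids: pd.Index  # medoid gene ids
    sizes: pd.Series

    def summary(self) -> str:
        lines = [f"{len(self.sizes)} clusters over {len(self.assignments)} genes"]
        for c, s in self.sizes.items():
            lines.append(f"  cluster {c}: {s} genes, medoid {self.medoids[c]}")
        return "\n".join(lines)


def cocluster(tm: pd.DataFrame, k: int = 9, seed: int = 0) -> CoclusterResult:
    """Cluster genes on the merged TF-target / logFC matrix with PAM.

    ``seed`` is accepted for interface symmetry; BUILD+SWAP PAM is
    deterministic, so it only matters if the input were subsampled.
    """
    if len(tm) < k:
        raise ValueError("fewer genes than clusters")
    labels, med_idx = pam(tm.to_numpy(), k)
    assignments = pd.Series(labels, index=tm.index, name="cluster")
    sizes = assignments.value_counts().sort_index()
    return CoclusterResult(
        assignments=assignments,
        medoids=tm.index[med_idx],
        sizes=sizes,
    )
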