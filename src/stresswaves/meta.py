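"""Temporal wave clustering and surrogate-variable-adjusted meta-analysis.

Two independent facilities:

* k-means clustering of feature x (region, timepoint) logFC profiles into
  temporal "waves", with small clusters excluded from reporting (but never
  silently dropped) and clusters ordered by decreasing size;
* meta-analysis of stress effects across heterogeneous datasets (bulk
  transcriptome plus TRAP translatome experiments): surrogate variables
  capturing technical variation are estimated by SVD of the residuals after
  removing the protected design, with the dimension chosen against a
  row-permutation null, and included as additive covariates in per-gene
  linear models (additive: condition effect shared across datasets;
  interactive: additionally condition x dataset terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .phospho import DiffResult, bh_fdr

__all__ = [
    "ClusterResult",
    "SurrogateVariables",
    "kmeans_profiles",
    "elbow_report",
    "estimate_svs",
    "meta_fit",
    "log_cpm",
]


@dataclass
class ClusterResult:
    """Wave-clustering output.

    ``assignments`` maps feature -> reported cluster rank (0 = largest kept
    cluster) or -1 for members of excluded (undersized) clusters.
    ``summary`` holds per-cluster per-column mean logFC with SEM and SD.
    """

    assignments: pd.Series
    sizes: pd.Series  # kept clusters, decreasing size
    excluded: pd.Series  # excluded cluster sizes (original labels)
    summary: pd.DataFrame  # (cluster, stat) x columns
    inertia: float

    @property
    def empty(self) -> bool:
        return len(self.sizes) == 0


def kmeans_profiles(
    m: pd.DataFrame,
    k: int,
    min_size: int = 15,
    seed: int = 0,
    n_init: int = 50,
) -> ClusterResult:
    """Euclidean k-means of logFC profiles with small-cluster exclusion.

    ``k`` is a required analyst choice (5 was used for the phospho course,
    25 for the transcriptome); clusters with fewer than ``min_size``
    features are excluded from the report and listed separately. Kept
    clusters are relabelled by decreasing size.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(m) < k:
        raise ValueError("fewer features than clusters")
    if m.isna().any().any():
        raise ValueError("profile matrix must be complete")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(m.to_numpy())
    raw = pd.Series(raw, index=m.index)
    counts = raw.value_counts()
    kept = counts[counts >= min_size].sort_values(ascending=False)
    excluded = counts[counts < min_size]

    relabel = {old: rank for rank, old in enumerate(kept.index)}
    assignments = raw.map(lambda c: relabel.get(c, -1))

    rows = []
    for old, rank in relabel.items():
        sub = m.loc[raw == old]
        n = len(sub)
        rows.append(pd.concat({"mean": sub.mean(), "sd": sub.std(ddof=1),
                               "sem": sub.std(ddof=1) / np.sqrt(n)}, axis=0).rename(rank))
    summary = pd.DataFrame(rows) if rows else pd.DataFrame()
    if summary.size:
        summary.index.name = "cluster"
    return ClusterResult(
        assignments=assignments,
        sizes=pd.Series(kept.to_numpy(), index=range(len(kept)), name="size"),
        excluded=excluded,
        summary=summary,
        inertia=float(km.inertia_),
    )


def elbow_report(m: pd.DataFrame, k_range, seed: int = 0, n_init: int = 10) -> pd.DataFrame:
    """Inertia and silhouette per candidate k — a selection aid only.

    Automatic rating methods disagree on profile data, so the number of
    centers stays a manual choice; this report never auto-selects.
    """
    n = len(m)
    if n < 3:
        raise ValueError("need at least 3 features for an elbow report")
    x = m.to_numpy()
    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(x)
        sil = silhouette_score(x, km.labels_) if len(set(km.labels_)) > 1 else np.nan
        rows.append({"k": k, "inertia": float(km.inertia_), "silhouette": float(sil)})
    return pd.DataFrame(rows).set_index("k")


# ---------------------------------------------------------------------------
# surrogate variables


def log_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount (variance stabilisation)."""
    lib = counts.sum(axis=0)
    return np.log2((counts + pseudocount).div(lib + 2 * pseudocount, axis=1) * 1e6)


def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    parts = [np.ones((len(design), 1))]
    for col in design.columns:
        s = design[col]
        if s.dtype.kind in "ifu" and s.nunique() > 8:
            parts.append(s.to_numpy(dtype=float)[:, None])
        else:
            parts.append(pd.get_dummies(s.astype("category"), drop_first=True, dtype=float).to_numpy())
    return np.column_stack(parts)


@dataclass
class SurrogateVariables:
    """Estimated surrogate variables and selection diagnostics."""

    sv: pd.DataFrame  # samples x SVs
    n_sv: int
    singular_values: np.ndarray
    null_thresholds: np.ndarray

    def __len__(self) -> int:
        return self.n_sv


def estimate_svs(
    counts: pd.DataFrame,
    protected_design: pd.DataFrame,
    n_sv: int | None = None,
    n_permutations: int = 100,
    seed: int = 0,
    max_sv: int | None = None,
) -> SurrogateVariables:
    """Surrogate variables from residual SVD with permutation selection.

    The log-CPM matrix is regressed on the protected design (the biological
    model whose effects must not leak into the SVs); the right singular
    vectors of the residuals are candidate SVs. Unless ``n_sv`` is given,
    the dimension is chosen greedily: the k-th SV is kept while its singular
    value exceeds the 95th percentile of the k-th singular values obtained
    from ``n_permutations`` independent within-row permutations of the
    residuals. SVs are orthogonal to the protected design by construction.
    """
    x = _design_matrix(protected_design)
    n = len(protected_design)
    if n < x.shape[1] + 2:
        raise ValueError("not enough samples for the protected design")
    m = log_cpm(counts).to_numpy()
    q, _ = np.linalg.qr(x)
    resid = m - (m @ q) @ q.T
    # remove per-sample offsets (normalisation noise, unidentifiable from
    # library scaling) so they are not mistaken for latent structure
    resid = resid - resid.mean(axis=0, keepdims=True)
    if n - np.linalg.matrix_rank(x) < 1:
        raise ValueError("fewer residual degrees of freedom than 1")

    u, sv_vals, vt = np.linalg.svd(resid, full_matrices=False)

    rng = np.random.default_rng(seed)
    k_cap = max_sv if max_sv is not None else min(resid.shape) - 1
    if n_sv is None:
        null = np.empty((n_permutations, len(sv_vals)))
        idx = np.tile(np.arange(n), (m.shape[0], 1))
        for p in range(n_permutations):
            # parallel analysis: permute the data within rows, then rerun the
            # residualisation so null and observed singular values share scale
            perm = np.take_along_axis(m, rng.permuted(idx, axis=1), axis=1)
            perm = perm - (perm @ q) @ q.T
            perm = perm - perm.mean(axis=0, keepdims=True)
            null[p] = np.linalg.svd(perm, compute_uv=False)
        thresholds = np.percentile(null, 95, axis=0)
        n_sv = 0
        while n_sv < k_cap and sv_vals[n_sv] > thresholds[n_sv]:
            n_sv += 1
    else:
        thresholds = np.array([])
        n_sv = min(n_sv, k_cap)

    svs = vt[:n_sv].T
    # re-orthogonalise against the design for numerical hygiene
    if n_sv:
        svs = svs - q @ (q.T @ svs)
        svs, _ = np.linalg.qr(svs)
    sv_df = pd.DataFrame(
        svs, index=counts.columns, columns=[f"SV{i+1}" for i in range(n_sv)]
    )
    return SurrogateVariables(
        sv=sv_df, n_sv=n_sv, singular_values=sv_vals, null_thresholds=thresholds
    )


# ---------------------------------------------------------------------------
# meta-analysis fit


def meta_fit(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    svs: SurrogateVariables | pd.DataFrame | None = None,
    mode: str = "additive",
    condition_col: str = "condition",
    dataset_col: str = "dataset",
) -> DiffResult:
    """Per-gene linear meta-model of the stress effect across datasets.

    Fits ordinary least squares on log-CPM with surrogate variables as
    additive covariates. ``mode="additive"`` uses ``~SVs + condition`` and
    tests the shared condition coefficient; ``mode="interactive"`` uses
    ``~SVs + condition * dataset`` and tests the condition x dataset
    interaction block (the per-gene table then carries both ``p`` for the
    condition term and ``p_interaction``). BH FDR is applied per family.
    """
    if mode not in ("additive", "interactive"):
        raise ValueError("mode must be 'additive' or 'interactive'")
    cond = pd.Categorical(design[condition_col])
    dsets = pd.Categorical(design[dataset_col])
    if len(cond.categories) != 2:
        raise ValueError("condition must have exactly two levels")
    ct = pd.crosstab(design[condition_col], design[dataset_col])
    if (ct.to_numpy() == 0).any():
        raise ValueError(
            "condition is confounded with dataset (some condition absent "
            "from a dataset); the meta-model is aliased"
        )

    y = log_cpm(counts).to_numpy()
    n = y.shape[1]
    c = (np.asarray(cond.codes) == 1).astype(float)
    d_dum = pd.get_dummies(design[dataset_col], drop_first=True, dtype=float).to_numpy()
    sv_arr = None
    if svs is not None:
        sv_arr = svs.sv.to_numpy() if isinstance(svs, SurrogateVariables) else np.asarray(svs, float)
        if sv_arr.shape[1] == 0:
            sv_arr = None

    one = np.ones((n, 1))
    blocks = [one]
    if sv_arr is not None:
        blocks.append(sv_arr)
    if mode == "additive":
        x_full = np.column_stack(blocks + [c])
        x_red = np.column_stack(blocks)
        q_test = 1
    else:
        inter = d_dum * c[:, None]
        x_full = np.column_stack(blocks + [c[:, None], d_dum, inter])
        x_red = np.column_stack(blocks + [c[:, None], d_dum])
        q_test = inter.shape[1] if inter.size else 0
        if q_test == 0:
            raise ValueError("interactive mode needs >= 2 datasets")
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("aliased design (rank-deficient meta-model)")

    df_res = n - x_full.shape[1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")

    def _fit(x):
        qm, _ = np.linalg.qr(x)
        resid = y - (y @ qm) @ qm.T
        return (resid**2).sum(axis=1)

    rss_full = _fit(x_full)
    beta = np.linalg.lstsq(x_full, y.T, rcond=None)[0]

    if mode == "additive":
        rss_red = _fit(x_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (rss_red - rss_full) / (rss_full / df_res)
        p = stats.f.sf(f, 1, df_res)
        cond_coef = beta[-1]
        table = pd.DataFrame(
            {"log2fc": cond_coef, "F": f, "p": p, "fdr": bh_fdr(p)},
            index=counts.index,
        )
        label = "meta additive: condition"
    else:
        rss_red = _fit(x_red)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_int = (rss_red - rss_full) / q_test / (rss_full / df_res)
        p_int = stats.f.sf(f_int, q_test, df_res)
        # condition term tested in the reduced (additive within this fit) model
        rss_nocond = _fit(np.column_stack(blocks + [d_dum]))
        df_red = n - x_red.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_c = (rss_nocond - rss_red) / (rss_red / df_red)
        p_c = stats.f.sf(f_c, 1, df_red)
        n_sv_cols = 0 if sv_arr is None else sv_arr.shape[1]
        cond_coef = beta[1 + n_sv_cols]
        table = pd.DataFrame(
            {
                "log2fc": cond_coef,
                "F": f_c,
                "p": p_c,
                "fdr": bh_fdr(p_c),
                "F_interaction": f_int,
                "p_interaction": p_int,
                "fdr_interaction": bh_fdr(p_int),
            },
            index=counts.index,
        )
        label = "meta interactive: condition * dataset"
    return DiffResult(
        table=table,
        test=label,
        prior_df=0.0,
        prior_var=float("nan"),
        residual_df=float(df_res),
    )
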