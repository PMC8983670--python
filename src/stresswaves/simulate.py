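"""Synthetic multiomic stress-course data with known ground truth.

Emulates the measured layers of a 6-min acute-swim-stress experiment in
mouse hippocampus: a two-region (dHC/vHC) bulk RNA-seq time course sampled
45/90/120/180/240 min after stress onset, read-level data for the
spliced/unspliced counting stage, cell-type pseudo-bulk profiles, and an
early (6-45 min) phosphoproteomic wave with left-censored missingness.

Every generator takes an explicit seed and is bit-reproducible; each returns
a truth table alongside the observable data so downstream stages can be
validated against planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import GeneKinetics, simulate_kinetics

__all__ = [
    "CourseDesign",
    "PhosphoSimSpec",
    "GeneModel",
    "BulkSim",
    "CellTypeSim",
    "PhosphoSim",
    "sample_gene_population",
    "simulate_bulk_counts",
    "sample_gene_models",
    "simulate_reads",
    "simulate_celltype_profiles",
    "simulate_phospho",
]

DEFAULT_TIMEPOINTS = (0.75, 1.5, 2.0, 3.0, 4.0)
DEFAULT_REGIONS = ("dHC", "vHC")
DEFAULT_CELLTYPES = {
    "neurons": 0.55,
    "astrocytes": 0.20,
    "oligodendrocytes": 0.12,
    "vascular": 0.08,
    "microglia": 0.05,
}


@dataclass
class CourseDesign:
    """Bulk RNA-seq sampling design.

    ``timepoints`` are hours after stress onset; time 0 samples are the
    home-cage controls. 7 animals per group mirrors the study design;
    ``library_size`` (expected total processed counts per sample) and the
    negative-binomial dispersion are generator conventions.
    """

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_replicates: int = 7
    library_size: float = 1e7
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints)
        if any(t <= 0 for t in tps):
            raise ValueError("timepoints must be > 0 (0 is the implicit control)")
        if list(tps) != sorted(set(tps)):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        self.timepoints = tps

    @property
    def all_timepoints(self) -> tuple[float, ...]:
        return (0.0,) + self.timepoints


@dataclass
class PhosphoSimSpec:
    """Design of the synthetic phosphoproteomic wave.

    The transient phosphorylation wave peaks at ``wave_peak_time`` (hours)
    and relaxes with a Gaussian time profile of width ``wave_decay_time``,
    so effects are essentially gone by 30 min. ``effect_sd`` is the spread
    of planted log2 effect amplitudes; missingness is left-censored with a
    sharpness controlled by ``censoring_strength`` (0 = missing completely
    at random).
    """

    n_peptides: int = 2000
    phospho_fraction: float = 0.62
    responsive_fraction: float = 0.10
    phospho_enrichment: float = 1.5
    wave_peak_time: float = 0.1
    wave_decay_time: float = 0.12
    effect_sd: float = 1.0
    missing_rate: float = 0.2
    censoring_strength: float = 2.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.phospho_fraction <= 1.0:
            raise ValueError("phospho_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_peptides < 1:
            raise ValueError("need at least one peptide")
        if self.effect_sd < 0 or self.censoring_strength < 0:
            raise ValueError("effect_sd and censoring_strength must be >= 0")


# ---------------------------------------------------------------------------
# gene population


def sample_gene_population(
    n_genes: int = 2000,
    frac_induced: float = 0.05,
    frac_shutdown: float = 0.05,
    half_life_median: float = 4.5,
    half_life_sigma: float = 0.8,
    beta: float = 20.0,
    pulse_window: tuple[float, float] = (0.0, 1.0),
    induction_range: tuple[float, float] = (4.0, 16.0),
    rerouting: float = 1.0,
    celltypes: dict[str, float] | None = None,
    tfs: list[str] | None = None,
    targets_per_tf: int | None = None,
    seed: int = 0,
) -> list[GeneKinetics]:
    """Draw a gene population with planted induced and shut-down genes.

    Half-lives are log-normal with the given median (4.5 h matches the
    median of stress-downregulated genes in fibroblast decay tables) and
    sigma on the natural-log scale. Induced genes get a transcription pulse
    of fold ``U(induction_range)`` on ``pulse_window``; shut-down genes get
    ``alpha -> alpha * (1 - rerouting)`` over the same window (rerouting=1
    is a full shutdown). Induced genes are optionally attributed to driver
    TFs (round-robin) and to a planted responding cell type.
    """
    rng = np.random.default_rng(seed)
    if celltypes is None:
        celltypes = DEFAULT_CELLTYPES
    ct_names = list(celltypes)
    n_ind = int(round(n_genes * frac_induced))
    n_down = int(round(n_genes * frac_shutdown))
    if n_ind + n_down > n_genes:
        raise ValueError("frac_induced + frac_shutdown exceed 1")

    half_lives = np.exp(
        np.log(half_life_median) + half_life_sigma * rng.standard_normal(n_genes)
    )
    alpha0 = np.exp(np.log(10.0) + 1.0 * rng.standard_normal(n_genes))
    roles = np.array(["steady"] * n_genes, dtype=object)
    idx = rng.permutation(n_genes)
    roles[idx[:n_ind]] = "induced"
    roles[idx[n_ind : n_ind + n_down]] = "shutdown"

    genes: list[GeneKinetics] = []
    k_ind = 0
    for g in range(n_genes):
        role = roles[g]
        pulse = 1.0
        start, end = 0.0, 0.0
        amp: dict[str, float] = {}
        drivers: list[str] = []
        if role == "induced":
            pulse = float(rng.uniform(*induction_range))
            start, end = pulse_window
            ct = ct_names[int(rng.integers(len(ct_names)))]
            amp = {ct: 1.0}
            if tfs:
                drivers = [tfs[k_ind % len(tfs)]]
                k_ind += 1
        elif role == "shutdown":
            pulse = 1.0 - rerouting
            start, end = pulse_window
        genes.append(
            GeneKinetics(
                gene_id=f"g{g:05d}",
                alpha_baseline=float(alpha0[g]),
                alpha_pulse=pulse,
                pulse_start=start,
                pulse_end=end,
                beta=beta,
                half_life=float(half_lives[g]),
                celltype_amplitude=amp,
                tf_drivers=drivers,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# bulk counts


@dataclass
class BulkSim:
    """Bulk count simulation output: two count matrices plus ground truth."""

    processed: pd.DataFrame  # genes x samples
    unprocessed: pd.DataFrame  # genes x samples
    samples: pd.DataFrame  # sample, region, timepoint_h, replicate
    truth: pd.DataFrame  # per gene x timepoint true logFCs


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_bulk_counts(design: CourseDesign, genes: list[GeneKinetics]) -> BulkSim:
    """Simulate processed/unprocessed count matrices for a stress course.

    Per-sample expected counts are proportional to the mature (``s``,
    processed matrix) and pre-mRNA (``u``, unprocessed matrix) abundances at
    the sample's timepoint, scaled so the expected processed total equals
    ``library_size`` at baseline; the unprocessed library scales with the
    nascent fraction (roughly gamma/beta of the processed one), as in real
    intron-derived signal. Counts are negative-binomial.

    The truth table records, per gene and timepoint, the abundance-scale
    logFC (``true_lfc_*``) and the composition-aware CPM-scale logFC
    (``true_lfc_cpm_*``) that empirical normalised counts converge to.
    """
    if not genes:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(design.seed)
    tps = np.array(design.all_timepoints)
    n_g = len(genes)
    u = np.empty((n_g, tps.size))
    s = np.empty((n_g, tps.size))
    for i, g in enumerate(genes):
        u[i], s[i] = simulate_kinetics(g, tps)

    s_tot = s.sum(axis=0)
    u_tot = u.sum(axis=0)
    # baseline scaling: processed library = library_size at t=0
    scale = design.library_size / s_tot[0]

    gene_ids = [g.gene_id for g in genes]
    sample_rows = []
    proc_cols, unproc_cols, names = [], [], []
    for region in design.regions:
        for j, t in enumerate(tps):
            for rep in range(1, design.n_replicates + 1):
                name = f"{region}_t{int(round(t * 60)):03d}_r{rep}"
                names.append(name)
                sample_rows.append(
                    {"sample": name, "region": region, "timepoint_h": t, "replicate": rep}
                )
                proc_cols.append(_nb_draw(rng, s[:, j] * scale, design.nb_dispersion))
                unproc_cols.append(_nb_draw(rng, u[:, j] * scale, design.nb_dispersion))

    processed = pd.DataFrame(np.column_stack(proc_cols), index=gene_ids, columns=names)
    unprocessed = pd.DataFrame(np.column_stack(unproc_cols), index=gene_ids, columns=names)

    with np.errstate(divide="ignore"):
        truth_rows = []
        for j, t in enumerate(tps[1:], start=1):
            lfc_s = np.log2(s[:, j] / s[:, 0])
            lfc_u = np.log2(u[:, j] / u[:, 0])
            lfc_s_cpm = lfc_s - np.log2(s_tot[j] / s_tot[0])
            lfc_u_cpm = lfc_u - np.log2(u_tot[j] / u_tot[0])
            truth_rows.append(
                pd.DataFrame(
                    {
                        "gene_id": gene_ids,
                        "timepoint_h": t,
                        "true_lfc_processed": lfc_s,
                        "true_lfc_unprocessed": lfc_u,
                        "true_lfc_cpm_processed": lfc_s_cpm,
                        "true_lfc_cpm_unprocessed": lfc_u_cpm,
                        "half_life": [g.half_life for g in genes],
                        "role": [
                            "induced"
                            if (g.responsive and g.alpha_pulse > 1)
                            else ("shutdown" if g.responsive else "steady")
                            for g in genes
                        ],
                    }
                )
            )
    truth = pd.concat(truth_rows, ignore_index=True)
    samples = pd.DataFrame(sample_rows)
    return BulkSim(processed, unprocessed, samples, truth)


# ---------------------------------------------------------------------------
# reads


@dataclass
class GeneModel:
    """Minimal genomic gene model: ordered, non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("gene needs at least one exon")
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError("empty exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def mature_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def intron_length(self) -> int:
        return self.span - self.mature_length


def sample_gene_models(
    gene_ids: list[str],
    seed: int = 0,
    n_exons_range: tuple[int, int] = (2, 5),
    exon_len_range: tuple[int, int] = (100, 300),
    intron_len_range: tuple[int, int] = (200, 1000),
    read_length: int = 50,
    gap: int = 500,
    chrom: str = "chrSim",
) -> list[GeneModel]:
    """Lay out non-overlapping synthetic gene models along one chromosome.

    Intron lengths are kept >= ``read_length`` so fully intronic placement
    is always possible.
    """
    rng = np.random.default_rng(seed)
    lo = max(intron_len_range[0], read_length)
    models = []
    cursor = 1000
    for gid in gene_ids:
        n_ex = int(rng.integers(n_exons_range[0], n_exons_range[1] + 1))
        exons = []
        pos = cursor
        for i in range(n_ex):
            elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append((pos, pos + elen))
            pos += elen
            if i < n_ex - 1:
                pos += int(rng.integers(lo, intron_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(gid, chrom, strand, exons))
        cursor = pos + gap
    return models


def _mature_blocks(model: GeneModel, tpos: int, length: int) -> list[tuple[int, int]]:
    """Genomic blocks of a read starting at transcript coordinate ``tpos``."""
    blocks = []
    remaining = length
    offset = tpos
    for a, b in model.exons:
        elen = b - a
        if offset >= elen:
            offset -= elen
            continue
        take = min(remaining, elen - offset)
        blocks.append((a + offset, a + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    return blocks


def _exon_overlap(model: GeneModel, start: int, end: int) -> int:
    return sum(max(0, min(end, b) - max(start, a)) for a, b in model.exons)


def simulate_reads(
    models: list[GeneModel],
    abundances: dict[str, tuple[float, float]],
    n_reads: int,
    seed: int = 0,
    read_length: int = 50,
    p_secondary: float = 0.02,
    p_strand_flip: float = 0.02,
    p_overhang: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate aligned-read feature-overlap records with true origins.

    Under uniform fragmentation a molecule yields reads in proportion to
    its length, so reads are allocated to genes proportionally to
    ``u * span + s * mature_length`` and a gene's read is nascent with
    probability ``u * span / (u * span + s * mature_length)`` — this is why
    intron-derived signal is a sizeable share of real libraries even though
    pre-mRNA molecules are few. Mature reads are placed uniformly on the
    spliced transcript (split when they cross a junction); nascent reads
    uniformly on the unspliced genomic span, so the chance of a fully
    intronic read equals the intron share of placeable positions. A small fraction of reads is flagged
    secondary, strand-discordant, or shifted off the gene end to exercise
    the counting filters.

    Returns
    -------
    (records, truth) : records is the canonical read-record table (one row
    per read-gene candidate); truth holds per-read origin labels and a
    ``fully_intronic`` flag.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    by_id = {m.gene_id: m for m in models}
    gids = [m.gene_id for m in models if m.gene_id in abundances]
    if not gids:
        raise ValueError("no overlap between models and abundances")
    for m in models:
        if m.gene_id in abundances and m.span - read_length < 0:
            raise ValueError(f"gene {m.gene_id} shorter than read length")

    w = np.array(
        [
            abundances[g][0] * by_id[g].span + abundances[g][1] * by_id[g].mature_length
            for g in gids
        ],
        dtype=float,
    )
    probs = w / w.sum()
    gene_counts = rng.multinomial(n_reads, probs)

    rec_rows, truth_rows = [], []
    rid = 0
    for gid, n_g in zip(gids, gene_counts):
        if n_g == 0:
            continue
        m = by_id[gid]
        u_g, s_g = abundances[gid]
        mass = u_g * m.span + s_g * m.mature_length
        p_nasc = u_g * m.span / mass if mass > 0 else 0.0
        nasc = rng.random(n_g) < p_nasc
        for k in range(n_g):
            rid += 1
            read_id = f"r{rid:07d}"
            if nasc[k]:
                start = int(rng.integers(0, m.span - read_length + 1)) + m.start
                blocks = [(start, start + read_length)]
                split = False
                origin = "nascent"
            else:
                tpos = int(rng.integers(0, max(1, m.mature_length - read_length + 1)))
                blocks = _mature_blocks(m, tpos, read_length)
                split = len(blocks) > 1
                origin = "mature"
            unmatched = 0
            if rng.random() < p_overhang:
                # shift the read upstream off the gene start: bases outside
                # the gene span match no feature
                d = int(rng.integers(1, 9))
                first = blocks[0]
                blocks = [(first[0] - d, first[1] - d)] + list(blocks[1:])
                # recompute clip against gene span
                unmatched = max(0, m.start - blocks[0][0])
            exon_bp = sum(_exon_overlap(m, a, b) for a, b in blocks)
            span_bp = sum(
                max(0, min(b, m.end) - max(a, m.start)) for a, b in blocks
            )
            rec_rows.append(
                {
                    "read_id": read_id,
                    "gene_id": gid,
                    "split": split,
                    "exon_overlap_fraction": exon_bp / read_length,
                    "transcript_overlap_fraction": span_bp / read_length,
                    "unmatched_bases": unmatched,
                    "primary": bool(rng.random() >= p_secondary),
                    "strand_match": bool(rng.random() >= p_strand_flip),
                    "blocks": ";".join(f"{a}-{b}" for a, b in blocks),
                    "chrom": m.chrom,
                }
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "gene_id": gid,
                    "origin": origin,
                    "fully_intronic": exon_bp == 0 and unmatched == 0,
                }
            )
    records = pd.DataFrame(rec_rows)
    truth = pd.DataFrame(truth_rows)
    return records, truth


# ---------------------------------------------------------------------------
# cell-type pseudo-bulk profiles


@dataclass
class CellTypeSim:
    """Cell-type pseudo-bulk simulation output (log2 scale matrices)."""

    pseudobulk_stress: pd.DataFrame  # genes x celltypes, log2 mean
    pseudobulk_control: pd.DataFrame
    p_values: pd.DataFrame  # genes x celltypes
    bulk_lfc: pd.Series  # genes
    bulk_mean_stress: pd.Series  # noise-free linear-scale mixture
    bulk_mean_control: pd.Series
    truth: pd.DataFrame  # gene_id, responsive, origin, lfc


def simulate_celltype_profiles(
    celltypes: dict[str, float],
    genes: list[GeneKinetics],
    n_replicates: int = 2,
    at_time: float = 0.75,
    rep_sd: float = 0.15,
    baseline_log2: tuple[float, float] = (6.0, 1.5),
    seed: int = 0,
) -> CellTypeSim:
    """Simulate per-cell-type pseudo-bulks with planted response origins.

    A responsive gene changes only in the cell types named in its
    ``celltype_amplitude`` map (log2 effect = bulk-level logFC from its
    kinetics at ``at_time``, scaled by the amplitude). The bulk signal is
    the abundance-share-weighted linear mixture of the cell types, so the
    noise-free bulk means satisfy the mixture identity exactly. Per-type
    p-values come from a two-sample t-test on ``n_replicates`` vs
    ``n_replicates`` noisy pseudo-bulk replicates (2 animals per condition
    in the emulated design).
    """
    from scipy import stats

    if len(celltypes) < 2:
        raise ValueError("need at least two cell types")
    rng = np.random.default_rng(seed)
    ct_names = list(celltypes)
    shares = np.array([celltypes[c] for c in ct_names], dtype=float)
    shares = shares / shares.sum()
    n_g = len(genes)
    gene_ids = [g.gene_id for g in genes]

    base = rng.normal(baseline_log2[0], baseline_log2[1], size=(n_g, len(ct_names)))
    delta = np.zeros_like(base)
    truth_rows = []
    for i, g in enumerate(genes):
        lfc = 0.0
        origin = ""
        if g.responsive:
            amp = g.celltype_amplitude
            if amp and not any(v != 0 for v in amp.values()):
                raise ValueError(
                    f"responsive gene {g.gene_id} has all-zero cell-type amplitudes"
                )
            _, s = simulate_kinetics(g, [0.0, at_time])
            lfc = float(np.log2(s[1] / s[0]))
            if amp:
                for j, c in enumerate(ct_names):
                    delta[i, j] = lfc * amp.get(c, 0.0)
                origin = max(amp, key=lambda c: abs(amp[c]))
            else:
                # no planted origin (e.g. passive decay): uniform response
                delta[i, :] = lfc
                origin = "all"
        truth_rows.append(
            {"gene_id": g.gene_id, "responsive": g.responsive, "origin": origin, "lfc": lfc}
        )

    # replicate-level log2 matrices per condition: (gene, ct, rep)
    ctrl = base[:, :, None] + rng.normal(0, rep_sd, size=(n_g, len(ct_names), n_replicates))
    strs = (
        base[:, :, None]
        + delta[:, :, None]
        + rng.normal(0, rep_sd, size=(n_g, len(ct_names), n_replicates))
    )
    pb_ctrl = pd.DataFrame(ctrl.mean(axis=2), index=gene_ids, columns=ct_names)
    pb_strs = pd.DataFrame(strs.mean(axis=2), index=gene_ids, columns=ct_names)
    t_res = stats.ttest_ind(strs, ctrl, axis=2)
    pvals = pd.DataFrame(np.nan_to_num(t_res.pvalue, nan=1.0), index=gene_ids, columns=ct_names)

    # noise-free linear mixtures (exact identity) and noisy bulk logFC
    mix_ctrl = (2.0 ** base * shares).sum(axis=1)
    mix_strs = (2.0 ** (base + delta) * shares).sum(axis=1)
    bulk_ctrl_rep = (2.0 ** ctrl * shares[None, :, None]).sum(axis=1)
    bulk_strs_rep = (2.0 ** strs * shares[None, :, None]).sum(axis=1)
    bulk_lfc = np.log2(bulk_strs_rep.mean(axis=1) / bulk_ctrl_rep.mean(axis=1))

    return CellTypeSim(
        pseudobulk_stress=pb_strs,
        pseudobulk_control=pb_ctrl,
        p_values=pvals,
        bulk_lfc=pd.Series(bulk_lfc, index=gene_ids),
        bulk_mean_stress=pd.Series(mix_strs, index=gene_ids),
        bulk_mean_control=pd.Series(mix_ctrl, index=gene_ids),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# phospho


@dataclass
class PhosphoSim:
    """Synthetic peptide-level phospho dataset."""

    values: pd.DataFrame  # peptides x samples, NaN = missing
    samples: pd.DataFrame  # sample, condition, timepoint_h, replicate
    peptides: pd.DataFrame  # is_phospho, protein_id, site, localization_probability
    truth: pd.DataFrame  # responsive, effect, and per-sample complete matrix reference
    complete: pd.DataFrame  # uncensored matrix


def _wave(t: float, peak: float, width: float) -> float:
    return float(np.exp(-((t - peak) ** 2) / (2.0 * width**2)))


def simulate_phospho(
    spec: PhosphoSimSpec,
    timepoints: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75),
    n_replicates: int = 6,
) -> PhosphoSim:
    """Simulate a transient phosphorylation wave with left-censored missingness.

    Group 0 h is the home-cage control. Responsive peptides carry a log2
    effect ``amplitude * wave(t)`` where the wave is a Gaussian bump peaked
    at ``wave_peak_time`` — large right after the 6-min stressor, near zero
    by 30 min. Missingness is left-censored: the probability of a missing
    cell decreases with intensity on a probit scale whose slope is
    ``censoring_strength`` / intensity-sd, calibrated so the marginal
    missing rate equals ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    tps = (0.0,) + tuple(timepoints)
    n_p = spec.n_peptides
    pep_ids = [f"pep{i:05d}" for i in range(n_p)]

    n_resp = int(round(n_p * spec.responsive_fraction)) if spec.effect_sd > 0 else 0
    responsive = np.zeros(n_p, dtype=bool)
    responsive[rng.permutation(n_p)[:n_resp]] = True
    amplitude = np.where(responsive, rng.normal(0.0, spec.effect_sd, n_p), 0.0)
    # responsive peptides skew positive (phosphorylation wave is mostly up)
    amplitude = np.where(responsive & (rng.random(n_p) < 0.7), np.abs(amplitude), amplitude)

    # phospho flags, enriched among responsive peptides
    p_flag = np.full(n_p, spec.phospho_fraction)
    p_flag[responsive] = np.minimum(1.0, spec.phospho_fraction * spec.phospho_enrichment)
    is_phospho = rng.random(n_p) < p_flag

    base = rng.normal(spec.baseline_mean, spec.baseline_sd, n_p)

    cols, meta_rows = [], []
    data = np.empty((n_p, len(tps) * n_replicates))
    j = 0
    for t in tps:
        eff = amplitude * _wave(t, spec.wave_peak_time, spec.wave_decay_time) if t > 0 else 0.0
        for rep in range(1, n_replicates + 1):
            name = f"t{int(round(t * 60)):03d}_r{rep}"
            cols.append(name)
            meta_rows.append(
                {
                    "sample": name,
                    "condition": "control" if t == 0 else f"stress_{int(round(t*60))}min",
                    "timepoint_h": t,
                    "replicate": rep,
                }
            )
            data[:, j] = base + eff + rng.normal(0, spec.noise_sd, n_p)
            j += 1

    complete = pd.DataFrame(data, index=pep_ids, columns=cols)

    if spec.missing_rate > 0:
        sd_all = float(np.std(data))
        if spec.censoring_strength > 0:
            slope = spec.censoring_strength / sd_all
            from scipy import stats as _st
            from scipy.optimize import brentq

            flat = data.ravel()

            def _marginal(tau: float) -> float:
                return float(np.mean(_st.norm.cdf(slope * (tau - flat)))) - spec.missing_rate

            lo, hi = flat.min() - 10 * sd_all, flat.max() + 10 * sd_all
            tau = brentq(_marginal, lo, hi)
            p_miss = _st.norm.cdf(slope * (tau - data))
        else:
            p_miss = np.full_like(data, spec.missing_rate)
        mask = rng.random(data.shape) < p_miss
    else:
        mask = np.zeros_like(data, dtype=bool)

    values = complete.mask(mask)
    peptides = pd.DataFrame(
        {
            "is_phospho": is_phospho,
            "protein_id": [f"prot{i // 4:04d}" for i in range(n_p)],
            "site": [f"S{(i * 7) % 900 + 1}" if f else "" for i, f in enumerate(is_phospho)],
            "localization_probability": np.where(is_phospho, rng.uniform(0.76, 1.0, n_p), 0.0),
        },
        index=pep_ids,
    )
    truth = pd.DataFrame(
        {"responsive": responsive, "amplitude": amplitude}, index=pep_ids
    )
    return PhosphoSim(
        values=values,
        samples=pd.DataFrame(meta_rows),
        peptides=peptides,
        truth=truth,
        complete=complete,
    )
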