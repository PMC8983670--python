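# Methods

## The kinetic model

Each gene is a linear two-compartment system

    du/dt = α(t) − β u        (pre-mRNA / unprocessed)
    ds/dt = β u − γ s         (mature mRNA / processed)

with transcription rate α(t) piecewise constant, processing (splicing +
export) rate β and first-order decay rate γ = ln 2 / t½. The solver
propagates the exact matrix-exponential solution segment by segment, so
trajectories carry no integration error (the β = γ degeneracy uses the
Δt·e^(−βΔt) limit branch). The system starts at the baseline steady state
u* = α₀/β, s* = α₀/γ.

Parameter conventions and defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| half-life t½ | log-normal, median 4.5 h, σ = 0.8 (ln scale) | h | mammalian mRNA half-life distributions are roughly log-normal; 4.5 h matches the median reported for stress-downregulated transcripts in fibroblast decay tables. The generator replaces external half-life estimates with known truth so decay consistency can be tested exactly. |
| processing rate β | 20 / h | 1/h | pre-mRNA half-life ≈ 2 min, a literature-typical splicing timescale; the in-vivo value is unknown and β is a free parameter — any β ≫ γ preserves the limits the tests rely on. |
| baseline α₀ | log-normal, median 10, σ = 1 | molecules/h | generic expression-abundance spread. |
| induction pulse | α × U(4, 16) on [0, 1 h] | — | immediate-early-gene-like fold inductions peaking 45–90 min. |
| rerouting r | 1 (full shutdown) | — | downregulation is modelled as α → α(1 − r); r = 1 lets the decay module see pure passive decay. Active degradation (γ multiplied) is generated analytically in the tests as the contrast case. |
| library size | 10⁷ (course), smaller in tests | counts | typical bulk RNA-seq depth; not stated by the emulated study. |
| NB dispersion | 0.05 | — | typical bulk RNA-seq biological dispersion; 0 gives Poisson. |
| replicates | 7 per group | animals | the emulated design used 7–8 mice per group. |

## Read simulation and the three counting schemes

Reads are allocated to genes proportionally to u·(genomic span) +
s·(mature length) — under uniform fragmentation a molecule contributes
reads in proportion to its length, which is why intronic signal is a
sizeable fraction of real libraries although pre-mRNA molecules are few. A
gene's read is nascent with probability u·span / (u·span + s·mature).
Mature reads are placed uniformly on the spliced transcript and become
split (junction-spanning) when they cross an exon boundary; nascent reads
are placed uniformly on the unspliced span. Small fractions of secondary,
strand-discordant and gene-overhanging reads exercise the filters. Reads
carry coordinates and overlap summaries, not base strings.

Classification follows featureCounts-style semantics: primary alignment,
strand concordance under a reverse-stranded protocol, at most 3 bases
outside candidate features, at least 90 % of the read on the feature (exons
for schemes i/ii, the transcript body for scheme iii); schemes ii and iii
reject split reads. Reads overlapping several genes go to the gene with the
largest relevant overlap; exact ties are left unassigned to avoid double
counting (the original tool's tie policy is unstated). Negative
unprocessed counts (possible only through threshold asymmetries between
schemes ii and iii) are clamped to zero and flagged.

GTF coordinates are 1-based closed on disk, converted to 0-based half-open
internally. The SAM adapter assumes single-end alignments; "strand match"
means the read aligns antisense to the gene (reverse-stranded library).

## Decay consistency

`expected_remaining(t, t½) = 2^(−t/t½)`; the consistency check compares
100·(1 − 2^(−t/median t½)) with the observed loss. Two conventions for
"observed" exist — percent of the median logFC (default) or median of
per-gene percent losses; they coincide up to median interpolation because
the transform is monotone. The tolerance (5 percentage points) and the
half-life binning (quartiles) are analyst conventions, config-exposed; the
emulated analysis reported only a qualitative judgment.

A genuine limitation: at 45 min (t ≪ t½) passive shutdown and a doubling of
γ produce nearly identical mature-pool losses (10.9 % vs 10.3 % at
t½ = 4.5 h), so no median-based test can separate the mechanisms there.
The discrimination test therefore evaluates the 240-min timepoint of the
stated design, where the curves diverge (46 % vs 35 % at 2×): shutdown
worlds are called consistent and γ-doubling worlds inconsistent. A green
discrimination test establishes mechanism separation late in the course,
not at the earliest timepoint.

## Phosphoproteomic statistics

The simulated wave is a Gaussian bump in time peaked at 6 min (width
7 min), so planted effects are essentially gone by 30 min, matching the
fast on/off kinetics of stress-induced phosphorylation. Missingness is
left-censored: P(missing | intensity x) = Φ(slope·(τ − x)) with slope =
censoring_strength / sd(x) and τ calibrated by root-finding so the marginal
missing rate is exact; censoring_strength 0 degrades to missing completely
at random.

MinProb imputation draws each missing cell from N(q-quantile of that
sample's observed intensities, (σ_scale × median per-sample observed sd)²)
with q = 0.01 — the standard left-censored formulation; the emulated
pipeline names only the method and q.

The moderated test shrinks per-peptide variances toward a prior estimated
by moment matching on log s² (digamma/trigamma inversion): posterior
s̃² = (d₀s₀² + df·s²)/(d₀ + df), t referred to df + d₀ degrees of freedom.
When the observed variance spread is no wider than sampling noise the prior
df is infinite and the test uses the pooled variance with a normal
reference. `prior_df=0` reduces exactly to the ordinary two-sample t (a
tested limit). An optional blocking factor is absorbed by within-block
centring with the residual df reduced by (#blocks − 1). Two-way
stress × sex ANOVA uses type-II F-tests (interaction: full vs additive;
mains: dropped from the additive model).

Reported phospho fractions round half-up to integer percent, which
reproduces 62 % (10132/16302), 94 % (253/269) and 91 % (188/206) exactly.

## TF activity

Activity(tf, sample) = Σ w·mode·z(target, sample) / Σ w on gene-wise
z-scored unprocessed log-CPM. This replaces a pleiotropy-corrected
enrichment statistic with a transparent weighted mean whose permutation
null is exactly N(0, Σw²/(Σw)²) — a tested property. Pleiotropy is handled
by down-weighting targets shared by more than 10 regulons by 1/#regulons.
Category weights A–D = 1.0/0.8/0.6/0.4 preserve the benchmark ordering;
the exact values used originally are unpublished, and only the ordering
matters downstream. Differential activity uses a moderated F-test for
dropping the timepoint factor from ~region + timepoint; the activity
"logFC" is the difference of mean activities versus the earliest timepoint
(scores are already log-like).

The TF-target co-clustering matrix standardises each TF column over its
nonzero support (zeros stay zero, so non-targets exert no pull) and
concatenates the temporal logFC columns. PAM is the classic deterministic
BUILD + SWAP algorithm on Euclidean distances — no Python implementation
was available in the environment, so it is implemented here and validated
on planted partitions.

## Cell-type assignment

w_c = |pseudo-bulk stress − control|_c · (1 − p_c). The published phrase
"multiplying it by the power of 1 minus the p value" is grammatically
ambiguous; the multiplicative reading is the default and the power reading
(|Δ|^(1−p)) is available behind `weighting="power"` — both are monotone in
the required directions. The 2× dominance comparison runs against the
second-largest weight over *all* cell types (not only direction-concordant
ones), the stricter reading. Missing p-values are treated as 1 and logged.
Summary percentages are over assigned + ambiguous genes; pseudo-bulk
normalisation defaults to log-CPM-like log2 values.

## Surrogate variables and the meta-model

Counts are variance-stabilised as log2 CPM with pseudocount 0.5 (a
transparent, dependency-free stand-in for model-based transformations).
The matrix is residualised against the protected design, per-sample offsets
are removed (library-normalisation noise is unidentifiable and must not be
mistaken for latent structure), and the right singular vectors of the
residuals are candidate SVs. Dimension selection is parallel analysis: the
k-th singular value must exceed the 95th percentile of k-th singular values
from 100 within-row permutations of the data, each re-residualised so null
and observed spectra share the projection's rank — without that
re-projection the null is systematically deflated and the procedure
over-calls SVs. SVs are orthogonal to the protected design by construction.

`meta_fit` is ordinary least squares per gene (unmoderated — with one
dataset and no SVs it must reduce exactly to the ordinary linear model):
additive mode fits ~SVs + condition and tests the condition coefficient;
interactive mode fits ~SVs + condition * dataset and tests the interaction
block by F-test, with BH FDR per test family. The dataset main effect is
deliberately absent from the additive GLM, following the emulated model
specification (dataset is protected during SV estimation instead).
Condition nested within dataset aborts with an aliasing diagnostic.

## Wave clustering

Euclidean k-means with 50 restarts (best inertia kept, seeded); k is a
required analyst input — 5 for the phospho course, 25 for the transcriptome
in the emulated study — because rating indices disagree on profile data and
automatic selection would hide that choice. Clusters with fewer than 15
members are excluded from the report but listed with their sizes, never
silently dropped; kept clusters are relabelled by decreasing size and
summarised as per-column mean ± SEM and SD, recomputable exactly from the
assignments (a tested invariant). `elbow_report` provides inertia and
silhouette diagnostics and never auto-selects k.

## What the generators do and do not establish

The synthetic world has: known kinetic truth per gene, NB count noise,
cell-type mixtures that sum exactly before noise, a transient phospho wave
with calibrated left-censoring, and planted TF drivers. It does not have:
real sequence content, isoform structure, ambient RNA/doublets, droplet
chemistry, region-specific biology (dHC and vHC share kinetics), or
correlated gene-gene noise beyond library composition. Green tests
establish that each algorithm recovers planted structure under its stated
error model — not that the biological conclusions of any particular dataset
are reproduced.

## Numerical conventions

- All RNGs are `numpy.random.default_rng` with explicit seeds; every
  generator is bit-reproducible.
- The β ≈ γ kinetic branch switches at a relative difference of 1e-9.
- Trigamma inversion runs Newton to 1e-10 relative tolerance; prior df is
  capped at infinity (normal reference) when moment matching degenerates.
- PAM swaps require an improvement > 1e-12 to terminate deterministically.
- k-means ties and symmetry are resolved by scikit-learn's seeded init;
  PAM's BUILD is fully deterministic.
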