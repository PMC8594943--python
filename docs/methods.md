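# Methods

This note documents the models behind `iriskit`: what the synthetic
generators emulate, the measurement procedures, the tunable parameters and
their defaults, and the numerical choices made where the design was open.

## Synthetic snRNA-seq atlas

### Model

A library is a sparse count matrix over `n_genes = 2000` genes (13 of them
the mouse mitochondrial protein-coding genes) and
`n_nuclei_per_library = 9000` nuclei. Each nucleus is assigned one of ten
populations — dilator, sphincter 1, sphincter 2, stroma 1, stroma 2, iris
pigment epithelium (PE), ciliary-body epithelium (CBE), ciliary body (CB),
endothelial, leukocyte — by a multinomial draw on fixed proportions. The
proportions are anchored to the study design: endothelial (1.2%) and
leukocyte (0.8%) land in the 50–200-nuclei-per-library band of the rarest
populations, while dilator (20%), iris PE (19%) and stroma 2 (19%) each
exceed 1600 nuclei per library.

Counts are gamma–Poisson (negative binomial) with per-gene dispersion
`0.3`, typical of droplet data. Expected means are built from a shared
lognormal(0, 1.5) base-expression vector; each population multiplies its
40 marker genes by `marker_fold = 8` (canonical names — *Adra1a*, *Ttn*,
*Rbfox3*, *Chrm3*, *Syt1*, *Sox10*, *Tfap2b*, *Zic1*, *Otx1/2*, *Erg*,
*Ptprc*, … — head each program); the profile is then scaled so the
expected detected transcripts per nucleus equal
`target_mean_detected = 1760`. Mitochondrial genes carry ~0.2% of reads, a
level at which sampling noise cannot push an ordinary nucleus over the 1%
QC threshold, so the planted QC tail (below) is identifiable exactly.

**Conditions.** The constricted condition is, by construction, identical in
expectation to untreated — the pharmacologically constricted iris is
transcriptionally near-indistinguishable from the resting iris, and the
generator encodes that as exact equality of expected means. The dilated
condition applies a gene-wise `2^effect` program without renormalization:
180 dilator-muscle genes with |log₂ effect| uniform in [1.0, 3.0] (75%
up-regulated; the named dilation-responsive transcripts *Pde10a*, *Btg2*,
*Egr1*, *Junb*, *Slc26a4*, *Tmem158*, *Anks1b* and four *Pde* family
members head the list), plus 20 genes with smaller effects (|log₂| in
[0.3, 0.7]) shared by sphincter 1/2, stroma 1/2, iris PE and leukocytes.
Endothelial, CBE and CB carry no program, mirroring the three populations
with little dilation response. Program genes are drawn from the
mid-expression band (25th–75th weight percentile) so the program perturbs,
but does not dominate, library totals.

The program magnitudes are a calibration, not free dials: they are sized so
that the dilator pseudobulk R²(dilated vs untreated) falls at or below
0.920 — the study's printed value — while R²(constricted vs untreated)
stays at or above 0.983. A program of 100 genes at |log₂| ∈ [0.8, 2.5]
(an earlier candidate) leaves R² ≈ 0.97 at a 2000-gene universe: the
variance it injects, ≈ (fraction of genes) × E[effect²_log10], is several
times too small against the ≈0.5 variance of log₁₀ pseudobulk profiles.

**Replicates.** Each library multiplies every gene by an independent
lognormal(0, `replicate_jitter_sd = 0.08`) factor. This value is set so
that a *single pair* of libraries reproduces the printed per-cell-type
technical R² (0.983–0.991) for the large populations. The study's printed
replicate Pearson band (0.98–0.99) and its per-cell-type technical R² were
measured after merging 2–3 replicates per condition, which shrinks jitter
variance ~3-fold; with one library per side both anchors cannot hold at
once, and the technical-R² anchor was chosen as binding. Whole-library
replicate correlations consequently sit at ≈ 0.995–0.997, at the top of
(slightly above) the printed band.

**Planted QC tail.** 1.2% of nuclei are scaled to an expected total of
~260 (below the 500 floor), 0.6% to ~7900 (above the 6000 ceiling), and
0.7% get mitochondrial means raised to 5% of reads. Each violation sits
>5σ beyond its threshold, so the planted set coincides exactly with the
set removed by the QC filter; this identity is asserted in the tests.

### What it does not emulate

No doublets, no ambient RNA, no batch structure beyond gene-wise jitter,
no gene–gene correlation within a population, and a 10-fold-reduced gene
universe. Passing tests therefore demonstrate correctness of the
*procedures* (filters, averages, correlations, tests) under a faithful
count-noise model — not robustness to every artifact of real droplet data.

## QC, normalization, pseudobulk

Boundary semantics follow the exclusion rules as stated: nuclei are removed
for mito fraction **>** 1% or totals **<** 500 or **>** 6000, so boundary
nuclei are retained. Mitochondrial genes are resolved by the
case-insensitive identifier prefix `mt-` (configurable).

Normalization is log-CPM: `ln(1 + count·10⁴/total)`. The original analysis
used a regularized negative-binomial regression (SCTransform); every
statistic downstream of normalization here (R², percent-expressing,
z-scaled means, t-tests) is equally well-defined under log-normalization,
so the simpler transform sits behind a single pluggable operation and is
the documented substitution. Pseudobulk averages follow the
de-log-then-mean convention (mean of `expm1` over cells), matching the
AverageExpression convention; whether the original figures de-logged
before averaging is not stated, so this choice is flagged for anyone
comparing to deposited data.

Clustering is scaled-PCA (30 components) → kNN graph (k = 15) → Leiden.
The default resolution is **0.2**: at 0.5, modularity optimization
fragments even a perfectly homogeneous population's kNN graph into several
communities (a generic property of Leiden/Louvain on unstructured graphs),
whereas at 0.2 a homogeneous population stays in one community *and* the
default ten-population atlas still resolves into exactly ten communities
with adjusted Rand index 1.0 against the planted labels. The original
clustering parameters are not published; these defaults are this package's
choice.

## Comparison statistics

R² uses log₁₀(x + 1) on the per-cell-type pseudobulk, restricted to genes
with nonzero average on at least one side ("all transcripts" is undefined
at zero–zero genes under a log). The pseudocount is 1; the original
handling of zeros is unstated. ΔR² is constricted-minus-dilated, so a
positive value means dilation moved the transcriptome further than
technical noise — the direction that makes seven of ten cell types
positive.

Differential expression uses the equal-variance Student's *t* (as named,
not Welch), computed from sufficient statistics; `p = 1` when both groups
have zero variance and equal means, `p = 0` (infinite t) when variance is
zero but means differ. Log₂ fold changes come from de-logged group means
with pseudocount ε = 0.01. The Bonferroni multiplier is the **total**
number of genes in the dataset, not the number tested. Because a contrast
between two single libraries includes replicate-level jitter, a few
non-planted genes can pass in jittered contrasts; the family-wise error
guarantee is therefore asserted under the exchangeable null (no planted
effects, no jitter), where it is a clean Bonferroni property.

## RNAscope quantification

The two printed formulas are evaluated literally; their algebra makes the
ROI estimate exactly background-independent for uniform dots, which the
tests exploit (exact recovery over a background × dot-count grid, and
linearity with slope 1). Dot counts are kept fractional — the formulas
yield reals — and negative estimates (noise on near-empty ROIs) are floored
at 0 and flagged rather than raised.

Dot selection was manual in the original workflow ("20 representative
single dots"). The automated surrogate detects isolated local maxima above
background + 3σ on a lightly smoothed image (a uniform dot is an intensity
plateau, so detection without smoothing finds several coequal maxima per
dot), segments a disk of the nominal dot radius around each, ranks by
background-corrected integrated intensity, and picks the *n* dots spanning
the interquartile band — "representative" read as mid-distribution, which
avoids the brightest, possibly merged, dots.

## Nuclear morphometry

Synthetic fields place non-overlapping ellipses (hard-core sequential
placement with a 50·n retry cap) with axis ratios drawn normal around the
preset mean, truncated at 1, at random orientation. The preset means are
the study's values: sphincter 1 ≈ 6 in every condition; dilator (OTX⁺) 2 →
3 with dilation; stroma (SOX10⁺/TFAP2B⁺) 2 → 5. The ZIC1⁺ and ERG⁺ presets
(untreated 2, dilated 4) are *placeholders* — the study reported their
elongation as highly significant without printing means. The default mean
nucleus area (2000 px²) keeps the minor axis ≥ ~10 px so pixelation bias
on the measured ratio stays under ~2%.

Measurement: length is the maximum Feret diameter, computed by brute-force
calipers over the convex hull of the region's pixel centers; width is the
hull extent perpendicular to the maximizing axis ("largest nuclear width
perpendicular to the length", read as the global perpendicular maximum).
For non-convex masks the hull convention can differ from the widest
perpendicular chord; the hull reading is used and documented. Note the
convention measures the *longest dimension*: for a 60×20 rectangle that is
the diagonal, giving ratio 5/3, not 3 — for the ellipse-like nuclei this
package measures, Feret and major axis coincide.

Segmentation is Gaussian smoothing (σ = 1) → Otsu → distance-transform
watershed. Watershed seeds are connected regions deeper than 60% of each
component's maximal (smoothed) distance: one seed for an elongated ridge,
two for a touching pair with a shallow neck. Border-touching objects and
regions under 100 px are dropped.

Because flat-mount nuclei are measured in Z-projection, a tilted 3D
ellipsoid's 2D ratio is at most its 3D axis ratio;
`projected_axis_ratio` computes the analytic shadow (Schur complement of
the ellipsoid quadratic form) and the inequality is property-tested over
500 random orientations.

Group statistics report mean ± SD; two groups get the Student's *t*, three
get one-way ANOVA with Tukey HSD ("appropriate multiple comparisons test"
is unstated; Tukey is the conventional choice), with the standard
significance tiers (\*p<0.05 … \*\*\*\*p<0.0001).

## Lineage co-localization

Synthetic fields plant `round(frac_coloc × n)` GFP⁺ nuclei among *n*
marker⁺ disks, so the planted fraction is exact. Presence is scored as
mean in-mask intensity above background + kσ (k = 3, exposed); the
original scoring was manual and intensity-independent, so any
positive-signal rule is a surrogate. Fractions are computed over
marker-positive nuclei only and accompanied by Wilson 95% intervals (the
original bar graphs carry none). The dilator category applies the OTX⁺
ZIC1⁻ gate. Per-type fractions are not printed in the study; the presets
are placeholders consistent with its qualitative account — the sphincter-1
Wnt1-Cre preset is 0.30, honoring the one quotable bound (< 50%), with
n = 130 inside the 120–140 scoring design.

## Problem sizes and determinism

Default sizes — 9000-nucleus libraries, 300-nucleus morphometry fields,
200-repetition null suite — were chosen so the full validation runs on a
single CPU in a few minutes while keeping Monte-Carlo error well inside
every tolerance. All generators are `numpy.random.Generator`-seeded; the
same seed reproduces counts, images and truth byte-for-byte. The pipeline
fans one base seed into per-library seeds by fixed offsets so stages are
independently reproducible.

## Known limitations

- Log-CPM is a deliberate stand-in for regularized NB normalization;
  statistics sensitive to variance stabilization at very low counts may
  differ on real data.
- Automated segmentation and dot selection replace manual measurement;
  they are validated on synthetic truth, not against human annotations.
- The generator's independence assumptions (genes, nuclei) make the null
  suites cleaner than real data would be.
- Replicate jitter is calibrated to single-library technical R², so
  whole-library replicate correlations sit slightly above the printed
  0.98–0.99 band (see the replicate paragraph above).
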