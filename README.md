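# iriskit

Quantitative procedures for a single-nucleus RNA-seq (snRNA-seq) atlas of
the mouse iris, re-implemented as a tested, reusable Python library. The
iris changes shape dramatically with pupil dilation (mydriasis) and
constriction (miosis); the underlying study profiled ~34,000 iris and
ciliary-body nuclei across untreated, dilated and constricted eyes,
validated markers by RNAscope in-situ hybridization and immunostaining,
quantified nuclear shape changes, and traced neural-crest lineage
contributions with Cre reporters. `iriskit` packages the numerical core of
that work — plus synthetic-data generators with full ground truth, so every
stage can be validated without any sequencing or imaging data.

## What it computes

**Atlas statistics** (`iriskit.atlas`, `iriskit.compare`)

- Nucleus-level QC: retain nuclei with mitochondrial fraction ≤ 1% and
  total transcripts in [500, 6000].
- Log-normalization (log-CPM, scale 10⁴), pseudobulk averaging per
  (cell type, condition) in the de-log-then-mean convention, dot-plot
  statistics (percent expressing, z-scaled mean), and Leiden clustering
  over principal components.
- Pairwise pseudobulk *R²*: the squared Pearson correlation of
  log₁₀(average normalized expression) across genes between two
  conditions, per cell type; and the dilation-asymmetry summary
  ΔR² = R²(constricted vs untreated) − R²(dilated vs untreated).
- Thresholded differential expression: per-gene Student's *t*,
  Bonferroni correction over **all** genes in the dataset, passing at
  |log₂FC| > 0.6 and adjusted *p* < 0.05.

**RNAscope dot quantification** (`iriskit.ish`)

    avg intensity per dot = (Σ dot intensity − bg × Σ dot area) / n_dots
    dots in ROI           = (ROI intensity − bg × ROI area) / avg intensity per dot

with background estimated from signal-free regions and relative abundances
normalized to a reference probe (*Adra1a*, *Chrm3* or *Syt1*).

**Nuclear morphometry** (`iriskit.morph`) — maximum-intensity Z-projection,
watershed segmentation, and length:width measurement (length = maximum
Feret diameter; width = hull extent perpendicular to it), with mean ± SD
group statistics, Student's *t* / one-way ANOVA + Tukey HSD.

**Lineage co-localization** (`iriskit.lineage`) — a nucleus co-localizes
when both the cell-type marker and the H2B-GFP reporter are present,
regardless of intensity; fractions are reported over marker-positive nuclei
with Wilson 95% intervals, including the OTX⁺ ZIC1⁻ gate for dilator
muscle.

**Synthetic data with ground truth** (`iriskit.synthetic`) — a
negative-binomial count generator (10 populations at iris-like proportions,
~1760 transcripts/nucleus, marker programs, a dilator-concentrated dilation
program, planted QC violators, replicate jitter) and fluorescence-field
generators for nuclei, RNAscope dots and two-channel lineage images. Every
generator returns the planted truth.

## Worked example

```bash
python examples/03_dilation_response.py
```

```
dilator R² dilated vs untreated:     0.905
dilator R² constricted vs untreated: 0.993

ΔR² per cell type (constricted-minus-dilated, positive = dilation-responsive):
             r2_constricted_vs_untreated  r2_dilated_vs_untreated   delta
cell_type
dilator                           0.9932                   0.9053  0.0879
stroma1                           0.9917                   0.9903  0.0013
...
differential genes passing thresholds in dilator: 183
```

Constriction barely perturbs the transcriptome, so the constricted-vs-
untreated comparison (R² ≈ 0.99) measures technical noise; the drop to
R² ≈ 0.91 for dilated-vs-untreated in dilator muscle is the dilation
response, and ΔR² ranks cell types by it. The 183 passing genes recover the
generator's planted 180-gene dilator program (the handful extra reflect
replicate-level jitter between single libraries).

The other examples cover simulation + MTX output (`01`), QC + clustering —
10 communities, adjusted Rand index 1.0 against planted labels (`02`),
RNAscope counting — planted 80 and 40 dots recovered exactly, relative
abundance 2.00 (`04`), morphometry — stromal nuclei 2.01 ± 0.27 untreated
vs 5.00 ± 0.74 dilated, p < 0.0001 (`05`), and lineage scoring — 39/130 =
30.0% GFP⁺ sphincter-1 nuclei (`06`).

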