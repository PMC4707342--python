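# Methods

`myomics` implements the analysis stack used to separate uterine
leiomyosarcoma (LMS, malignant) from leiomyoma (LM, benign) and normal
myometrium (NM) with three array platforms plus a gel-based methylation
assay. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmark does and does not show.

## Chromosomal abnormality burden (`myomics.cnv`)

**Model.** A SNP genotyping array reports, per probe, the log R ratio
(LRR — log2 total intensity relative to a diploid reference, ≈0 at copy
number 2) and the B allele frequency (BAF — the B-allele proportion,
clustering near 0, 0.5 and 1 in a diploid genome). Copy-number events shift
the LRR mean and split the heterozygous BAF band; copy-neutral loss of
heterozygosity (CN-LOH) leaves LRR unchanged but removes heterozygous BAF
values over an extended run.

**Segmentation.** Each chromosome's LRR track is fitted with a
piecewise-constant mean by minimising

    sum of within-segment RSS + penalty × (number of breakpoints)

subject to a minimum of `min_probes` (default 2) probes per segment. The
minimiser is found by exact optimal-partitioning dynamic programming
(O(n²), vectorised over the last-changepoint candidate). We chose the exact
DP over greedy binary segmentation deliberately: it is in the same
piecewise-constant model class as the sparse-Bayesian and HMM-based callers
used on real arrays, but its optimum is reproducible and can be verified
against exhaustive enumeration on short tracks, which the test suite does.
The penalty defaults to 10·σ̂², with σ̂ estimated robustly from median
absolute successive differences (σ̂ = median|Δ|/(√2·Φ⁻¹(¾))), so the
effective sensitivity adapts to track noise.

**State calling.** Segments are labelled gain when mean LRR > `gain_t`
(default +0.10) and loss when below `loss_t` (default −0.15); inequalities
are strict. The thresholds sit well inside the single-copy shifts (≈+0.4 /
−0.55) so that mosaic events, whose shift is attenuated by the clonal
fraction, are still caught; the asymmetry reflects the larger magnitude of
a one-copy loss.

**CN-LOH.** A call is a maximal run of ≥ `min_run` (50) consecutive probes
spanning ≥ `min_span` (3 Mb) in which no probe has BAF inside the
heterozygous band (0.15, 0.85), restricted to copy-neutral segments —
homozygosity inside a gain or loss is explained by the copy-number event
itself. Under Hardy–Weinberg heterozygosity ≈0.5, the chance of 50
consecutive probes being homozygous by drift is ≈2⁻⁵⁰, so false calls are
negligible without any statistical model.

**Burden.** The abnormality ratio of a sample is
(bp in gain ∪ loss)/basis + (bp in CN-LOH)/basis, where the basis is the
first-to-last probe position per autosome, summed over autosomes; sex
chromosomes are excluded. Segments are probe-delimited (interval = first to
last supporting probe, 1-based inclusive; BED export converts to 0-based
half-open). The report is invariant to subdividing a segment.

## Expression markers (`myomics.expression`)

Raw intensities are quantile-normalised (every column is forced onto the
per-rank mean distribution; tied values share the mean of their ranks'
targets, so ties stay tied), then log2-transformed for testing. The
differential funnel is: per-probe one-way ANOVA across the four groups
(NM, LM, LMS, cell lines) with Benjamini–Hochberg correction, selected at
q < 0.05 strictly; a linear fold-change filter keeping probes with FC > 2
or < 0.5 (strict) in LMS-vs-NM or LM-vs-NM, computed on linear-scale group
means of the normalised intensities; removal of probes without a gene
symbol and de-duplication to one probe per symbol (largest |log2 FC|, then
lexicographically smallest probe id). Probes with zero variance within and
between groups receive p = 1 by convention.

Tissue-specific markers use the detection flag and a normalised log2
intensity threshold of 6: a probe is specific to a class C (one or two of
NM/LM/LMS) iff it is present AND > 6 in every sample of C, and absent OR
≤ 6 in every sample outside C. The exact conjunction is this package's
declared interpretation of a flag/intensity filter; cell lines do not
participate in the specificity definition. Per-sample deregulation counts
compare each non-reference sample to the NM group mean; group concordance
is |intersection|/|union| of the member samples' up (down) sets — the
union denominator is a declared choice.

## Differential methylation (`myomics.methylation`)

Beta values are β = M/(U + M + 100), in [0, 1); the 100-count offset
stabilises low-intensity probes. QC removes a probe when ANY sample shows
detection P > 0.05 or a blank β — a single genome-wide surviving probe set
shared by all downstream analyses (the alternative, per-analysis filtering,
would make every table's denominator different). Group differences are
Δβ = mean β(A) − mean β(B); probes are hypermethylated when Δβ > 0.2 and
hypomethylated when Δβ < −0.2, strictly.

Each probe carries exactly one gene feature category (TSS1500, TSS200,
5′UTR/first exon, gene body, 3′UTR, intergenic; precedence
TSS200 > TSS1500 > 5′UTR/first exon > body > 3′UTR > intergenic when
annotations overlap) and one CGI relation (island, shore/shelf within 4 kb,
open sea beyond), so category counts partition the probe total and the
per-category tabulation's rows sum to the grand total. Differentially
methylated regions are formed by binning ≥2 same-direction probes sharing
gene and feature group; every member must individually pass the Δβ
threshold, and the region spans the first to the last member probe.

The two-sided marker filter selects probes with β > 0.6 in all samples of
one group and β < 0.1 in all samples of the other (strict); promoter
refinement keeps genes with ≥2 such probes in TSS1500/TSS200 — loci with
near-binary methylation differences assayable by a single bisulfite-PCR
amplicon. Gene-set overlap reports |∩| and the fraction of the reference
set (e.g. polycomb-target genes hypermethylated in the tumour).

## COBRA quantification (`myomics.cobra_assay`)

After bisulfite PCR of LINE1 repeats and HinfI digestion, the methylated
template yields a 246-bp cut band and the unmethylated template the 413-bp
uncut amplicon. Intensities are converted to molar amounts by dividing by
fragment length, and the raw methylation index is the cut molar fraction
×100 — invariant to overall signal scale. A standard curve (ordinary least
squares, raw% = slope·true% + intercept) fitted to fully-methylated /
fully-unmethylated control mixes is inverted to correct each sample,
clamping to [0, 100]. A linear curve is the simplest monotone model
adequate for a two-template competitive assay; a nonlinear interpolation
would need more control points than a typical ladder provides.

## Synthetic data (`myomics.simulate`)

The generators produce probe-level tables in exactly the formats the real
readers consume, with all planted signal returned in a truth table.

- **SNP array**: genotypes Hardy–Weinberg at allele frequency 0.5; LRR
  noise additive Gaussian, default σ = 0.15 (typical of genotyping-array
  tracks); BAF noise σ defaults to a quarter of that, clipped to [0, 1].
  A gain/loss at clonal fraction f shifts LRR by +0.40·f / −0.55·f and
  splits heterozygous BAF by δ(f) = f/(4 − 2f) (exact for a one-copy loss,
  a close approximation for a one-copy gain). CN-LOH re-draws a fraction f
  of heterozygous probes near {0, 1} and leaves LRR unchanged; a
  consequence of this model is that partial-clonality CN-LOH leaves
  residual heterozygous probes and is intentionally invisible to the
  run-based detector — mirroring how mosaic CN-LOH defeats
  homozygosity-run callers on real arrays. Default genome: four 50-Mb
  autosomes at 20-kb probe spacing (10,000 probes), a deliberate
  scale-down that preserves per-chromosome probe counts typical of small
  chromosomes.
- **Expression**: null probes share a group-independent log-normal
  distribution (log2 mean 8, spread 1.5, per-sample noise 0.25); planted
  effects multiply the listed groups by a linear fold change; "specific"
  effects silence the probe to background outside its groups. A probe is
  flagged present iff its log2 intensity exceeds the background level (5).
- **Methylation**: baseline β is bimodal as on real arrays (islands
  ~Beta(2,18), elsewhere ~Beta(15,5)); per-sample noise is Gaussian on
  logit(β) (default σ = 0.25), which keeps β in (0,1) and shrinks variance
  near the rails. Planted effects move a probe set from a clean anchor
  (0.08 for hyper, 0.85 for hypo plants, configurable) by Δβ in one group;
  M/U intensities are then realised at total intensity 10,000 so that
  M/(U+M+100) reproduces the noisy β. 0.5% of cells draw detection
  P > 0.05.
- **COBRA**: the raw index follows a configurable linear distortion of the
  true methylated fraction plus Gaussian noise in percentage points; band
  intensities realise that index with the 246/413 length weighting, and a
  0–100% control ladder passes through the same process.

Seeding: every generator takes one integer seed; the pipeline derives
per-generator child streams from its top-level seed via `SeedSequence`.
Identical seeds give byte-identical outputs.

**What the synthetic benchmark does not show.** The generators emulate
probe-level summaries, not scanner physics: no dye bias, no batch or
position effects, no probe cross-reactivity, no correlated noise along the
genome, no copy-number interaction with β values, and gene/CGI annotations
are laid out on a simplified genome. Passing the planted-truth tests
demonstrates that the algorithms recover what their models define, not that
those models capture every artefact of real arrays.

## Default study conditions

The bundled synthetic study mirrors the biology of the tissue comparison:
3 samples per tissue group plus 3 cell lines; LMS genomes 67–81% aberrant
(large gains, a mosaic loss at f = 0.8, full-clonality CN-LOH) against LM
genomes at 1–5%; LMS methylomes globally hypomethylated with the CGI
gradient (≈30% of open-sea probes and ≈11% of shore/shelf probes planted
at Δβ = −0.4, islands spared) plus promoter-island hypermethylation;
sarcoma-specific overexpressed genes present/absent-separable; LINE1
methylated fraction 0.75 in NM/LM vs 0.45 in LMS measured through a 0.9
slope / +8 intercept assay distortion.

## Problem sizes and tolerances

Unit and acceptance tests run on scaled-down instances chosen as the
package's own benchmark sizes: 10,000-probe SNP tracks, expression matrices
of 300–2,000 probes, methylation manifests of 600–3,600 probes, 20 random
seeds for recovery statistics. Hand-computed formula examples are asserted
to 1e-9; oracle equivalences (segmentation vs exhaustive search, ANOVA vs
the direct F formula) to 1e-9 relative; planted-burden recovery to ±0.02;
planted Δβ recovery at ≥95% sensitivity with ≤1% false calls among
unplanted probes. Sensitivity is measured among QC-surviving probes: with
12 samples, a 0.5% per-cell detection-failure rate removes ≈5.8% of probes
outright, and that loss belongs to the QC model, not to the classifier
under test.

## Known limitations

- The segmentation penalty is a single global constant per chromosome; very
  short high-amplitude events below `min_probes` are invisible by design.
- No mosaic-fraction point estimation is attempted beyond the optional
  heuristic field on segment calls.
- The tissue-specificity marker filter is an exact conjunction; real
  datasets with borderline flags may warrant an "n-of-m samples"
  relaxation, which the thresholds expose but the defaults do not use.
- Region binning treats each (gene, feature) pair independently; a probe
  annotated to several genes would be counted once per assignment if the
  manifest carried multi-gene rows (the bundled manifests do not).
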