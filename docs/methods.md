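# Methods

## Scope and model overview

`leukotype` operates downstream of read-level processing: it consumes the
tables that alignment, fusion calling, variant calling, expression-based
subtype prediction and expression-dosage CNV inference produce, and fuses
them into a molecular subtype assignment. Nothing here touches FASTQ or
BAM; the dosage and MAF tables stand in for an expression-CNV caller's
output, the fusion tables for two RNA-seq fusion callers, the prediction
record for an expression classifier.

## Virtual karyotype features

Each sample becomes a fixed, ordered vector of 186 real features.

Per chromosome c ∈ {1..22, X} (7 features × 23 = 161):

| feature | definition |
| --- | --- |
| `log2fc_wmedian` | expression-weighted median of per-gene log₂(dosage/2) |
| `log2fc_p05`, `log2fc_p95` | weighted 5th/95th percentiles (range boundaries) |
| `maf_peak_primary` | argmax of the folded-MAF kernel density |
| `maf_peak_secondary` | next-highest local maximum ≥ 0.08 away (= primary if unimodal) |
| `maf_density_at_half` | density at 0.5 (balanced-heterozygosity mass) |
| `het_fraction` | share of SNVs with folded MAF ∈ [0.4, 0.5] |

Plus 24 equal-width positional bins (mean log₂FC) across the iAMP21
diagnostic region chr21:25,772,460–39,428,528 (1-based inclusive), and one
genome-wide weighted median. The manifest (names and order) is frozen in
`features.FEATURE_NAMES` and hashed into every trained model; prediction
refuses mismatched inputs.

Weighted order statistics use the cumulative-weight definition (smallest
value whose cumulative weight reaches q of the total); a brute-force scan
oracle checks this on random inputs in the test suite. Chromosome Y is
excluded throughout: expression-based copy-number inference on Y is
unreliable and sex effects are out of scope.

**Folded MAF and its density.** The minor-allele fraction is folded to
min(f, 1 − f) ∈ [0, 0.5]: balanced disomy peaks at 0.5, trisomy at 1/3,
loss of heterozygosity (LOH) near 0. The density is a Gaussian KDE with a
*fixed* bandwidth of 0.03 evaluated on a 256-point grid over [0, 0.5],
with mass reflected at both boundaries so the 0 (LOH) and 0.5 (disomy)
modes are not depressed. Fixed bandwidth is deliberate: peak positions are
the feature, and a data-adaptive bandwidth would make the same biological
state yield different peaks at different SNV counts. The peak finder is
cross-checked against exhaustive grid argmax in tests.

**Imputation.** Chromosomes with < 5 genes or < 5 SNVs receive
diploid-neutral values (median and boundaries 0; peaks 0.5; density at 0.5
equal to that of a point mass at 0.5; het fraction 1), with a logged
warning. This biases sparse samples toward the majority non-aneuploid
class, which is the conservative direction for a screening tool. Empty
chr21 bins are imputed with the chromosome-21 weighted median so a
uniformly gained chr21 does not fake a focal amplification.

## Karyotype classifier

Five classes: near-haploid, low-hypodiploid, high-hyperdiploid,
iAMP21/chr21-amplification, other. Rare isolated chr21 amplifications in
otherwise diploid genomes are indistinguishable from iAMP21 in dosage
space, hence the combined class.

Training: (1) SMOTE balances every class up to the majority count —
synthetic minority points xᵢ + u(xⱼ − xᵢ), u ~ U(0,1), xⱼ one of the
k = min(5, class size − 1) nearest same-class neighbours; singleton
classes are duplicated. (2) Per-feature z-score standardization is fit on
the balanced matrix. (3) Three base learners are fit: random forest (200
trees), k-nearest-neighbours (k = 5, distance-weighted; k is clamped to
the training size on tiny folds), gradient-boosted trees (150 rounds,
depth 4, learning rate 0.1). Prediction averages the three class-probability
vectors with equal weights (each base vector renormalized in float64 to
absorb float32 rounding); the label is the argmax with alphabetical
tie-break. A randomized hyperparameter search (trees 100–500, depth 3–12,
k ∈ {3,5,7,9}, learning rate log-uniform 0.01–0.3; 5-fold stratified CV
maximizing weighted F1, balancing and scaling refit per fold) is available
but the defaults are used for the reported evaluation.

Evaluation is leave-one-out: for each held-out sample, balancing and
standardization are refit on the remaining n − 1 only, so the held-out
label cannot shape its own prediction (a corruption test asserts this).
Pooled predictions give accuracy, class-frequency-weighted F1, one-vs-rest
sensitivity/specificity per class (undefined metrics are NaN, never 0),
and a Wilson 95% interval on accuracy.

## Rule engine

The bundled rule set covers 26 ICC entities, 10 of which map to distinct
WHO-HAEM5 classes (near-haploid and low-hypodiploid share the WHO
hypodiploidy class; IGH::IL3 is not represented). Four driver-cryptic
subtypes carry an expression-only allowance: DUX4, CEBP (IGH-partner
fusions that RNA-seq callers miss), `BCR::ABL1`-like NOS and PAX5alt.

Decision procedure, strictly in order: (1) enumerate distinct subtype
definitions supported by driver evidence — a catalog-matched fusion, a
defining hotspot SNV, or a non-"other" karyotype call; (2) exactly one
supported definition with a concordant expression label (any confidence
tier) → automatic; (3) zero drivers, high-confidence expression of an
allowance subtype → automatic, GEP-only; (4) two or more supported
definitions → *additional driver*, even if one is concordant; (5) one
supported definition, non-concordant expression → *discordant driver*;
(6) zero drivers with an expression label that does not qualify under (3)
→ *missed driver*; (7) otherwise *unclassified*. Steps 4/5 outrank 3:
driver evidence always overrides the expression-only allowance, which
resolves the precedence question when a high-confidence allowance label
co-occurs with a foreign driver (the spirit of "absence of any other
subtype-defining driver"). Unclassified-tier predictions with empty labels
cannot establish concordance and flag as discordant when a driver is
present. Cooperating hotspot SNVs (NRAS/KRAS/FLT3 and friends) are
reported but never drive classification.

Karyotype concordance encodes the shared signatures: near-haploid and
high-hyperdiploid calls each accept either aneuploid expression label
(the karyotype decides the final subtype — this is how a doubled
near-haploid mislabeled as hyperdiploid by expression gets corrected);
iAMP21 additionally accepts the `BCR::ABL1`-like label.

An exhaustive truth-table test (driver count × expression concordance ×
tier × allowance) checks the implementation against an independently
written restatement of the procedure.

## Driver catalogs

Fusion harmonization uppercases and strips gene symbols and merges calls
orientation-insensitively (RNA-seq callers disagree on partner order for
reciprocal events); per caller, supporting reads of repeated rows are
summed and the maximum across callers is retained. Catalog entries may
opt into orientation-specific matching. Hotspot filtering retains a
pileup row iff its position and alt allele are in the catalog and depth ≥
10, alt reads ≥ 3 and VAF ≥ 0.05 — invented but conventional cut-offs,
all exposed as parameters and on the CLI.

The bundled catalogs are *synthetic curations* assembled from public
B-ALL literature (165 fusion entries across the rule set's subtypes; 46
hotspot positions in ZEB2, KRAS, NRAS, FLT3, CRLF2, IDH1, IDH2, JAK1,
JAK2, TP53, PAX5, IKZF1, with PAX5 P80R, IKZF1 N159Y and ZEB2 H1038R as
subtype-defining). Genomic positions are approximate; they serve as a
self-consistent reference resolved identically by the simulator and the
filter. Both files carry a source tag and are replaceable via
configuration.

## Double-driver proximity

PCA (2 components, centred, unscaled) is fit on the log1p submatrix of
the top 600 variable genes — variance taken on the log scale, ties broken
by gene identifier — over the query plus all members of the two candidate
subtypes. Centroids are the mean (PC1, PC2) of each subtype's members
*excluding the query*, avoiding self-attraction bias (an invariance test
asserts that annotating the query into its own subtype changes nothing).
The dominant subtype is the nearer centroid by Euclidean distance;
distance ties at machine precision are reported as "indeterminate", never
silently broken. Clustering uses the Ward criterion on raw Euclidean
observations (the Ward.D2 convention, monotone merge heights), with
optional Newick export.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes, with one
`numpy` Generator seeded from the cohort seed driving everything (same
seed ⇒ byte-identical output files).

Karyotype classes: near-haploid draws a modal count uniform on 23–29,
retaining chromosomes 21 and X preferentially disomic, and with
probability 0.5 undergoes whole-genome doubling ("masked": monosomies
become copy-number 2 with LOH; the modal count is recorded pre-doubling) —
the doubling rate is a free choice, as the real prevalence of masked
hypodiploidy in RNA-seq series is not well pinned down, and it is
configurable. Low-hypodiploid draws 33–39 with losses biased away from
21/X; high-hyperdiploid draws 52–67 with gains favouring chromosomes
4, 6, 10, 14, 17, 18, 21, X (weight 5:1, copy number capped at 4);
iAMP21 is near-diploid with the diagnostic region at copy number 5–8;
"other" is exactly diploid.

Dosage: gene counts proportional to GRCh38 chromosome lengths
(largest-remainder allocation; default 15,000 genes), positions uniform,
log₂FC ~ Normal(log₂(effective cn / 2), σ) with σ = 0.25 — chosen so that
per-chromosome medians are well resolved at realistic gene counts while
individual genes remain noisy, the regime expression-dosage CNV callers
operate in. Masked chromosomes emit effective copy number 2; zero-copy
chromosomes emit a floor ratio of 0.1/2 rather than −∞. iAMP21 samples
top the region up to ≥ 200 genes. Weights are log1p of a log-normal
expression level. MAF: per chromosome 30 SNVs (default) at Poisson(80)
depth; heterozygous sites on copy number c carry k/c allele copies
(k uniform on 1..c−1) sampled binomially; LOH chromosomes emit only a
0.5% error rate. Evidence: the subtype's defining fusion is emitted in
both caller dialects (IG-partner fusions are RNA-invisible and emit
nothing, motivating the allowance rules), defining SNVs as pileup rows at
VAF 0.35–0.5 and depth 60–120, comfortably above the filter defaults.

Cohort-level defaults mirror the observed field conditions: double-driver
rate 0.026, evidence completeness 0.8 (each sample is fully concordant
with probability 0.8, otherwise degraded into a missed / discordant /
unclassified scenario), which lands the automatic-classification fraction
in the observed 74–85% band. The default subtype mix is uniform over the
subtypes that can be automatically classified (driver-generable or
allowance); class frequencies are otherwise the caller's choice via
`CohortSpec`.

What the generator does **not** model: raw reads, realistic gene-level
expression programs (dosage is noise around the copy-number mean, so the
expression-proximity module is exercised on separately constructed
matrices), subclonality, contamination, low blast fractions, sex
chromosomes beyond a disomic X. Passing tests therefore demonstrate the
pipeline's logic and the separability structure of the feature space, not
performance on clinical data.

## Reported evaluation

The default evaluation cohort is 30 samples per class (150 total), cohort
seed 42, generator defaults. Leave-one-out evaluation of the ensemble on
this cohort yields accuracy and weighted F1 of ≈ 0.98 (recomputed, not
stored, by `scripts/acceptance.py` and the acceptance tests). Problem
sizes elsewhere (36-sample ablation cohort, 1210-sample double-driver
sanity cohort with 30-gene tables, 400–500-sample rule-engine cohorts)
were chosen to give stable statistics at desk scale.

## Known limitations

- The 186-feature decomposition (23×7 + 24 + 1) is this package's
  canonical scheme; other groupings of the same chromosome-level metrics
  are possible and would need retraining.
- The bundled catalogs are literature-derived stand-ins, not a validated
  diagnostic reference; positions are approximate.
- The classifier is trained per cohort; no pretrained weights ship with
  the package.
- Blast fraction is reported but not used as a gate for expression-only
  calls; low-blast behaviour is untested by construction.
- Masked low-hypodiploidy (doubling of 33–39-chromosome genomes) is not
  simulated; only near-haploid doubling is.
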