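# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
design decisions taken where the underlying procedure is genuinely open.

## Reference genome and gene model

The package embeds the 16,569-bp revised Cambridge Reference Sequence
(rCRS, NC_012920.1) as FASTA package data, with the standard 37-gene
annotation (13 protein, 22 tRNA, 2 rRNA genes) plus a control-region record
spanning 16024–16569 ∪ 1–576. Coordinates are 1-based inclusive throughout,
the MitoMap convention; BED export converts to 0-based half-open.

Provenance of the embedded sequence: it was reconstructed offline from the
16,571-bp hg19 mitochondrial sequence (NC_001807.4) by applying the
documented set of divergences between that assembly and the rCRS
(32 substitutions; removal of the 309.1C, 315.1C and 16193.1C insertions;
restoration of 16183A and 16189T; insertion of the historical placeholder
N at position 3107). The reconstruction was validated structurally rather
than by byte-comparison with an official copy: all 13 protein-coding genes
translate under the vertebrate mitochondrial code without internal stops
and with canonical N-termini; the three worked amino-acid substitutions
(F411S, T387A, S28P), a panel of ~95 positions whose rCRS reference alleles
are fixed by standard variant nomenclature (e.g. 3243A, 8344A, 1555A,
11778G, 8993T, 14484T), the historical CRS-correction sites (3423T, 4985A,
9559C, 11335C, 13702C, 14199T, 14272C, 14365C, 14368C), seven published
mtDNA primer/probe sequences, and the forensic HVS poly-C tract structures
all match. Residual disagreement with the canonical reference, if any, is
estimated at no more than a few bases (the base composition differs from
the published rCRS counts by ±1 per nucleotide class) and is confined to
positions not covered by any of the above constraints. For variant
annotation this is immaterial unless a query variant falls exactly on such
a position, in which case the reference-allele check would reject it
visibly rather than misannotate silently.

### Annotation conventions

* Codon index = ceil(offset/3) with offset measured on the coding strand;
  light-strand genes (MT-ND6 and nine tRNAs) complement the alleles first.
* Incomplete stop codons are completed with A (polyadenylation) before
  translating the terminal codon.
* A variant overlapping two protein genes (MT-ATP8/6, MT-ND4L/4 overlaps)
  yields one consequence per gene.
* Position 3107 (placeholder N) rejects any variant as a reference
  mismatch; indels raise a typed error rather than being dropped.
* rRNA and tRNA variants count as "coding" (non-control) in the
  coding-vs-control dichotomy, with their sub-class exposed.
* Translation table 2 is implemented as an explicit codon table; agreement
  with Biopython's table 2 is asserted codon-by-codon in the tests.

## Respirometry

State fluxes are read from titration traces as the **median** volume-specific
flux over a trailing window (default 60 s) before the next titration event,
divided by wet mass (chamber volume, default 2 mL, is a config key). The
instrument software's manual mark placement is not reproducible, so the
median-window rule is a documented, configurable stand-in; the median
resists titration spikes. The window CV per state is reported for QC.

ROX correction subtracts the post-antimycin residual flux from every
metabolic state; corrected values below zero are kept and flagged, since
clamping would bias the effect deltas. Flux control ratios divide by NS_E
(so FCR(NS_E) ≡ 1 and FCRs are invariant to overall scale, which the tests
assert as an algebraic identity). Effects are the state differences listed
in the module docstring; protocols without the oxidative-stress step map
their single GM-OXPHOS state to both GM_P_pre and GM_P, making the stress
delta zero rather than undefined.

The rotenone-titration compensation curve for cell lines reports percent
N-pathway inhibition (decline of rotenone-sensitive flux vs the dose-0
baseline) against S-pathway OXPHOS capacity relative to NS_E of the same
run.

## Heteroplasmy processing

Detection thresholds: variant level > 2% (mean VAF of two independent runs;
single-run variants are dropped and counted), per-strand coverage > 10 for
acceptance (a separate, lower detection coverage of 5 is a config key),
and forward/reverse VAF agreement. The strand-bias rule is not numerically
standardized anywhere, so the default is |VAF_fwd − VAF_rev| ≤ max(0.1,
3·binomial SD at the observed depth), configurable and disableable; every
rejection is logged with its reason. Records at level ≥ 0.95 are kept but
labelled homoplasmic and excluded from heteroplasmy counts.

AF strata are left-closed/right-open except the last ([thr,10), [10,20),
[20,50), [50,100]); a level of exactly 10% falls in 10–20%. The Complex I
level stratum per sample (none / 30–60% / >60%) derives from the maximum
non-synonymous CI-gene level. "Potentially deleterious" = non-synonymous
in MT-ND1–6/4L, MT-CO1–3 or MT-CYB; ATP-synthase genes are excluded by
definition.

The MT-ND gene-size correlation uses gene length in kbp against per-gene
heteroplasmy counts in malignant samples, Pearson r with the two-tailed
t-test on n−2 df. Uniform-per-base mutation placement (no hotspots) is
exactly what the synthetic generator plants, so a strong positive r on
synthetic cohorts is a structural check of the computation.

## Copy number

CN = 2·E^(−ΔΔCq) with the plasmid calibrator defining ΔCq = 0 at CN = 2.
E defaults to 2.0 (perfect doubling): the assay ships a plasmid standard
but no measured per-assay efficiency, so per-assay E is a config key. With
Cq noise of σ = 0.1 cycles on each of two channels the per-sample error is
~2^(0.14σ√2) ≈ 10% (1 SD); the estimator is unbiased on the log scale, so
cohort-level recovery (median within 5%) is the tested guarantee.

## Statistics

* Paired comparisons: Shapiro–Wilk on the pairwise differences selects
  paired t (p > 0.05) or Wilcoxon signed-rank; two-sided p throughout.
* Holm and Benjamini–Hochberg corrections are implemented directly and
  tested against definitional oracles and statsmodels on random vectors.
* Fisher's exact test uses the point-probability two-sided rule (sum of
  hypergeometric probabilities ≤ that of the observed table), verified by
  enumeration for all small tables; both the sample odds ratio and the
  conditional-MLE odds ratio are reported, since the two differ and
  published tables do not always state which was used.
* The logistic model of heteroplasmy presence enters tumor stage as an
  ordered integer (pT2=2..pT4=4) and reports per-predictor likelihood-ratio
  p-values from nested-model deviance differences; perfect separation
  triggers a penalized fallback and a flag.
* Capacity-by-category comparisons use one-way ANOVA + Tukey HSD for ≥3
  groups and the Wilcoxon rank-sum for 2 groups; undersized groups are
  dropped with a warning.
* The significance threshold is p ≤ 0.05 and is surfaced in config.

## Signature and survival

The severe phenotype is relative GM capacity ≤ 0.27 (the cohort mean of
malignant samples; configurable). Metagene extraction computes the Pearson
(point-biserial) correlation of log2 expression with the severe indicator —
correlating against the continuous GM fraction is available as an option,
since "correlation with the phenotype" is ambiguous — and keeps genes with
r > 0.4 and BH-adjusted p < 0.05 among the supplied candidate genes. The
candidate list is an input (genes overexpressed in the severe group, e.g.
from an external differential-expression analysis); feeding the whole
transcriptome instead makes the BH step much more conservative and
correspondingly lowers recovery.

The metagene score is the mean of gene-wise z-scores of log2 expression
within the scored cohort: no score formula is standard, so the simplest
scale- and order-invariant choice is the default, with a first-principal-
component alternative provided (sign-aligned to the mean-z score). At
least half the signature genes must be present in the cohort matrix.

The optimal cut-point scans all observed score values inside the central
80% quantile band, computes the two-group log-rank p per candidate, applies
a Benjamini–Hochberg correction across the candidate set (the
Lausen–Schumacher maximally-selected-rank correction would be an
alternative; neither is canonical for this construction), and picks the
minimal corrected p with Harrell's C distance from 0.5 as tie-break —
minimizing p first and using C as tie-break is one of two defensible
orderings and both are exposed. Candidates leaving a group with no events
are skipped with the next-best chosen. A full audit table of all candidates
is returned. Null simulations (score independent of survival) keep the
fraction of corrected minimal p < 0.05 at ≈7% or less, which the tests
assert over 500 replicates.

Kaplan–Meier curves come from lifelines; the hazard ratio from a Cox fit
on the group indicator (stratified when strata are given, e.g. cohort id
in multi-cohort settings); the log-rank test is implemented directly (and
checked against lifelines) so that the cut-point scan stays fast.
Harrell's C is the all-pairs definition: usable pairs are those where the
shorter time is an event; score ties count ½. Cox covariate models report
uni- and multivariate HRs with 95% CIs; constant covariates are dropped,
monotone-likelihood failures flagged.

## Synthetic data: what it emulates, and what not

All generators are seeded (`numpy.random.default_rng`) and return a truth
record alongside the data; fixed seed ⇒ identical output.

* **Respirometry**: paired tables whose state means reproduce the
  cohort-level effect structure — ADP effect 4.5 (benign) vs 2.4 (tumor)
  pmol·s⁻¹·mg⁻¹, stress drop 1.1 vs 1.7, larger pyruvate/succinate gains
  and smaller rotenone-sensitive share in tumors, tumor GM_P/NS_E centered
  near 0.27, amplified shifts in the high-grade stratum (default 20% of
  pairs). Subject-level variation is a shared multiplicative factor
  (mitochondrial density) plus additive per-state noise (SD 1.0). At n = 50
  pairs the paired GM_P comparison reaches Holm-corrected p < 0.01 in ≥95%
  of replicates, which is asserted as the power property.
* **Heteroplasmy**: Poisson per-sample counts calibrated to 33 private-
  benign, 84 private-cancer and ~15 shared variant sites per 50 pairs;
  positions uniform over non-control bases (so the gene-size correlation
  emerges); allele frequencies Beta(0.3, 2) truncated at the 2% threshold
  (a preponderance of low-level variants with a minority above 50%);
  dual-run VAF jitter SD 0.01; per-strand depths Poisson(5000) with
  binomial alt reads. The three worked variants can be spiked in.
* **qPCR**: true CN log-normal (median 310, ~0.35 log-SD, matching the
  cohort's median and range); Cq noise SD 0.1 cycles.
* **Expression/survival**: the severe phenotype is assigned by ranking a
  latent respiratory capacity and splitting at the configured fraction
  (exactly balanced at 0.5, mirroring a median dichotomization); planted
  genes are shifted by 2.0 log2 units against noise SD 1.0, i.e. a true
  point-biserial r ≈ 0.7; survival is exponential with the severe group's
  hazard scaled by 1/HR (default HR 0.5 in favour of the mild group) and
  independent uniform censoring. Weibull survival is a documented option.

Not emulated: instrument drift and reoxygenation events in traces;
alignment and base-quality error structure of sequencing (calls are
generated at the variant level); PCR efficiency drift; batch and platform
effects in expression; informative censoring. Passing tests therefore
demonstrate the computational pipeline's correctness and statistical
behaviour under the assumed data structure, not robustness to raw-data
artifacts upstream of the package's inputs.

## Problem sizes in the test suite

The suite runs the power/error-control properties at the sizes stated in
their docstrings — 200 replicates of 50 pairs for the respirometry power
property, 500 replicates (n = 40) for cut-point null error control,
100 replicates (n = 500) for hazard-ratio recovery, 50 replicates for
metagene recovery, and 25 end-to-end discovery→validation replicates with
a 500-subject validation cohort — chosen so the whole suite stays in the
minutes range on a single core while keeping Monte-Carlo error well below
the asserted margins.

## Known limitations

* The embedded reference's residual uncertainty is discussed above.
* The respirometry plateau rule is a stand-in for manual mark placement.
* The strand-bias filter and the cut-point multiplicity correction are
  explicit choices among non-standardized alternatives; both are exposed
  in config and results are audited (rejection log, candidate table).
* MutPred pathogenicity scores are consumed as input columns, never
  computed.
* No haplogroup logic, contamination checks or read-level processing.
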