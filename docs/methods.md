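# Methods

This note documents the statistical models, the synthetic-data
generator, and the numerical and design choices behind `linkld`.

## Study designs being modelled

Two populations drive the analysis. The linkage population is a large
outbred full-sib family (nominally 1,200 progeny) genotyped on a
19-linkage-group map of ~1,270 dominant-marker loci (mean interval
2.3 cM) and phenotyped for stem height (H, cm), basal diameter (BD,
mm) and volume (V) at 12 within-season timepoints. The association
panel is 435 unrelated trees from three climatic subpopulations —
southern (S, 180), north-western (NW, 95) and north-eastern (NE, 160) —
resequenced across the SHRs and phenotyped for the same traits at nine
timepoints (five within the first season, then four annual), giving
3 × 9 = 27 phenotype sets.

## Full-sib QTL mapping

**Coding.** The map is dominated by markers heterozygous in one parent
and null in the other, which segregate 1:1; the package therefore uses
a two-class pseudo-testcross coding {0, 1} throughout and does not
attempt four-allele outbred phase inference. This preserves the
backcross-like statistical structure the scan needs.

**Scan.** At each grid position (1-cM lattice plus the marker
positions), the expected QTL genotype score is computed from the
nearest flanking marker calls via Haldane recombination fractions
(`r = (1 − e^(−2d/100))/2`, no interference; the map function is a
package choice, the source toolchain does not state one). Haley–Knott
regression of the phenotype on that score gives
`LOD = (n/2)·log10(RSS0/RSS1)` and `PVE = 1 − 10^(−2·LOD/n)`. A
missing flanking call contributes an uninformative prior (0.5) on that
side rather than being chained through farther markers — adequate at
the low missingness rates simulated, and the positions coincide with
markers so a marker-exact call always dominates. Haley–Knott was chosen
over full EM interval mapping: for a two-class cross the LOD surfaces
are near-identical at far lower cost, and the regression form
vectorises over grid positions and permutations.

**Thresholds.** Genome-wide significance is the (1 − α) quantile of the
maximum LOD over seeded phenotype permutations (default 1,000, α =
0.05). A uniform reporting cut-off of LOD ≥ 3.0 is applied by default,
matching the average permutation threshold at the study scale;
both are configurable.

**Peaks and intervals.** Support intervals are the maximal run around a
peak with LOD ≥ peak − 1, clipped at LG ends. Two local maxima count as
distinct QTL only when the profile between them dips at least 1 LOD
below the smaller — shoulders of a single peak are not reported twice.

**Cofactor (MQM-style) rescan.** Iteratively: scan, take the marker
nearest each peak as a candidate cofactor, keep candidates with
partial-regression P < 0.02 in the joint marker model, rescan with the
kept set (cofactors within 10 cM of the test position are excluded;
the window width is a package choice), until the set stabilises (≤ 10
iterations, flagged otherwise). Reported PVE is the partial R² under
the cofactor model; the marginal (no-cofactor) PVE is reported
alongside, since the source tool's convention is ambiguous.

**Co-localisation and hotspots.** QTL across trait × timepoint sets are
single-linkage clustered when support intervals overlap *and* peaks are
< 1.0 cM apart. The hotspot test bins peaks per 1-cM interval and
redistributes all peaks uniformly over the map 1,000 times; the
threshold is the 95th percentile of the null genome-wide maximum
per-bin count (FWER-controlling; a pooled per-bin null is available
behind a flag, the max-count null being the conservative reading of an
ambiguous prescription).

## SHR projection

Anchor markers with both a map (cM) and a genomic (bp) position define
a piecewise-linear cM↔bp map per LG, requiring ≥ 3 anchors; a global
linear fit is deliberately avoided because recombination rate varies
along chromosomes. Non-co-monotone anchors flag the region as
inverted/rearranged and projection is refused rather than resolved.
Queries beyond the terminal anchors extrapolate with the nearest
segment's slope and are flagged. Projected regions whose genomic
intervals overlap by ≥ 1 bp merge into a single SHR — the rule that
lets k projected regions yield fewer SHRs.

## Windowed population statistics

All statistics run in fixed, non-overlapping 250-bp windows (the
selection scan extends the SHR domain by 10 kb each side). Haplotype
counts are 2 × the non-missing diploids per site — alleles are treated
as independent draws (no phasing); missing genotypes are never imputed
here (complete-case per site).

* per-site π = 2c(n−c)/(n(n−1)) with c the alternate count; window π
  is the per-site sum divided by the window length in bp (monomorphic
  positions count in the denominator — windows are fixed genomic spans);
* θ_w = (S/a₁)/length with a₁ = Σ_{i<n} 1/i, using the median
  haplotype count over the window's usable sites when missingness makes
  n vary;
* Tajima's D = (π_total − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants; D is undefined (NaN), not zero, when S = 0;
* Fst uses the Weir–Cockerham (1984) variance components a, b, c per
  site, windowed as Σa/Σ(a+b+c) (ratio of sums, the convention of the
  standard VCF toolchain). Negative estimates are reported raw with a
  flag so empirical quantiles stay honest;
* ROD = 1 − π_obj/π_ref, undefined when π_ref = 0.

**Joint selection criterion.** A window is a candidate when it is in
the top q (default 1%) of the Fst distribution *and* the top q of
diversity reduction, measured as log(π_obj/π_ref) — a window with
π_obj = 0 counts as maximal reduction (the log-ratio is kept at a
finite sentinel for quantile purposes), while π_ref = 0 leaves the
window undefined. Adjacent flagged windows (gap ≤ 1 window) merge into
regions; each region is confirmed by a one-sided Mann–Whitney test for
lower window-level D in the objective subpopulation (P < 0.05 and a
lower mean; < 3 defined windows per side → "not evaluable"). Quantiles
are computed per subpopulation pair.

**Fixation classes.** Per SNP and subpopulation: completely fixed
(MAF = 0 in ≥ 1 subpopulation), nearly fixed (0 < MAF < 0.05 in ≥ 1),
else segregating; all-missing subpopulations are excluded and flagged.

## Functional annotation

SNPs are classified per overlapping gene model as nonsynonymous /
synonymous (standard genetic code, strand- and frame-aware on the
spliced CDS), genic_noncoding (intron, UTR, or flank within 2 kb) or
intergenic, with ncRNA overlap flagged independently. With several
overlapping transcripts the most severe class wins (nonsynonymous >
synonymous > genic_noncoding); the precedence is this package's
documented choice. Per-class diversity is the mean per-variant-site π
of the class's sites; the reported nonsyn/syn ratio is a diversity
ratio (π_N/π_S-style), not a codon-model ω.

## Linkage disequilibrium

r² is the squared Pearson correlation of diploid dosage vectors
(composite LD) — phase-free, and monotone with haplotype r² under HWE.
Observed values use complete-case individuals per pair (≥ 10 required,
configurable); permutation P-values use shared individual-label
permutations on mean-imputed dosages with the plus-one correction, so
P ≤ 10⁻³ requires ≥ 10³ permutations (tests run 10³; full runs 10⁵).
Blocks are maximal runs of consecutive, position-ordered sites whose
every within-run pair satisfies r² ≥ 0.75 and P ≤ 10⁻³ — the stated
criterion applied to runs, not the Gabriel confidence-interval method,
which the source names but does not parameterise. Decay is fitted by
nonlinear least squares to the Hill–Weir (1988) drift expectation with
sample-size correction (n = sampled chromosomes), reporting ρ̂ and the
distance at which the fitted curve crosses r² = 0.2 ("beyond data
range" when it does not within the observed span).

## Mixed-model association

The model is y = Qβ + xb + u + e with u ~ N(0, σ²_g K). K is pairwise
IBS similarity (diagonal 1, bent positive semi-definite by eigenvalue
flooring when needed); Q is subpopulation indicators by default (the
three regions are known) with a PCA alternative. Variance components
are fitted once per phenotype set by REML on the spectral decomposition
of K (the population-parameters-previously-determined compromise; no
compression, i.e. compression level 1); each SNP is then a
generalized-least-squares Wald test, with per-SNP mean imputation of
missing dosages in this module only. Per-SNP PVE is the partial R² on
the whitened scale. Thresholds: suggestive 1/n, significant 0.05/n for
n markers.

Additive/dominance decomposition uses least-squares means of the three
genotype classes under the Q-adjusted linear model:
a = (μ̂_AA − μ̂_aa)/2, d = μ̂_Aa − (μ̂_AA + μ̂_aa)/2, each contrast
tested at P < 0.001 (the source's dominance rule); classes
{additive, dominant, both, none}. When any genotype class has < 3
individuals only the dosage-regression additive test runs, flagged
`restricted`. PVE trajectories over timepoints are classified by the
sign/magnitude of fitted slopes in each half of the series (tolerance
0.02 PVE per normalized time unit, configurable) into increasing /
decreasing / level / increase-then-level.

Association hotspots count, per annotated feature, the distinct
phenotype sets (of 27) with ≥ 1 associated SNP at the chosen threshold;
the permutation null shuffles phenotype-set labels over association
events (a package construction — the source states only α < 0.05), and
a feature must both exceed the 95th-percentile null maximum and reach
the stated count (12 suggestive / 8 significant). Unique signals are
greedy lead-SNP clusters: lowest-P SNP leads (ties: smaller
coordinate), absorbing significant SNPs with r² ≥ 0.2 to the lead;
candidate genes are features within 10 kb of the lead.

## Two-locus epistasis

For a SNP pair, per-locus additive and dominance contrast scores are
built orthogonal to the mean — and to each other — under the *observed*
genotype frequencies (the extended-Kempthorne behaviour, robust to HWE
and linkage-equilibrium departures; classical equal-frequency weighting
is available for oracle checks). The four interaction columns (a×a,
a×d, d×a, d×d) are sequentially orthogonalized against the main-effect
space in the realized data inner product; their sums of squares then
add exactly to the 4-df interaction sum of squares, which yields the
overall F-test (degrees of freedom reduced automatically when cells
are empty; pairs with < 5 of 9 classes populated at ≥ 2 individuals
are skipped). The contribution statistic is reported as
c = SS_int/SS_total ∈ [0, 1]: the source formula divides a sum of
squares by a phenotypic variance, which is dimensionally inconsistent;
SS_int/SS_total is the bounded reading (equal to SS_int/(n·Var_p) up
to n vs n−1). Under unbalanced designs the sequential orthogonalization
order (a×a, a×d, d×a, d×d) determines how shared interaction variance
is attributed to components; the total SS_int, the overall P and c do
not depend on it, and swapping the pair order permutes a×d ↔ d×a as
expected.

## Synthetic data: what it emulates, and what it does not

No generative model for the study's phenotypes or genotypes is
published; every distribution below is this package's choice and is
labelled as such in the truth record.

**Family.** Markers are placed with exponential gaps (mean 2.3 cM,
floor 0.05) on 19 (default) LGs; progeny inheritance is a two-state
Markov chain along each LG with Haldane transition probabilities —
planted QTN loci are simulated jointly in the chain and then dropped
from the marker set. Phenotypes are Σ QTN effects + an AR(1) residual
across timepoints (ρ = 0.6 by default; the longitudinal error model is
a package choice). Additive effects are back-solved from target PVE
trajectories (four shapes: increasing, decreasing, level,
increase-then-level).

**Panel.** Sites sit on SHR-like regions. Ancestral derived-allele
frequencies follow a density ∝ x^(−1.35) on (2.5 × 10⁻⁴, 0.9) by
default: the exponent was calibrated once so that after the
Balding–Nichols drift step (subpopulation frequency ~
Beta(p(1−F)/F, (1−p)(1−F)/F)) the within-subpopulation site frequency
spectra are approximately neutral — window Tajima's D centred near 0
at F = 0.10. (A uniform MAF ~ U(0.05, 0.5) option is retained; it
emulates a post-MAF-filter common-variant panel and is
intermediate-frequency-rich, hence strongly positive D — drift from
any fixed ancestral spectrum skews local spectra, so neutrality of the
generator had to be imposed at the ancestral stage.) Genotypes are
Hardy–Weinberg within subpopulation; an optional founder-haplotype
copying mode and explicit two-haplotype "block segments" provide local
LD for block-detection studies. Selective sweeps fix one favoured
haplotype drawn from the pre-sweep pool: per site the frequency is
compressed toward that haplotype's allele by ρ_sweep, so diversity
collapses by ~ρ_sweep while sites where the favoured haplotype carries
the locally rarer allele become near-fixed differences — the standard
hitchhiking picture. (Simply shrinking minor-allele frequencies would
reduce diversity without creating differentiation, and a sweep would be
invisible to Fst.) Phenotypes for all 27 sets are additive + dominance
+ centred pairwise interaction deviations + a polygenic term with
covariance proportional to the realized kinship (so the mixed model
has a true variance component to recover; default polygenic PVE 0.2)
+ unit Gaussian noise.

**Not emulated:** coalescent genealogies, recombination-driven LD
beyond the copying/block devices, sequence-level mutation processes,
genotyping error structure, shared environment/spatial effects, and
real measurement-scale phenotypes. Passing tests therefore demonstrate
statistical correctness and calibration of the machinery under a known
truth, not performance on real resequencing data.

## Problem sizes and validation experiments

Tests and the acceptance script run desk-scale versions of the study
designs (the full sizes sit behind the same configs): families of
200–400 progeny on 2–3 LGs, panels of 150–300 members in the
three-subpopulation structure, SHR-like regions at about one SNP per
45 bp of common variation (the densest SHR density reported for the
filtered panel). The main seeded experiments:

* neutral-panel calibration (F = 0.10, 2,000 SNPs, 100+100): genome-
  wide ratio-of-sums Fst vs 0.10 and mean window Tajima's D vs 0;
* structured-null mixed-model inflation λ over ~2,000 SNPs;
* epistasis type-I error at P < 0.001 over ≥ 10⁴ null pairs;
* genome-wide QTL error rate over 200 null families;
* hotspot false-positive rate over 100 uniform-peak replicates;
* planted-QTN 1-LOD interval coverage (PVE 0.20, n = 400, 100
  replicates);
* sweep recovery (ρ_sweep = 0.05, F = 0.10, 150-member panel; a 2-kb
  sweep in a 360-kb scan domain; objective S vs reference NE — the two
  largest subpopulations): window sensitivity, neutral-window FPR,
  Tajima-confirmation rate;
* effect-class and a/d recovery at planted PVE 0.20, n = 300 (the
  dominance contrast at P < 0.001 needs this scale for reliable
  classification);
* planted d×d pair (PVE 0.12, n = 300) detection — the interaction PVE
  was chosen so the 4-df test at P < 0.001 operates at high power
  against the polygenic-plus-noise background;
* LD-decay ρ recovery on synthetic Hill–Weir curves.

## Numerical choices and degenerate inputs

0-based half-open genomic coordinates internally; VCF/GFF3 converted at
the boundary. Multi-allelic VCF records are skipped (counted), not
split. Constant phenotypes give LOD 0; monomorphic score columns are
skipped; quantile edges (α = 1) return the distribution minimum.
Permutation P-values carry the plus-one correction. REML optimises
log δ ∈ [−10, 10] by bounded scalar minimisation; kinship eigenvalues
are floored at 10⁻⁹. The decay fit bounds ρ ∈ (10⁻¹², 10]; ties in
lead-SNP P-values break on genomic coordinate. All stochastic code
paths take explicit integer seeds, and the pipeline writes every
stage's configuration and a content hash into its provenance record;
identical configurations reproduce byte-identical outputs.

## Known limitations

* Single-parent pseudo-testcross only; no CP-cross phase inference, no
  multi-trait or functional (growth-curve) QTL models.
* The scan's missing-marker handling conditions on immediate flanking
  markers only.
* Composite-LD r² underestimates haplotype r² when HWE fails; the EM
  haplotype variant is not implemented.
* The epistasis model is fixed-effects; structure/kinship enter only
  through optional covariates, not a random effect.
* Window statistics at 250 bp on desk-scale SNP densities are noisy;
  empirical-quantile selection criteria are rank-based and cannot flag
  more than q of the windows by construction.
* The hotspot and association-hotspot permutation nulls are package
  constructions where the source prescriptions are ambiguous.
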