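# linkld

Linkage–linkage-disequilibrium (linkage–LD) mapping of dynamic
stem-growth traits in a forest tree, as a tested, reusable pipeline.

The strategy combines two mapping populations. A **full-sib family**
genotyped on a dense linkage map localises quantitative trait loci
(QTL) for height (H), basal diameter (BD) and stem volume (V) measured
repeatedly through time. An unrelated **association panel** — three
climatic subpopulations resequenced at the genomic regions syntenic to
those QTL (segmental homology regions, SHRs) — then dissects each
region at single-SNP resolution: selection scans between
subpopulations, LD structure, mixed-model association with
additive/dominance decomposition, and two-locus epistasis.

Because the study's phenotypes and resequencing data are proprietary,
the package ships a first-class synthetic-data module that emulates
both populations with planted ground truth (QTL with time-varying
effects, selective sweeps, additive/dominant/epistatic causal SNPs),
so every stage is testable end to end.

## Methods at a glance

* **QTL scans** — Haley–Knott regression on the expected QTL genotype
  from flanking markers (Haldane map function, 1-cM grid) in a
  pseudo-testcross coding; `LOD = (n/2)·log10(RSS0/RSS1)`,
  `PVE = 1 − 10^(−2·LOD/n)`. Genome-wide thresholds from 1,000
  phenotype permutations (5% error rate); iterative cofactor (MQM-style)
  rescans; 1-LOD support intervals; co-localisation of QTL whose
  intervals overlap with peaks < 1 cM apart; a permutation test for
  QTL hotspots per 1-cM bin.
* **SHR projection** — piecewise-linear cM↔bp interpolation through at
  least three co-monotone anchor markers per linkage group; regions
  projecting to overlapping genomic intervals merge into one SHR.
* **Selection scans** — π, Watterson's θ_w and Tajima's D per 250-bp
  window per subpopulation; Weir–Cockerham Fst (ratio of sums) per
  subpopulation pair; ROD = 1 − π_obj/π_ref. Windows jointly in the
  top 1% of Fst and of diversity reduction are merged into candidate
  regions and confirmed by a rank-sum test for lower Tajima's D in the
  objective subpopulation.
* **LD** — composite (dosage-correlation) r² with permutation
  P-values; high-LD blocks as maximal runs with all pairs r² ≥ 0.75 and
  P ≤ 10⁻³; decay fitted with the Hill–Weir drift expectation.
* **Association** — EMMAX-style mixed model (IBS kinship, subpopulation
  covariates, one REML fit per phenotype set); thresholds 1/n
  (suggestive) and 0.05/n (significant); least-squares-means
  decomposition into additive `a = (μ_AA − μ_aa)/2` and dominance
  `d = μ_Aa − (μ_AA + μ_aa)/2`; PVE-trajectory classes over
  timepoints; association-hotspot features; lead-SNP signal clustering
  at r² < 0.2.
* **Epistasis** — extended Kempthorne two-locus partition with
  observed-frequency-orthogonal contrasts (a×a, a×d, d×a, d×d), 4-df
  interaction F-test, and contribution c = SS_int/SS_total.

## Worked example

Run the synthetic end-to-end pipeline (a 300-progeny family with one
QTL of PVE 0.20 planted at 30 cM on LG_01, and a 150-member panel with
a planted sweep and a planted additive SNP):

```bash
linkld run --seed 1 --out demo/
cat demo/report.txt
```

```
linkld pipeline report
==============================
                 qtl: 2
            hotspots: 1
   selective_regions: 3
            ld_pairs: 1770
               assoc: 1408
           epistasis: 0
                shrs: 1
            family_qtn_covered: 1/1
              sweeps_recovered: 1/1
```

The two QTL rows in `demo/qtl.tsv` are the planted locus found in both
scanned timepoints — peak at 31.0 cM (truth: 30 cM), LOD 11.1 and 18.2,
PVE 0.16 and 0.24, 1-LOD interval 28.0–33.0 cM covering the truth
(`family_qtn_covered: 1/1`). The interval projects through the anchor
markers to one SHR on Chr01 (`demo/shr.bed`), inside which the scan of
the NW subpopulation against the reference recovers the planted sweep
(`sweeps_recovered: 1/1`). `assoc.tsv` holds the per-SNP mixed-model
results with additive/dominance classes for the suggestive hits;
`epistasis: 0` — no interaction was planted, and none is declared at
P < 0.001.

Individual stages are also exposed as subcommands
(`linkld qtl|assoc|ld|simulate|report`); the library API mirrors the
spec modules (`linkld.linkage_qtl`, `linkld.popgen_selection`,
`linkld.association_mlm`, ...).

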