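# panelprio

A toolkit for the tertiary analysis of targeted rare-disease gene-panel
sequencing: virtual-panel–driven, inheritance-aware prioritization of SNVs
and small indels, a read-depth "gene dose + z-score" CNV caller with
comparative-Ct (2^−ΔΔCt) confirmation arithmetic, panel coverage QC, and
cohort diagnostic-yield summarization. It is aimed at clinical-genetics
bioinformaticians who run large captures (hundreds to ~1,400 genes) but
analyze each patient through a phenotype-specific *virtual panel* — a gene
subset applied in silico — to keep candidate lists interpretable and avoid
incidental findings.

## The method

For each diagnostic case, annotated variant calls pass through a cascade of
filters:

1. **Virtual panel** — keep variants in genes linked to the referral
   phenotype; each panel gene carries its inheritance modes
   (AD / AR / XLd / XLr) and optional exception flags.
2. **Population frequency** — drop variants whose largest population MAF
   exceeds the ceiling of their gene's most permissive mode (defaults:
   10⁻³ dominant, 10⁻² recessive). Genes flagged for previously reported
   pathogenic alleles, hypomorphic alleles, or incomplete penetrance /
   variable expressivity bypass the ceiling; variants with no frequency
   record are kept and flagged.
3. **Clinical classification** — drop benign/likely-benign (ACMG B/LB);
   keep variants with conflicting interpretations of pathogenicity (CIP)
   only when at least one submitter reported P/LP (CIP†).
4. **Zygosity vs inheritance mode** — AD: het or hom; AR: hom, candidate
   compound hets (≥ 2 surviving hets in one gene), or a lone P/LP het kept
   toward a *partial* diagnosis; XLr: hemizygous males, homozygous or
   compound-het females; XLd: any non-reference genotype.
5. **Compound-het phasing and segregation** — with parental genotypes,
   within-gene het pairs are confirmed in trans or discarded in cis;
   candidates inconsistent with unaffected relatives' genotypes are removed
   (full penetrance assumed unless the gene is flagged otherwise).
6. **Ranking and outcome** — candidates are ordered by class, rarity,
   predictor votes and position; each case collapses to POSITIVE
   (genotype-complete P/LP configuration), UNCERTAIN (configuration
   involving a VUS), PARTIAL (monoallelic P/LP in an AR gene), UNSOLVED,
   or CARRIER_FINDINGS for carrier screenings. Survivors at depth < 20×
   are flagged for Sanger confirmation.

The CNV caller median-normalizes a batch depth matrix, builds per-target
reference statistics from the other samples, and calls a target when
**both** the gene dose (sample depth / reference mean; ≈ 0.5 for a het
deletion, ≈ 1.5 for a duplication) and the z-score cross their thresholds
(defaults 0.7 / 1.3 and |z| ≥ 2.5); runs of same-type targets within a gene
merge into events. Orthogonal qPCR confirmation uses fold change
2^−ΔΔCt against negative-control calibrators. QC covers the fold-80 base
penalty (mean depth / 20th percentile of per-base depth; 1 = perfect
uniformity), coverage at 20×/30×, duplicate and on-target fractions, and a
scan for exons covered < 50% in ≥ 95% of batch samples.

A synthetic-data module generates everything at desk scale — annotated
variant tables with planted causal genotypes per inheritance mode,
Mendelian-consistent trios, depth matrices with injected CNVs — so the
whole pipeline is testable without patient data, including a pseudocontrol
spike-in validation harness.

## Worked example

`examples/01_prioritize_case.py` plants a trans compound heterozygote
(both alleles pathogenic) in an autosomal-recessive panel gene among ~300
background variants, then runs the cascade with trio phasing:

```
Filter funnel (variants surviving each stage):
  raw            302
  panel          20
  frequency      15
  classification 11
  zygosity       8
  final          8
Ranked candidates:
  #1 4:509773 C>A GENE0029 HET P segregation=CONSISTENT
  #2 4:511065 C>A GENE0029 HET P segregation=CONSISTENT
  ...
Case outcome: POSITIVE
```

The virtual panel removes ~93% of the raw variants; the planted pair
survives every filter, is phased in trans from the parents, and ranks at
the top, so the case classifies as a positive genetic diagnosis. The other
examples demonstrate CNV calling plus ΔΔCt confirmation
(`02_cnv_calling.py`), coverage QC (`03_panel_qc.py`), pseudocontrol
validation (`04_pseudocontrol_validation.py`) and cohort yield
summarization (`05_cohort_summary.py`). A thin CLI (`panelprio
simulate|prioritize|cnv-call|qc|validate|summarize|report`) wraps the same
functions for shell use.

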