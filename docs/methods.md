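# Methods

## Scope and data model

The toolkit covers the tertiary stage of a targeted rare-disease workflow:
it consumes per-sample VCF 4.2 calls plus a sidecar annotation table, panel
definitions, pedigrees, per-target depth matrices and qPCR Ct tables, and
produces ranked candidate variants, CNV events, QC metrics, case outcomes
and cohort summaries. Secondary analysis (alignment, variant calling) and
annotation computation (consequence prediction, MAF lookup, ACMG engines)
are upstream concerns: annotation arrives as data, keyed by
chrom/pos/ref/alt, because INFO/CSQ dialects vary across annotators while a
flat table is a stable contract. A thin adapter could populate it from VCF
INFO without touching the rest of the toolkit.

Internal coordinates are 1-based inclusive (VCF-style); BED input is
converted at the boundary and round-trips exactly. Chromosome names are
compared after stripping an optional `chr` prefix. Multiallelic records are
decomposed per ALT allele; no left-alignment or normalization is performed
(that is the caller's job, and re-normalizing here would silently re-key
the annotation join).

## Prioritization cascade

Filters run in a fixed order (panel → frequency → classification →
zygosity → compound-het/segregation → ranking) and each is a pure subset
predicate except the compound-het stage, so the funnel counts are
non-increasing by construction and the frequency/classification predicates
commute (property-tested). Design choices that were genuinely open:

- **Frequency ceilings.** Defaults are 10⁻³ for AD/XLD and 10⁻² for
  AR/XLR, the customary dominant/recessive split in diagnostic filtering;
  a gene with several modes is judged against its most permissive ceiling
  (a variant must survive for *some* plausible mode). Exception-flagged
  genes (known pathogenic alleles, hypomorphic alleles, incomplete
  penetrance / variable expressivity) bypass the ceiling entirely, since
  exactly these classes of alleles are known to violate rarity
  assumptions. A variant with no frequency record passes and is flagged
  `NO_FREQUENCY_DATA`: absence of a database entry must never hide a
  candidate.
- **VAF bands.** Heterozygotes outside [0.30, 0.70] and homozygotes below
  0.80 are flagged (`VAF_OUT_OF_RANGE`), never dropped: an aberrant VAF is
  a mosaicism/quality signal for the reviewer, not a veto.
- **Zygosity logic.** A lone het in a recessive-only gene is removed when
  VUS but kept (flagged `MONOALLELIC`) when P/LP, because a monoallelic
  likely causative allele in a recessive gene grounds the *partial*
  outcome and is clinically actionable (targeted second-allele search).
  The het count that licenses compound-het candidacy is taken among
  variants surviving the classification filter, within one gene.
- **Compound-het phasing.** All within-gene het pairs are proposed. With
  parental genotypes, a pair is in trans when each parent carries exactly
  one allele, in cis when one parent carries both while the other carries
  neither, and unknown otherwise (flagged `PHASE_UNKNOWN`). A parent
  listed in the genotype map carries a variant iff an entry exists for its
  key; a parent absent from the map is treated as ungenotyped, making the
  phase unknown rather than wrongly trans. Unphased pairs may support a
  positive outcome — most diagnostic cases are singletons, and insisting
  on trio data would misclassify them wholesale — while cis-established
  pairs are removed; a het VUS whose only retention rationale was such a
  pair is then retired at the final stage.
- **Segregation.** Full penetrance is assumed: an unaffected relative
  carrying a dominant candidate (or the complete recessive genotype) makes
  it inconsistent, unless the gene carries the incomplete-penetrance flag.
  With no genotyped relatives the check returns uninformative and imposes
  nothing.
- **Ranking** is an invented deterministic total order (the workflow being
  reproduced prescribes filters, not an ordering): ACMG class (P > LP >
  CIP† > VUS > unclassified), then smaller maximum MAF (missing treated as
  rarest), then more deleterious in-silico votes, then genomic position as
  the final tie-break. Ties can therefore never reorder across reruns.
- **Outcomes.** POSITIVE requires a genotype-complete P/LP configuration
  (dominant het/hom; recessive hom or non-cis pair, both alleles P/LP;
  hemizygous P/LP for X-linked recessive males). A genotype-complete
  configuration involving a VUS or CIP† yields UNCERTAIN — "compatible
  with the phenotype" is operationalized as membership in the applied
  panel, the panel being the phenotype proxy; free-text phenotype matching
  is out of scope. A lone P/LP het in a recessive-mode gene yields
  PARTIAL. Carrier-mode referrals report het P/LP findings in recessive
  genes as CARRIER_FINDINGS and are excluded from diagnostic yields.
- **Confirmation flag.** Candidates surviving at depth < 20 reads are
  flagged `NEEDS_CONFIRMATION` for orthogonal (Sanger) verification and
  always appear in the report's confirmation section.

## CNV calling

Each sample column is divided by its median target depth, removing
library-size effects (median, not mean, so a handful of true CNV targets
cannot shift the normalizer). The reference baseline for a test sample is
all other batch samples — the simplest defensible choice, documented for
replacement; no outlier-sample removal is applied beyond the per-target
mask. A target is masked when its reference mean relative depth is below
0.1 (too shallow to judge) or its coefficient of variation exceeds 0.3
(intrinsically noisy capture). Masked targets are never called and break
event runs.

Per unmasked target, gene dose = relative depth / reference mean and
z = (relative depth − mean) / max(sd, 0.05). The sd floor of 0.05
relative-depth units prevents infinite z on degenerate (near-identical)
references. Calling requires **both** criteria — dose ≤ 0.7 with
z ≤ −2.5 for deletions, dose ≥ 1.3 with z ≥ 2.5 for duplications —
reflecting that dose measures effect size and z measures evidence; either
alone over-calls. The printed thresholds are configurable defaults: the
workflow being reproduced calibrated its cutoffs privately against
patients with known CNVs, so these values are this package's own
calibration, exercised against synthetic truth. Maximal runs of same-type
calls within one gene merge into events (no bridging across neutral or
masked targets; events below `min_targets` are dropped).

qPCR confirmation: replicate Cts are averaged arithmetically, ΔCt = mean
Ct(target) − mean Ct(reference) per sample, ΔΔCt subtracts the mean ΔCt of
the negative-control calibrators, and fold change = 2^−ΔΔCt with no
efficiency correction (the pure comparative-Ct formula). Fold ≈ 0.5 marks
a heterozygous deletion, ≈ 2 a duplication.

## QC metrics

Fold-80 base penalty = mean per-base depth / 20th percentile of per-base
depth, with linear interpolation between closest ranks so the statistic is
bit-reproducible; it is scale-invariant and equals 1 on constant coverage.
When ≥ 20% of bases have zero depth the statistic is undefined and
reported as missing with a flag rather than infinite. Coverage fractions
are simple ≥-threshold proportions. The commonly-uncovered-exon rule flags
an exon when its covered fraction is strictly below 0.5 in at least 95% of
batch samples; "covered" means per-base depth ≥ 20, a configurable
interpretation (the recurring 20× confirmation threshold) since no
universal depth floor defines "covered". Inputs are run-length-encoded
per-base depth tracks (mosdepth-style BED) and summary read counts, not
alignments.

## Synthetic data

The generator emulates the *shape* of targeted-panel data, not its
biology: an invented genome of 400 genes (1–10 exons each) on five
autosomes plus X, with the layout fixed independently of the draw seed so
fixtures built under different seeds share coordinates. Background
variants draw their class from a mix dominated by benign/unclassified
annotation (P 1%, LP 1%, VUS 15%, CIP 3%, LB 20%, B 30%, none 30%),
frequencies log-uniform on (10⁻⁶, 0.5) with 10% of variants lacking any
record, HET:HOM at 85:15 on autosomes and hemizygous on X for males.
Spiked causal genotypes are placed per inheritance mode with
filter-compatible defaults (MAF 10⁻⁵, depth 100); every spike is listed in
a first-class truth manifest so validation never re-derives truth from
generator internals.

Coverage matrices are baseline × library-size factor × multiplicative
lognormal noise; the lognormal (median 1) keeps a spiked CNV's expected
dose exactly nominal. Default noise sigma is 0.05 (~5% per-target
inter-sample CV, a well-performing hybrid-capture batch) with batches of
12 samples: at this CV the duplication dose threshold 1.3 lies
ln(1.3)/0.05 ≈ 5 noise sigmas out, so chance dose excursions are
negligible, while a het deletion (dose 0.5) is a >13-sigma departure —
the conjunction of dose and z thresholds then separates cleanly. As the
CV grows toward the 0.3 mask ceiling this separation degrades; the
thresholds would need re-calibration for noisier batches, exactly as the
original workflow re-calibrated against known-CNV patients.

What passing tests on these fixtures demonstrate: the cascade's logic
(filters, phasing, outcomes) and the caller's operating characteristics
under the stated noise model. What they do not demonstrate: robustness to
real-data pathologies — segmental duplications, GC waves, batch effects,
allele dropout, annotation disagreement between sources — which have no
synthetic counterpart here.

## Numerical and formatting choices

Yields round half-up to one decimal, reanalysis rates to the nearest
integer percent (`decimal`-based, not banker's rounding). Depth tables
serialize floats with `repr` so write→read round-trips are exact.
Percentile computation is pinned to linear interpolation. Reports render
from `string.Template` with fully deterministic content; identical inputs
yield byte-identical documents, and the same holds for every CLI
subcommand under a fixed seed.

## Known limitations

- Gene matching is by exact case-insensitive symbol; no alias resolution.
- CNV events are per-gene; no cross-gene or breakpoint-resolution calling,
  and CNVs are reported separately from the SNV funnel.
- Segregation handles unaffected-carrier refutation only; it does not
  compute likelihoods over arbitrary pedigrees.
- The uncertain/positive boundary leans entirely on the supplied ACMG
  class labels; no internal evidence scoring.
- X-linked logic treats unknown-sex samples as potentially male for
  hemizygous calls and flags female hemizygous genotypes as data
  inconsistencies rather than resolving them.
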