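"""Prioritize one synthetic diagnostic case with a planted compound het.

Builds a background variant table, spikes a trans compound heterozygote
(P + LP) into an autosomal-recessive panel gene, runs the full filter
cascade with trio phasing, and prints the funnel and ranked candidates.
"""

from panelprio.panels import Mode
from panelprio.prioritize import (
    check_segregation,
    classify_outcome,
    prioritize_case,
)
from panelprio.synthetic import (
    SimConfig,
    SyntheticGenome,
    VariantSpike,
    make_panel_library,
    simulate_pedigree,
    simulate_variant_table,
)
from panelprio.types import ClinClass, SampleCase, Sex

base = SimConfig(seed=42)
genome = SyntheticGenome(base.n_genes)
library = make_panel_library(base, genome)
ar_gene = next(e.gene for e in library["SP1"].entries if e.modes == {Mode.AR})

cfg = SimConfig(
    seed=43,
    spikes=[
        VariantSpike(gene=ar_gene, mode=Mode.AR, pattern="COMPHET",
                     clin_class=ClinClass.P),
    ],
)
variants, manifest = simulate_variant_table(cfg, genome)
spiked = [v for v in variants if (v.chrom, v.pos) in
          {(r.chrom, r.pos) for r in manifest.itertuples()}]
pedigree = simulate_pedigree("CASE001", spiked, manifest)

case = SampleCase(sample_id="CASE001", sex=Sex.MALE, panels=["SP1"])
candidates, funnel = prioritize_case(case, variants, library, pedigree)
outcome = classify_outcome(candidates, case)

print(f"Spiked gene: {ar_gene} (autosomal recessive, trans compound het)")
print("Filter funnel (variants surviving each stage):")
for stage, count in funnel.stages:
    print(f"  {stage:<15}{count}")
print("Ranked candidates:")
for c in candidates:
    v = c.variant
    seg = check_segregation(c, pedigree, "CASE001")
    print(
        f"  #{c.rank} {v.chrom}:{v.pos} {v.ref}>{v.alt} {v.gene} "
        f"{v.zygosity.value} {v.clin_class.value} segregation={seg.value}"
    )
print(f"Case outcome: {outcome.label.value}")
print(
    "The funnel shows the virtual panel doing most of the work; the two\n"
    "planted heterozygotes survive as a parent-phased (trans) pair and\n"
    "yield a positive diagnosis."
)
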