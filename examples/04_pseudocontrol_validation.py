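"""Pseudocontrol spike-in validation of the whole prioritization cascade.

Plants one filter-compatible causal genotype per control sample and checks
end-to-end recovery, then demonstrates that engineered violations are missed
with a stage-specific reason code.
"""

from panelprio.panels import Mode
from panelprio.synthetic import (
    PseudocontrolSpec,
    SimConfig,
    SyntheticGenome,
    VariantSpike,
    default_pseudocontrol_specs,
    make_panel_library,
    run_pseudocontrol_validation,
)
from panelprio.types import ClinClass

base = SimConfig(seed=20)
genome = SyntheticGenome(base.n_genes)
library = make_panel_library(base, genome)

specs = default_pseudocontrol_specs(base, library, genome, n_controls=20)
report = run_pseudocontrol_validation(specs, library, base, genome=genome)
print(
    f"Compatible spikes: recovered {report.recovered}/{report.total_spiked} "
    f"({report.recovery_rate:.0%})"
)

ar_gene = next(e.gene for e in library["SP1"].entries if e.modes == {Mode.AR})
violation = PseudocontrolSpec(
    "VIOL1",
    [VariantSpike(gene=ar_gene, mode=Mode.AR, pattern="HOM", maf=0.2)],
    panels=["SP1"],
)
viol_report = run_pseudocontrol_validation(
    [violation], library, SimConfig(seed=21, n_background_variants=0),
    genome=genome,
)
miss = viol_report.misses[0]
print(
    f"Engineered violation (population frequency 20%): missed at the "
    f"'{miss.reason}' stage"
)
print(
    "Full recovery of compatible spikes, plus stage-attributed misses for\n"
    "engineered violations, is the behavior a diagnostic pipeline must show\n"
    "before clinical use."
)
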